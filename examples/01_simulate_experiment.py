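"""Simulate a Break-Ins-style amplicon experiment with known ground truth.

Builds a mock reference (nuclear chromosome with the break-locus amplicon, a
Ty element with identical terminal repeats, an rDNA interval; mtDNA; 2-micron
plasmid; PhiX-like decoy), draws 500 independent NHEJ products, and renders
paired reads with PCR duplicates, sequencing error, index hopping and decoy
spike-ins.
"""

from collections import Counter

from breakins.simulate import SimulationConfig, render_reads, simulate_events, simulate_reference

mock = simulate_reference(seed=7)
print("reference sequences:", {k: f"{v:,} bp" for k, v in mock.genome.lengths.items()})
print("amplicon:", mock.design.amplicon_len, "bp; cut at offset", mock.design.break_point)

config = SimulationConfig(seed=7, n_products=500)
events = simulate_events(mock, config)
pairs = render_reads(events, mock, config)

classes = Counter(ev.event_class for ev in events)
print("\nsimulated products by repair outcome:", dict(classes))
print("read pairs rendered (PCR copies + spike-ins):", len(pairs))
print("hopped pairs:", sum(p.hopped for p in pairs),
      "| decoy spike-ins:", sum(p.is_phix for p in pairs))

ins = [ev for ev in events if ev.event_class in ("single_donor", "multi_donor")]
sizes = [len(ev.insert_seq) for ev in ins]
print(f"\n{len(ins)} templated insertions; insert sizes "
      f"{min(sizes)}-{max(sizes)} bp (median {sorted(sizes)[len(sizes)//2]})")
# Each insertion's ground truth records junctions, donor intervals, trimming,
# microhomology and untemplated bases -- the oracle every stage is tested against.
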