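# Methods

## The measurement model

The assay amplifies a single repaired break locus from a pooled population of
survivor colonies, each of which represents one independent NHEJ repair
event. A repaired product has the form

```
locus-left-flank (possibly trimmed) · [insert] · locus-right-flank (possibly trimmed)
```

where the insert, when present, is a concatenation of one or more donor
fragments copied from elsewhere in the (nuclear, mitochondrial, plasmid or
retroelement) genome, optionally flanked or separated by a few untemplated
nucleotides. Junctions may carry microhomology: a terminal stretch perfectly
shared by the locus flank and the donor context, which makes the exact
boundary between "locus" and "donor" intrinsically ambiguous.

All coordinate handling is 0-based half-open on the plus strand;
minus-strand alignments store plus-strand intervals with a strand flag. The
single conversion to the 1-based inclusive convention of alignment-tabular
files lives in the align module.

### Junction convention

Every stage resolves microhomology ambiguity the same way: **maximize the
locus alignment first**. Junctions on a merged read are located by diagonal
scoring walks (match +2 / mismatch −3) anchored at the amplicon's two ends —
the left junction is the prefix position maximizing cumulative score, the
right junction the symmetric suffix position. The shared (microhomology)
bases therefore sit inside the locus alignment, donor intervals are the inner
intervals, and the annotation stage recovers microhomology from the donor
context beyond the chosen boundary — never counting a base as both locus and
donor. An insertion event requires an unaligned gap of at least 10 bp whose
amplicon interval contains the cut offset.

### Alignment engine

A seed-and-extend local aligner over a k-mer index: exact-word seeding,
diagonal clustering (band 16), and banded gapped refinement of each cluster
window with an affine-gap dynamic program. Presets: `standard` (word 11,
+2/−3, gap 5/2), `short` (word 7, +1/−1) as the fallback for inserts the
standard preset cannot seed, and `ty-loose` (word 11, +1/−1, gap open 5,
identity floor 60 %) for realigning diverged retroelement inserts.
Significance is a per-preset minimum score (standard 30, short 14, ty-loose
16), calibrated once so that random 20-mers against the mock genome produce
hits in under 1 % of trials; no E-value statistics are computed. Ties order
deterministically (score, subject name, start, '+' before '−').

### Donor segmentation

Greedy cover of the insert: repeatedly take the hit contributing the most
aligned score over still-uncovered insert positions (score prorated by
uncovered fraction — among equal-identity alternatives this is exactly the
largest-covered-proportion rule), stop when less than 10 bp remains
coverable, trim overlaps between adjacent chosen hits at the overlap
midpoint. Proration by score rather than raw coverage makes a long
low-identity chance hit lose to a shorter exact one, which raw coverage
greed does not guarantee. Inserts with no hits in either preset are retained
with zero donors and flagged unmapped.

### Deduplication

The four pairwise rules (junction key, donor-location distances, long-form
identity, cross-sample contamination) are applied in that order, each
completed to an equivalence by union-find transitive closure, making the
partition invariant to event input order; a canonical smallest-index root
rule plus sorted processing makes the output bit-reproducible. Junction-key
comparison uses global edit distance (edlib): identity = 1 − d/max(L),
coverage = min(L)/max(L), differences = d, all three conditions conjunctive —
over a full 60 bp key the 95 % identity condition is strictly tighter than
the 6-difference cap and binds. The multi-donor location rule generalizes
the single-donor distances: the locus-side sum is |Δ left junction| +
|Δ right junction| plus insert-span differences at internal fragment
boundaries; the donor-side sum adds |Δ start| + |Δ end| per paired fragment;
fragments are paired in insert-span order and must match by subject and
strand. Representative selection is lexicographic: mergeable first, then
mean quality, then identical-copy count, then event id.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| minimum insert length | 10 bp | definition of a templated insertion |
| unmerged-pair separation | 10–3,000 bp | same-sequence distance between the two 3′ portions |
| junction key | 11 bp locus + 19 bp donor per junction | duplicate detection key (60 bp combined) |
| junction-rule thresholds | 95 % id, 95 % cov, ≤ 6 diffs | conjunctive |
| location sums | ≤ 6 (single), ≤ 10 (multi) | bp |
| long-form rule | < 10 reads, > 300 bp, > 80 % id (strict) | |
| contamination rule | ≤ 10 vs > 500 reads, same batch | |
| quality means | ≥ 25 (locus region), ≥ 15 (rest) | inclusive, Phred+33 |
| PhiX screen | k = 31, ≥ 1 shared k-mer, both strands | replaces an external screening tool |
| merging | min overlap 10, mismatch fraction ≤ 0.1 | overlap scan maximizing overlap length |
| donor neighborhood | 20 bp | extra bases explainable by the donor context are absorbed |
| permutation shuffles | 100,000 | tests run scaled down (199–10,000) |
| proximity windows | 1 kb (ARS/telomere), 0.2 kb (tRNA/R-loop) | passed per feature |

Every threshold is an explicit argument with these defaults.

## The synthetic-data generator

The generator **defines the study conditions**. Defaults: 2,000 independent
NHEJ products split 30 % simple rejoins / 55 % single-donor / 15 %
multi-donor; donor sources 50 % mtDNA, 20 % Ty, 20 % nuclear, 5 % rDNA, 5 %
2-micron (the stressed-cell regime where mtDNA dominates); insert lengths
log-normal with median ~100 bp clipped to 40–300 bp (efficient NHEJ capture
needs ~45 bp; observed inserts run to ~500 bp); 2–4 fragments per complex
insert (min 20 bp each); trimming 0–20 bp and microhomology 0–5 bp per side;
geometric PCR copy counts (p = 0.4, mean 2.5); 300 bp reads (600-cycle
paired chemistry); 0.1 % per-base substitution error; 1 % index hopping; 10 %
decoy spike-in. The mock reference (~43 kb total) carries one nuclear
chromosome with the amplicon locus (88 bp: 30 bp primer + 11 bp, cut, 18 bp
+ 29 bp primer), a Ty element with two identical 300 bp terminal repeats, a
2 kb rDNA interval, an 8 kb mtDNA sequence, a 3 kb 2-micron sequence, and a
2 kb decoy standing in for PhiX — the screening contract (remove reads
sharing k-mers with a decoy), not the specific genome, is what is exercised.

Ground truth is recorded under the pipeline's own junction convention, and
placements are **rejection-sampled so that no boundary is movable by an
aligner**: an affine-gap extension DP (depth 50) must find no
positive-scoring extension across any junction, fragment boundary or
untemplated-base boundary; realized diagonal junctions on the full product
must equal the constructed ones; fragment sequences must be unique in the
genome (both strands); same-subject same-strand fragments must be too far
apart to bridge in a single gapped alignment; and generated insertions within
a sample must be distinct under the duplication rules (with margin), so that
"number of unique insertions" is well-defined truth. Under error-free
conditions this makes exact recovery of every insertion ≥ 10 bp — junctions,
donor intervals, trims, extras and microhomology — a provable round trip,
which the acceptance checks verify at scale.

What the generator does **not** emulate: empirical MiSeq error profiles
(quality is a two-parameter normal per region; errors are uniform
substitutions, no indels), chimeric PCR artifacts, true biological hotspots
or G4-correlated insertion bias, and donors sampled from repeat families
other than the single two-LTR element. Passing tests therefore demonstrate
correctness of the algorithms under the stated generative model, not
robustness to every artifact of real libraries.

## Statistical procedures

- **Permutation test**: control locations preserve each donor interval's
  size and are placed uniformly on the eligible territory (whole sequences of
  excluded donor classes removed, plus the Ty/rDNA intervals and the
  amplicon). Statistic: overlap count (optionally within a proximity window)
  or median edge distance. p = (1 + #{null at least as extreme})/(N + 1) —
  never exactly 0. Calibration uses the median-distance statistic, whose
  near-continuous null makes a Kolmogorov–Smirnov uniformity check
  meaningful; integer overlap counts over a small genome are too discrete
  for that check by construction.
- **Edge distance**: 0 for any ≥ 1 bp overlap; otherwise nearest-base
  distance (start of later) − (end of earlier, exclusive) + 1, so adjacency
  gives 1. Any monotone convention yields the same permutation p-values.
- **Fisher's exact test** is authored by direct hypergeometric enumeration
  (`math.comb`); two-sided sums tables no more probable than observed (with a
  1e−9 relative tolerance for float ties). The rank-sum and χ² engines wrap
  scipy's exact Mann–Whitney U and the Pearson formula; the test suite checks
  all three against independent enumeration oracles for n ≤ 12.
- **G4 motifs**: four tracts of ≥ 3 G (C on the minus strand) with 1–7 nt
  loops, scanned with overlapping regex lookahead; association uses 100 bp
  non-overlapping windows (the window size is this package's convention).
- **Fold changes**: per-class frequency = 10⁵ × unique insertions /
  n_colonies; a class absent from the reference reports a minimal bound
  computed against a floor of one reference insertion.

## Numerical and degenerate-input choices

Quality thresholds are inclusive ("at least"). A read whose bases are all
locus-aligned is judged on the locus mean alone. Merging scans offsets from
the largest overlap down and takes the first acceptable one; consensus takes
the higher-quality base and the maximum quality. Events with equal scores
anywhere tie-break lexicographically for determinism. The contamination rule
compares cluster representatives by junction key. Ty1 realignment picks the
largest insert coverage, then score, then the **largest** subject start — so
perfect ties between the two identical LTRs resolve to the right LTR; the
right-LTR rule is the only place the aligner's ascending-start tie order is
overridden. Sub-threshold (< 10 bp) inserts and simple rejoins are detected
and logged with reasons but never analyzed further.

## Problem sizes

Tests and the acceptance script run on the ~43 kb mock reference with 100 —
2,000 products, 199–10,000 permutation shuffles and 500-case fuzz oracles —
sizes chosen so the full suite completes in minutes on one core while still
exercising every rule at its exact thresholds; the same code paths scale to
real amplicon libraries (the per-sample deduplication is quadratic in
candidate events after identical-copy collapsing, which is the step to watch
on very deep libraries).

## Known limitations

- Unmerged-pair events carry only a length lower bound and a bounding donor
  interval; they are excluded from size histograms and junction profiling.
- The separation rule for unmerged pairs measures inner hit edges (the
  measurement points are otherwise ambiguous).
- The internal aligner reports no E-values; score floors are calibrated to
  the desk-scale genome and should be re-calibrated for a full-genome
  reference.
- Whether "6 bp mismatches and indels" counts indel events or bases is
  resolved as bases (edit distance).
- The per-sample O(n²) duplicate comparison is exact, not heuristic; for
  millions of candidates a pre-clustering (e.g. exact-key bucketing, already
  used as a fast path) would be needed.
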