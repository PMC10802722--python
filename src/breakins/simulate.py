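"""Mock genomes and ground-truth amplicon read sets.

The generator emulates the products of NHEJ repair at a single induced DSB:
simple rejoins (with end trimming and a few untemplated bases), single-donor
templated insertions, and complex multi-donor insertions whose fragments come
from mtDNA, a Ty retroelement, rDNA, the 2-micron plasmid, or elsewhere in the
nuclear genome. Reads carry an inline 3-base home index in addition to the
(simulated) Illumina sample index, PCR duplicates, per-base sequencing error,
index hopping between samples, and PhiX-like decoy spike-in pairs.

Ground truth is recorded under the same conventions the caller uses: junctions
maximize the locus alignment first, microhomology is the realized maximal
perfect match between flank and donor context, and donor intervals are the
called (inner) intervals. Donor placements are rejection-sampled so that no
accidental sequence coincidence can move a called boundary: the bases beyond
every junction, fragment boundary, and realized microhomology are required to
break any scoring extension. With sequencing error, hopping, and spike-ins
disabled this makes exact recovery of every simulated insertion a well-defined
round trip.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import edlib
import numpy as np

from breakins.model import AmpliconDesign, ReferenceGenome, revcomp

_BASES = "ACGT"

EVENT_CLASSES = ("simple_rejoin", "single_donor", "multi_donor", "short_insert")


def _rand_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[i] for i in rng.integers(0, 4, n))


def _sample_weighted(rng: np.random.Generator, dist: dict) -> object:
    keys = sorted(dist)
    weights = np.array([dist[k] for k in keys], dtype=float)
    return keys[rng.choice(len(keys), p=weights / weights.sum())]


def _occurrences(seqs: dict[str, str], pattern: str) -> int:
    """Count occurrences of pattern on both strands of all sequences (overlapping)."""
    total = 0
    rc = revcomp(pattern)
    for seq in seqs.values():
        for pat in (pattern, rc) if rc != pattern else (pattern,):
            start = 0
            while True:
                i = seq.find(pat, start)
                if i < 0:
                    break
                total += 1
                start = i + 1
    return total


def _no_positive_extension(x: str, y: str, depth: int = 50) -> bool:
    """True iff a local alignment cannot profitably extend from a boundary.

    ``x`` is the continuation on the query side, ``y`` on the reference side,
    both read outward from the boundary. An affine-gap extension DP (match +2,
    mismatch -3, gap open 5, extend 2) starting exactly at the boundary scores
    every possible extension; any positive score means an aligner could absorb
    boundary bases, moving a called junction or donor interval.
    """
    x, y = x[:depth], y[:depth]
    nx, ny = len(x), len(y)
    if nx == 0 or ny == 0:
        return True
    neg = -1e9
    # three-state affine DP over prefixes; extension anchored at (0, 0)
    m = [[neg] * (ny + 1) for _ in range(nx + 1)]   # ends in match/mismatch
    gx = [[neg] * (ny + 1) for _ in range(nx + 1)]  # gap in y (consumes x)
    gy = [[neg] * (ny + 1) for _ in range(nx + 1)]  # gap in x (consumes y)
    m[0][0] = 0.0
    best = 0.0
    for i in range(nx + 1):
        for j in range(ny + 1):
            if i > 0:
                gx[i][j] = max(m[i - 1][j] - 5, gx[i - 1][j] - 2)
            if j > 0:
                gy[i][j] = max(m[i][j - 1] - 5, gy[i][j - 1] - 2)
            if i > 0 and j > 0:
                sub = 2 if x[i - 1] == y[j - 1] else -3
                m[i][j] = max(m[i - 1][j - 1], gx[i - 1][j - 1], gy[i - 1][j - 1]) + sub
            if i or j:
                best = max(best, m[i][j])
                if best > 0:
                    return False
    return True


@dataclass
class SimulationConfig:
    """Study conditions of the simulated amplicon experiment.

    Defaults reflect the assayed system: reads of 300 bp (MiSeq v3 600-cycle
    chemistry), inserts of ~40-300 bp (efficient NHEJ capture requires ~45 bp,
    and observed templated inserts run up to ~500 bp), a donor mix dominated by
    mtDNA in stressed cells, complex events joining 2-4 fragments, a ~10%
    PhiX spike-in, and a low rate of index hopping countered by the home index.
    """

    seed: int = 0
    n_products: int = 2000
    class_mix: dict = field(default_factory=lambda: {
        "simple_rejoin": 0.30, "single_donor": 0.55, "multi_donor": 0.15,
    })
    donor_source_mix: dict = field(default_factory=lambda: {
        "mtDNA": 0.50, "Ty": 0.20, "nuclear": 0.20, "rDNA": 0.05, "plasmid_2micron": 0.05,
    })
    insert_len_min: int = 40
    insert_len_max: int = 300
    insert_len_log_mean: float = 4.6   # lognormal location: median ~100 bp
    insert_len_log_sigma: float = 0.5
    n_donor_fragments_dist: dict = field(default_factory=lambda: {2: 0.6, 3: 0.3, 4: 0.1})
    min_fragment_len: int = 20
    microhomology_len_dist: dict = field(default_factory=lambda: {
        0: 0.50, 1: 0.15, 2: 0.12, 3: 0.10, 4: 0.08, 5: 0.05,
    })
    trim_len_dist: dict = field(default_factory=lambda: {
        0: 0.45, 1: 0.12, 2: 0.10, 3: 0.08, 4: 0.07, 5: 0.06, 6: 0.05, 8: 0.04,
        12: 0.02, 20: 0.01,
    })
    extra_len_dist: dict = field(default_factory=lambda: {0: 0.75, 1: 0.10, 2: 0.08, 3: 0.07})
    pcr_geometric_p: float = 0.4
    pcr_max_copies: int = 20
    per_base_error_rate: float = 0.001
    read_len: int = 300
    index_hop_rate: float = 0.01
    phix_fraction: float = 0.10
    q_mean_locus: float = 35.0
    q_mean_rest: float = 33.0
    q_disp: float = 3.0

    def __post_init__(self) -> None:
        for name, mix in (("class_mix", self.class_mix), ("donor_source_mix", self.donor_source_mix)):
            if any(not 0 <= v <= 1 for v in mix.values()):
                raise ValueError(f"{name} proportions must lie in [0,1]")
            if abs(sum(mix.values()) - 1.0) > 1e-9:
                raise ValueError(f"{name} must sum to 1")
        for cls in self.class_mix:
            if cls not in EVENT_CLASSES:
                raise ValueError(f"unknown event class {cls!r}")
        if self.insert_len_min < 10 and "short_insert" not in self.class_mix:
            raise ValueError("insert lengths below 10 bp belong to the short_insert class")
        for p in (self.per_base_error_rate, self.index_hop_rate, self.phix_fraction):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0,1]")


@dataclass
class TruthSegment:
    subject: str
    start: int
    end: int
    strand: str
    insert_start: int
    insert_end: int

    def oriented_seq(self, genome: ReferenceGenome) -> str:
        return genome.fetch(self.subject, self.start, self.end, self.strand)


@dataclass
class GroundTruthEvent:
    """One independent NHEJ product with full generative provenance."""

    event_id: str
    sample_id: str
    event_class: str
    trim_left: int
    trim_right: int
    mh_left: int
    mh_right: int
    extra_left: str
    extra_right: str
    segments: list[TruthSegment]
    insert_seq: str
    left_junction: int
    right_junction: int
    product_seq: str
    pcr_copies: int

    def render(self, amplicon: str) -> str:
        """Deterministically rebuild the product from the truth fields."""
        return amplicon[: self.left_junction] + self.insert_seq + amplicon[self.right_junction :]


@dataclass
class MockReference:
    """A mock genome bundle: reference, amplicon design, decoy, Ty1 element."""

    genome: ReferenceGenome
    design: AmpliconDesign
    decoy_name: str
    decoy_seq: str
    ty_interval: tuple[int, int]   # on the nuclear chromosome
    ty_ltr_len: int
    rdna_interval: tuple[int, int]

    @property
    def ty1_seq(self) -> str:
        s, e = self.ty_interval
        return self.genome.sequences[self.design.locus_name][s:e]

    def ty1_reference(self) -> ReferenceGenome:
        """The canonical Ty1 element as its own realignment reference."""
        seq = self.ty1_seq
        return ReferenceGenome(
            sequences={"Ty1": seq},
            source_class_map={"Ty1": "Ty"},
            class_intervals={"Ty": [("Ty1", 0, len(seq))]},
        )

    def ty1_ltr_intervals(self) -> tuple[tuple[int, int], tuple[int, int]]:
        n = len(self.ty1_seq)
        return (0, self.ty_ltr_len), (n - self.ty_ltr_len, n)

    def write_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for name, seq in list(self.genome.sequences.items()) + [(self.decoy_name, self.decoy_seq)]:
                fh.write(f">{name}\n")
                for i in range(0, len(seq), 70):
                    fh.write(seq[i : i + 70] + "\n")

    def donor_windows(self, margin: int = 12) -> dict[str, list[tuple[str, int, int]]]:
        """Eligible sampling windows per donor source class."""
        chrn = self.design.locus_name
        chrn_len = len(self.genome.sequences[chrn])
        ty_s, ty_e = self.ty_interval
        rd_s, rd_e = self.rdna_interval
        loc_s, loc_e = self.design.amplicon_start, self.design.amplicon_end
        blocked = sorted([
            (max(0, loc_s - 500), min(chrn_len, loc_e + 500)),
            (ty_s - 100, ty_e + 100),
            (rd_s - 100, rd_e + 100),
        ])
        nuclear: list[tuple[str, int, int]] = []
        cursor = margin
        for bs, be in blocked:
            if bs - cursor > 200:
                nuclear.append((chrn, cursor, bs))
            cursor = max(cursor, be)
        if chrn_len - margin - cursor > 200:
            nuclear.append((chrn, cursor, chrn_len - margin))
        mito = next(n for n, c in self.genome.source_class_map.items() if c == "mtDNA")
        plasmid = next(n for n, c in self.genome.source_class_map.items() if c == "plasmid_2micron")
        return {
            "nuclear": nuclear,
            "mtDNA": [(mito, margin, len(self.genome.sequences[mito]) - margin)],
            "plasmid_2micron": [(plasmid, margin, len(self.genome.sequences[plasmid]) - margin)],
            # internal region only: the two identical LTRs are non-unique by design
            "Ty": [(chrn, ty_s + self.ty_ltr_len + margin, ty_e - self.ty_ltr_len - margin)],
            "rDNA": [(chrn, rd_s + margin, rd_e - margin)],
        }


_DEFAULT_SIZES = {
    "nuclear": 30_000,
    "mtDNA": 8_000,
    "plasmid_2micron": 3_000,
    "decoy": 2_000,
    "ty_ltr": 300,
    "ty_internal": 4_000,
    "rdna": 2_000,
}

_DEFAULT_SAMPLES = {
    "S1": (("AACCGGTT", "TTGGCCAA"), ("ACT", "GAT")),
    "S2": (("CCAATTGG", "GGTTAACC"), ("CGA", "TCG")),
    "S3": (("GGTTCCAA", "AACCTTGG"), ("GTC", "ATC")),
}


def simulate_reference(seed: int, sizes: dict | None = None) -> MockReference:
    """Build a deterministic mock reference with every donor source class.

    The nuclear chromosome carries the break-locus amplicon, a Ty element with
    two identical terminal repeats (for the right-LTR tie-break), and an rDNA
    interval; separate sequences model mtDNA, the 2-micron plasmid, and a
    PhiX-like decoy.
    """
    sz = dict(_DEFAULT_SIZES)
    if sizes:
        sz.update(sizes)
    for key in ("nuclear", "mtDNA", "plasmid_2micron", "decoy"):
        if sz[key] < 500:
            raise ValueError(f"sequence size for {key!r} must be >= 500 bp")
    rng = np.random.default_rng(seed)
    ltr = _rand_dna(rng, sz["ty_ltr"])
    ty_internal = _rand_dna(rng, sz["ty_internal"])
    ty_element = ltr + ty_internal + ltr
    ty_start, rdna_start = 12_000, 20_000
    backbone = _rand_dna(rng, sz["nuclear"])
    chrn = backbone[:ty_start] + ty_element + backbone[ty_start : rdna_start - len(ty_element)] \
        + backbone[rdna_start - len(ty_element):]
    chrn = chrn[: sz["nuclear"]]
    ty_interval = (ty_start, ty_start + len(ty_element))
    rdna_interval = (rdna_start, rdna_start + sz["rdna"])
    genome = ReferenceGenome(
        sequences={
            "chrN": chrn,
            "mito": _rand_dna(rng, sz["mtDNA"]),
            "two_micron": _rand_dna(rng, sz["plasmid_2micron"]),
        },
        source_class_map={"chrN": "nuclear", "mito": "mtDNA", "two_micron": "plasmid_2micron"},
        class_intervals={
            "Ty": [("chrN", *ty_interval)],
            "rDNA": [("chrN", *rdna_interval)],
        },
    )
    # amplicon: 30 bp left primer + 11 bp, cut, 18 bp + 29 bp right primer
    design = AmpliconDesign(
        locus_name="chrN",
        amplicon_start=1_000,
        amplicon_end=1_088,
        break_point=41,
        left_flank_len=11,
        right_flank_len=18,
        home_index_len=3,
        sample_indexes=dict(_DEFAULT_SAMPLES),
    )
    return MockReference(
        genome=genome,
        design=design,
        decoy_name="phix_decoy",
        decoy_seq=_rand_dna(rng, sz["decoy"]),
        ty_interval=ty_interval,
        ty_ltr_len=sz["ty_ltr"],
        rdna_interval=rdna_interval,
    )


def _oriented_left_context(genome: ReferenceGenome, seg: TruthSegment, k: int) -> str:
    seq = genome.sequences[seg.subject]
    if seg.strand == "+":
        return seq[max(0, seg.start - k) : seg.start]
    return revcomp(seq[seg.end : seg.end + k])


def _oriented_right_context(genome: ReferenceGenome, seg: TruthSegment, k: int) -> str:
    seq = genome.sequences[seg.subject]
    if seg.strand == "+":
        return seq[seg.end : seg.end + k]
    return revcomp(seq[max(0, seg.start - k) : seg.start])


def _realized_mh(flank: str, context: str, cap: int = 10) -> int:
    """Longest terminal string perfectly shared by flank end and donor context end.

    Both strings are read so that their last characters abut the junction.
    """
    m = 0
    while m < cap and m < len(flank) and m < len(context) and flank[-1 - m] == context[-1 - m]:
        m += 1
    return m


class _PlacementError(Exception):
    pass


def _diag_boundaries(product: str, amplicon: str) -> tuple[int, int]:
    """Realized junctions under the locus-maximizing diagonal convention.

    Returns (left junction, right junction) in amplicon coordinates: the
    earliest prefix/suffix positions maximizing the cumulative match(+2) /
    mismatch(-3) score of product against amplicon.
    """
    best, left, score = 0.0, 0, 0.0
    for i in range(min(len(product), len(amplicon))):
        score += 2 if product[i] == amplicon[i] else -3
        if score > best:
            best, left = score, i + 1
    best, best_k, score = 0.0, 0, 0.0
    for k in range(1, min(len(product), len(amplicon)) + 1):
        score += 2 if product[-k] == amplicon[-k] else -3
        if score > best:
            best, best_k = score, k
    return left, len(amplicon) - best_k


def _place_fragment(
    rng: np.random.Generator,
    mock: MockReference,
    windows: list[tuple[str, int, int]],
    frag_len: int,
    left_needle: str | None,
    right_needle: str | None,
) -> TruthSegment:
    """Place one donor fragment, optionally forcing junction microhomology.

    ``left_needle`` (if given) must equal the fragment's oriented left context;
    ``right_needle`` its oriented right context. Raises when no placement fits.
    """
    genome = mock.genome
    margin = 12
    for _ in range(60):
        subject, lo, hi = windows[rng.integers(0, len(windows))]
        if hi - lo < frag_len + 2 * margin:
            continue
        strand = "+" if rng.random() < 0.5 else "-"
        seq = genome.sequences[subject]
        if left_needle:
            # occurrence whose end becomes the fragment start (plus) / start
            # becomes the fragment end (minus)
            pat = left_needle if strand == "+" else revcomp(left_needle)
            positions = []
            i = seq.find(pat, lo + margin)
            while 0 <= i and i + len(pat) <= hi - margin:
                positions.append(i)
                i = seq.find(pat, i + 1)
            positions = [positions[j] for j in rng.permutation(len(positions))]
            for occ in positions:
                if strand == "+":
                    s = occ + len(pat)
                    e = s + frag_len
                else:
                    e = occ
                    s = e - frag_len
                if lo + margin <= s and e <= hi - margin:
                    return TruthSegment(subject, s, e, strand, 0, 0)
            continue
        if right_needle:
            pat = right_needle if strand == "+" else revcomp(right_needle)
            positions = []
            i = seq.find(pat, lo + margin)
            while 0 <= i and i + len(pat) <= hi - margin:
                positions.append(i)
                i = seq.find(pat, i + 1)
            positions = [positions[j] for j in rng.permutation(len(positions))]
            for occ in positions:
                if strand == "+":
                    e = occ
                    s = e - frag_len
                else:
                    s = occ + len(pat)
                    e = s + frag_len
                if lo + margin <= s and e <= hi - margin:
                    return TruthSegment(subject, s, e, strand, 0, 0)
            continue
        s = int(rng.integers(lo + margin, hi - margin - frag_len))
        return TruthSegment(subject, s, s + frag_len, strand, 0, 0)
    raise _PlacementError("no fragment placement found")


def _build_insertion(
    rng: np.random.Generator,
    mock: MockReference,
    cfg: SimulationConfig,
    event_class: str,
) -> dict:
    """Sample one insertion event; raises _PlacementError when guards fail."""
    genome, design = mock.genome, mock.design
    amplicon = design.amplicon_seq(genome)
    windows_by_class = mock.donor_windows()

    t_l = _sample_weighted(rng, cfg.trim_len_dist)
    t_r = _sample_weighted(rng, cfg.trim_len_dist)
    p_l = design.break_point - t_l
    p_r = design.break_point + t_r

    if event_class == "short_insert":
        n_frags = 1
        total_len = int(rng.integers(1, 10))
    elif event_class == "single_donor":
        n_frags = 1
        total_len = int(np.clip(
            round(rng.lognormal(cfg.insert_len_log_mean, cfg.insert_len_log_sigma)),
            cfg.insert_len_min, cfg.insert_len_max,
        ))
    else:
        n_frags = _sample_weighted(rng, cfg.n_donor_fragments_dist)
        total_len = int(np.clip(
            round(rng.lognormal(cfg.insert_len_log_mean, cfg.insert_len_log_sigma)),
            max(cfg.insert_len_min, n_frags * cfg.min_fragment_len), cfg.insert_len_max,
        ))

    mh_l_target = _sample_weighted(rng, cfg.microhomology_len_dist)
    mh_r_target = _sample_weighted(rng, cfg.microhomology_len_dist)
    extra_left = "" if mh_l_target > 0 else _rand_dna(rng, _sample_weighted(rng, cfg.extra_len_dist))
    extra_right = "" if mh_r_target > 0 else _rand_dna(rng, _sample_weighted(rng, cfg.extra_len_dist))
    if event_class == "short_insert":
        extra_left = extra_right = ""

    # fragment lengths
    if event_class == "short_insert":
        frag_lens = [total_len]
    else:
        spare = total_len - n_frags * cfg.min_fragment_len
        parts = rng.multinomial(spare, [1.0 / n_frags] * n_frags) if spare > 0 else [0] * n_frags
        frag_lens = [cfg.min_fragment_len + int(p) for p in parts]

    segments: list[TruthSegment] = []
    for k, flen in enumerate(frag_lens):
        source = _sample_weighted(rng, cfg.donor_source_mix)
        windows = windows_by_class[source]
        left_needle = amplicon[p_l - mh_l_target : p_l] if (k == 0 and mh_l_target > 0 and not extra_left) else None
        right_needle = (
            amplicon[p_r : p_r + mh_r_target]
            if (k == n_frags - 1 and n_frags > 1 and mh_r_target > 0 and not extra_right)
            else None
        )
        seg = _place_fragment(rng, mock, windows, flen, left_needle, right_needle)
        segments.append(seg)

    oriented = [seg.oriented_seq(genome) for seg in segments]
    insert_seq = extra_left + "".join(oriented) + extra_right
    if event_class != "short_insert" and len(insert_seq) < 10:
        raise _PlacementError("insert too short")

    # fragments sharing subject and strand must be far enough apart that no
    # single gapped alignment can bridge them
    for ai in range(n_frags):
        for bi in range(ai + 1, n_frags):
            sa, sb = segments[ai], segments[bi]
            if sa.subject == sb.subject and sa.strand == sb.strand:
                gap = max(sb.start - sa.end, sa.start - sb.end)
                if gap < total_len + 66:
                    raise _PlacementError("same-subject fragments bridgeable")

    # --- guards: no boundary may be movable by an aligner ---
    if not _no_positive_extension(insert_seq, amplicon[p_l : p_l + 16]):
        raise _PlacementError("left junction extendable")
    if not _no_positive_extension(insert_seq[::-1], amplicon[max(0, p_r - 16) : p_r][::-1]):
        raise _PlacementError("right junction extendable")
    if event_class != "short_insert":
        for seq in oriented:
            if _occurrences(genome.sequences, seq) != 1:
                raise _PlacementError("fragment not unique")
        for k in range(n_frags - 1):
            # the query-side continuation is the whole rest of the insert:
            # an aligner extension can cross several fragment boundaries
            right_ctx = _oriented_right_context(genome, segments[k], 50)
            x_fwd = "".join(oriented[k + 1 :]) + extra_right
            if not _no_positive_extension(x_fwd, right_ctx):
                raise _PlacementError("fragment boundary extendable (fwd)")
            left_ctx = _oriented_left_context(genome, segments[k + 1], 50)
            x_rev = (extra_left + "".join(oriented[: k + 1]))[::-1]
            if not _no_positive_extension(x_rev, left_ctx[::-1]):
                raise _PlacementError("fragment boundary extendable (rev)")
        if extra_left:
            left_ctx = _oriented_left_context(genome, segments[0], 50)
            if not _no_positive_extension(extra_left[::-1], left_ctx[::-1]):
                raise _PlacementError("extra-left extendable")
        if extra_right:
            right_ctx = _oriented_right_context(genome, segments[-1], 50)
            if not _no_positive_extension(extra_right, right_ctx):
                raise _PlacementError("extra-right extendable")

    # realized microhomology (maximal perfect match, 0 when extra bases present)
    if extra_left or event_class == "short_insert":
        mh_l = 0
    else:
        mh_l = _realized_mh(amplicon[:p_l], _oriented_left_context(genome, segments[0], 10))
        if mh_l_target > 0 and mh_l != mh_l_target:
            raise _PlacementError("left microhomology not realized")
    if extra_right or event_class == "short_insert":
        mh_r = 0
    else:
        # right-side strings read away from the junction: reverse both
        mh_r = _realized_mh(
            amplicon[p_r : p_r + 10][::-1],
            _oriented_right_context(genome, segments[-1], 10)[::-1],
        )
        if mh_r_target > 0 and n_frags > 1 and mh_r != mh_r_target:
            raise _PlacementError("right microhomology not realized")

    # insert spans
    off = len(extra_left)
    for seg, seq in zip(segments, oriented):
        seg.insert_start = off
        seg.insert_end = off + len(seq)
        off += len(seq)

    product = amplicon[:p_l] + insert_seq + amplicon[p_r:]
    if _diag_boundaries(product, amplicon) != (p_l, p_r):
        raise _PlacementError("realized diagonal junctions differ from construction")
    return {
        "trim_left": t_l, "trim_right": t_r, "mh_left": mh_l, "mh_right": mh_r,
        "extra_left": extra_left, "extra_right": extra_right,
        "segments": segments, "insert_seq": insert_seq,
        "left_junction": p_l, "right_junction": p_r, "product_seq": product,
    }


def _junction_signature(fields: dict, amplicon: str, locus_bp: int = 11, donor_bp: int = 19) -> str:
    lj, rj, ins = fields["left_junction"], fields["right_junction"], fields["insert_seq"]
    return (
        amplicon[max(0, lj - locus_bp) : lj] + ins[:donor_bp]
        + ins[-donor_bp:] + amplicon[rj : rj + locus_bp]
    )


def _too_similar(new: dict, old: dict, amplicon: str) -> bool:
    """True when two generated insertions would collapse under deduplication.

    Simulated unique insertions are required to be distinct under the junction,
    location and long-form duplication rules (with margin), so that the number
    of unique insertions is well defined ground truth.
    """
    ka = _junction_signature(new, amplicon)
    kb = _junction_signature(old, amplicon)
    if edlib.align(ka, kb, task="distance")["editDistance"] <= 8:
        return True
    sa, sb = new["segments"], old["segments"]
    if len(sa) == len(sb) > 0 and all(
        x.subject == y.subject and x.strand == y.strand for x, y in zip(sa, sb)
    ):
        locus = abs(new["left_junction"] - old["left_junction"]) + abs(
            new["right_junction"] - old["right_junction"]
        )
        donor = sum(abs(x.start - y.start) + abs(x.end - y.end) for x, y in zip(sa, sb))
        if locus <= 12 and donor <= 12:
            return True
    pa, pb = new["product_seq"], old["product_seq"]
    if len(pa) > 300 and len(pb) > 300:
        dist = edlib.align(pa, pb, task="distance")["editDistance"]
        if 1.0 - dist / max(len(pa), len(pb)) > 0.78:
            return True
    return False


def _build_rejoin(rng: np.random.Generator, mock: MockReference, cfg: SimulationConfig) -> dict:
    design = mock.design
    amplicon = design.amplicon_seq(mock.genome)
    t_l = _sample_weighted(rng, cfg.trim_len_dist)
    t_r = _sample_weighted(rng, cfg.trim_len_dist)
    extra = _rand_dna(rng, _sample_weighted(rng, cfg.extra_len_dist))
    if t_l == 0 and t_r == 0 and not extra:
        t_r = 1  # a perfect rejoin restores the cut site; survivors are imprecise
    p_l = design.break_point - t_l
    p_r = design.break_point + t_r
    product = amplicon[:p_l] + extra + amplicon[p_r:]
    return {
        "trim_left": t_l, "trim_right": t_r, "mh_left": 0, "mh_right": 0,
        "extra_left": extra, "extra_right": "", "segments": [], "insert_seq": extra,
        "left_junction": p_l, "right_junction": p_r, "product_seq": product,
    }


def simulate_events(
    mock: MockReference, config: SimulationConfig
) -> list[GroundTruthEvent]:
    """Generate ground-truth NHEJ products under the configured study conditions."""
    rng = np.random.default_rng(config.seed)
    sample_ids = sorted(mock.design.sample_indexes)
    amplicon = mock.design.amplicon_seq(mock.genome)
    events: list[GroundTruthEvent] = []
    prior: dict[str, list[dict]] = {sid: [] for sid in sample_ids}
    for i in range(config.n_products):
        cls = _sample_weighted(rng, config.class_mix)
        sample_id = sample_ids[rng.integers(0, len(sample_ids))]
        for _attempt in range(500):
            try:
                if cls == "simple_rejoin":
                    fields = _build_rejoin(rng, mock, config)
                else:
                    fields = _build_insertion(rng, mock, config, cls)
            except _PlacementError:
                continue
            if cls in ("single_donor", "multi_donor") and any(
                _too_similar(fields, old, amplicon) for old in prior[sample_id]
            ):
                continue
            break
        else:
            raise RuntimeError(f"could not place event of class {cls!r} after 500 attempts")
        if cls in ("single_donor", "multi_donor"):
            prior[sample_id].append(fields)
        copies = min(int(rng.geometric(config.pcr_geometric_p)), config.pcr_max_copies)
        events.append(
            GroundTruthEvent(
                event_id=f"ev{i:05d}",
                sample_id=sample_id,
                event_class=cls,
                pcr_copies=copies,
                **fields,
            )
        )
    return events


@dataclass
class SimulatedPair:
    """One rendered read pair, with its generative provenance."""

    read_id: str
    event_id: str | None       # None for decoy spike-ins
    true_sample: str
    illumina_pair: tuple[str, str]
    seq1: str
    qual1: str
    seq2: str
    qual2: str
    hopped: bool = False
    is_phix: bool = False


def _phred_string(rng: np.random.Generator, means: np.ndarray, disp: float) -> str:
    q = np.clip(np.rint(rng.normal(means, disp)), 2, 40).astype(int)
    return "".join(chr(33 + v) for v in q)


def _inject_errors(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    mask = rng.random(len(seq)) < rate
    if not mask.any():
        return seq
    out = list(seq)
    for i in np.flatnonzero(mask):
        out[i] = _BASES[(("ACGT".index(out[i]) if out[i] in _BASES else 0) + int(rng.integers(1, 4))) % 4]
    return "".join(out)


def render_reads(
    events: Sequence[GroundTruthEvent],
    mock: MockReference,
    config: SimulationConfig,
) -> list[SimulatedPair]:
    """Render every PCR copy of every product as a read pair, plus spike-ins.

    R1 reads home-index + product; R2 reads home-index + reverse complement of
    the product. A fraction ``index_hop_rate`` of pairs receives the Illumina
    index pair of a different sample while keeping the true home index, and
    ``phix_fraction`` of all pairs are drawn from the decoy sequence.
    """
    rng = np.random.default_rng(config.seed + 1 if config.seed < 2**31 - 1 else 0)
    design = mock.design
    rl = config.read_len
    if rl < design.junction_flank_locus + design.junction_flank_donor:
        raise ValueError("read_len shorter than the junction key span")
    sample_ids = sorted(design.sample_indexes)
    pairs: list[SimulatedPair] = []
    for ev in events:
        ill_true, home = design.sample_indexes[ev.sample_id]
        product = ev.product_seq
        t1 = home[0] + product
        t2 = home[1] + revcomp(product)
        p_l, p_r = ev.left_junction, ev.right_junction
        ins_len = len(ev.insert_seq)
        # per-base region flags (locus vs insert) for the quality model
        flags1 = np.concatenate([
            np.zeros(len(home[0])), np.zeros(p_l), np.ones(ins_len),
            np.zeros(len(product) - p_l - ins_len),
        ])[: len(t1)]
        flags2 = np.concatenate([
            np.zeros(len(home[1])), np.zeros(len(product) - p_l - ins_len),
            np.ones(ins_len), np.zeros(p_l),
        ])[: len(t2)]
        for c in range(ev.pcr_copies):
            hop = rng.random() < config.index_hop_rate and len(sample_ids) > 1
            if hop:
                others = [s for s in sample_ids if s != ev.sample_id]
                ill = design.sample_indexes[others[rng.integers(0, len(others))]][0]
            else:
                ill = ill_true
            s1, s2 = t1[:rl], t2[:rl]
            m1 = np.where(flags1[: len(s1)] > 0, config.q_mean_rest, config.q_mean_locus)
            m2 = np.where(flags2[: len(s2)] > 0, config.q_mean_rest, config.q_mean_locus)
            pairs.append(
                SimulatedPair(
                    read_id=f"{ev.event_id}:c{c}",
                    event_id=ev.event_id,
                    true_sample=ev.sample_id,
                    illumina_pair=ill,
                    seq1=_inject_errors(rng, s1, config.per_base_error_rate),
                    qual1=_phred_string(rng, m1, config.q_disp),
                    seq2=_inject_errors(rng, s2, config.per_base_error_rate),
                    qual2=_phred_string(rng, m2, config.q_disp),
                    hopped=hop,
                )
            )
    # decoy spike-ins, a fraction phix_fraction of the final pool
    if config.phix_fraction > 0 and pairs:
        n_phix = rng.binomial(len(pairs), config.phix_fraction / (1 - config.phix_fraction))
        decoy = mock.decoy_seq
        for j in range(n_phix):
            sid = sample_ids[rng.integers(0, len(sample_ids))]
            ill, home = design.sample_indexes[sid]
            frag_len = int(rng.integers(300, 500))
            start = int(rng.integers(0, len(decoy) - frag_len))
            frag = decoy[start : start + frag_len]
            t1 = (home[0] + frag)[:rl]
            t2 = (home[1] + revcomp(frag))[:rl]
            pairs.append(
                SimulatedPair(
                    read_id=f"phix{j:05d}",
                    event_id=None,
                    true_sample=sid,
                    illumina_pair=ill,
                    seq1=_inject_errors(rng, t1, config.per_base_error_rate),
                    qual1=_phred_string(rng, np.full(len(t1), config.q_mean_rest), config.q_disp),
                    seq2=_inject_errors(rng, t2, config.per_base_error_rate),
                    qual2=_phred_string(rng, np.full(len(t2), config.q_mean_rest), config.q_disp),
                    is_phix=True,
                )
            )
    return pairs


def write_fastq_pairs(pairs: Sequence[SimulatedPair], r1_path: str | Path, r2_path: str | Path) -> None:
    with open(r1_path, "w") as f1, open(r2_path, "w") as f2:
        for p in pairs:
            f1.write(f"@{p.read_id}/1\n{p.seq1}\n+\n{p.qual1}\n")
            f2.write(f"@{p.read_id}/2\n{p.seq2}\n+\n{p.qual2}\n")


def write_index_tsv(pairs: Sequence[SimulatedPair], path: str | Path) -> None:
    """Index-assignment table: read id and the Illumina index pair it carries."""
    with open(path, "w") as fh:
        fh.write("read_id\tindex_i5\tindex_i7\n")
        for p in pairs:
            fh.write(f"{p.read_id}\t{p.illumina_pair[0]}\t{p.illumina_pair[1]}\n")


def write_truth_json(events: Sequence[GroundTruthEvent], path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump([asdict(ev) for ev in events], fh, indent=1)


def load_truth_json(path: str | Path) -> list[GroundTruthEvent]:
    with open(path) as fh:
        raw = json.load(fh)
    events = []
    for d in raw:
        d["segments"] = [TruthSegment(**s) for s in d["segments"]]
        events.append(GroundTruthEvent(**d))
    return events
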