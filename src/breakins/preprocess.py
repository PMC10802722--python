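"""Demultiplexing, index-hop and PhiX removal, quality filtering, read merging.

Filter order in the pipeline is fixed: hop -> PhiX -> merge -> quality, and
every stage conserves records (kept + discarded = input), which the per-record
discard log makes assertable.

Reads arrive with a 3-base home index inline at the 5' end of each mate, in
addition to the Illumina sample index carried alongside. A pair is kept for
sample s only when both index layers agree on s; disagreement is the signature
of index hopping. PhiX screening is exact k-mer sharing with a decoy sequence
(k=31 by default), replacing an external screening tool with the same
contract. Merging is an overlap scan maximizing overlap length with a mismatch
ceiling; at overlap mismatches the higher-quality base wins and the consensus
quality is the maximum of the two.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from breakins.model import AmpliconDesign, revcomp


@dataclass
class ReadPair:
    """A demultiplexed read pair with home indexes already stripped."""

    read_id: str
    seq1: str
    qual1: str
    seq2: str
    qual2: str
    illumina_sample: str | None = None
    home_sample: str | None = None

    def __post_init__(self) -> None:
        if len(self.seq1) != len(self.qual1) or len(self.seq2) != len(self.qual2):
            raise ValueError(f"read {self.read_id}: sequence/quality length mismatch")


@dataclass
class MergedRead:
    read_id: str
    seq: str
    qual: str
    merged: bool
    source: ReadPair


@dataclass
class DiscardLog:
    """Per-record discard reasons, one (read_id, stage, reason) row each."""

    rows: list[tuple[str, str, str]] = field(default_factory=list)

    def add(self, read_id: str, stage: str, reason: str) -> None:
        self.rows.append((read_id, stage, reason))

    def count(self, stage: str | None = None) -> int:
        return sum(1 for r in self.rows if stage is None or r[1] == stage)


def demultiplex_and_filter_hops(
    pairs: Iterable,
    design: AmpliconDesign,
    log: DiscardLog | None = None,
) -> tuple[dict[str, list[ReadPair]], DiscardLog]:
    """Assign pairs to samples; keep only pairs whose two index layers agree.

    Input records need ``read_id``, ``seq1/qual1``, ``seq2/qual2`` and
    ``illumina_pair`` attributes (the simulator's rendered pairs qualify).
    The home index is read from the first bases of each mate and stripped.
    A pair is kept for sample s iff illumina sample == home sample == s;
    everything else is logged as ``hop`` (two valid but different samples) or
    ``unassigned`` (either layer unresolvable).
    """
    if log is None:
        log = DiscardLog()
    ill_lookup = design.illumina_lookup()
    home_lookup = design.home_lookup()
    n = design.home_index_len
    out: dict[str, list[ReadPair]] = {sid: [] for sid in design.sample_indexes}
    for p in pairs:
        ill_sample = ill_lookup.get(tuple(p.illumina_pair))
        home_sample = home_lookup.get((p.seq1[:n], p.seq2[:n]))
        stripped = ReadPair(
            read_id=p.read_id,
            seq1=p.seq1[n:], qual1=p.qual1[n:],
            seq2=p.seq2[n:], qual2=p.qual2[n:],
            illumina_sample=ill_sample,
            home_sample=home_sample,
        )
        if ill_sample is None or home_sample is None:
            log.add(p.read_id, "demux", "unassigned")
        elif ill_sample != home_sample:
            log.add(p.read_id, "demux", "hop")
        else:
            out[ill_sample].append(stripped)
    return out, log


def _kmer_set(seq: str, k: int) -> set[str]:
    rc = revcomp(seq)
    return {seq[i : i + k] for i in range(len(seq) - k + 1)} | {
        rc[i : i + k] for i in range(len(rc) - k + 1)
    }


def filter_phix(
    pairs: Sequence[ReadPair],
    decoy: str,
    k: int = 31,
    min_kmer_hits: int = 1,
    log: DiscardLog | None = None,
) -> tuple[list[ReadPair], DiscardLog]:
    """Remove pairs sharing exact k-mers with the decoy sequence (either strand)."""
    if k < 21:
        raise ValueError("k must be >= 21 for specific decoy screening")
    if log is None:
        log = DiscardLog()
    decoy_kmers = _kmer_set(decoy.upper(), k)
    kept: list[ReadPair] = []
    for p in pairs:
        removed = False
        for seq in (p.seq1, p.seq2):
            hits = sum(1 for i in range(len(seq) - k + 1) if seq[i : i + k] in decoy_kmers)
            if hits >= min_kmer_hits:
                removed = True
                break
        if removed:
            log.add(p.read_id, "phix", "decoy_kmer")
        else:
            kept.append(p)
    return kept, log


def merge_pairs(
    pair: ReadPair,
    min_overlap: int = 10,
    max_mismatch_frac: float = 0.1,
) -> MergedRead:
    """Merge a read pair by 3' overlap, or return an unmerged carrier.

    Offsets are scanned from largest overlap down; the first offset whose
    overlap has a mismatch fraction within the ceiling wins. Consensus at a
    mismatch takes the higher-quality base; consensus quality is the maximum.
    """
    if not pair.seq1 or not pair.seq2:
        raise ValueError(f"read {pair.read_id}: empty mate")
    s1, q1 = pair.seq1, pair.qual1
    s2 = revcomp(pair.seq2)
    q2 = pair.qual2[::-1]
    l1, l2 = len(s1), len(s2)
    for offset in range(0, l1 - min_overlap + 1):
        olen = min(l1 - offset, l2)
        if olen < min_overlap:
            break
        mism = sum(1 for a, b in zip(s1[offset : offset + olen], s2[:olen]) if a != b)
        if mism <= max_mismatch_frac * olen:
            cons: list[str] = []
            consq: list[str] = []
            for i in range(olen):
                a, b = s1[offset + i], s2[i]
                qa, qb = q1[offset + i], q2[i]
                if a == b or qa >= qb:
                    cons.append(a)
                else:
                    cons.append(b)
                consq.append(max(qa, qb))
            seq = s1[:offset] + "".join(cons) + s2[olen:]
            qual = q1[:offset] + "".join(consq) + q2[olen:]
            return MergedRead(pair.read_id, seq, qual, True, pair)
    return MergedRead(pair.read_id, "", "", False, pair)


def phred_scores(qual: str) -> list[int]:
    scores = []
    for ch in qual:
        q = ord(ch) - 33
        if not 0 <= q <= 93:
            raise ValueError(f"quality symbol {ch!r} outside the printable Phred+33 range")
        scores.append(q)
    return scores


def quality_filter(
    qual: str,
    locus_intervals: Sequence[tuple[int, int]],
    q_locus: float = 25.0,
    q_rest: float = 15.0,
) -> bool:
    """Keep iff mean Q over locus-aligned bases >= q_locus and over the rest >= q_rest.

    ``locus_intervals`` are half-open intervals of the read covered by its
    alignment to the amplicon flanks. Thresholds are inclusive. A read with no
    non-locus bases is judged on the locus mean alone (and vice versa).
    """
    scores = phred_scores(qual)
    in_locus = [False] * len(scores)
    for s, e in locus_intervals:
        for i in range(max(0, s), min(len(scores), e)):
            in_locus[i] = True
    locus = [q for q, f in zip(scores, in_locus) if f]
    rest = [q for q, f in zip(scores, in_locus) if not f]
    if locus and sum(locus) / len(locus) < q_locus:
        return False
    if rest and sum(rest) / len(rest) < q_rest:
        return False
    return True
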