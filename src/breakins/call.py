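"""Detection of candidate insertion events at the break point.

A merged read carries an insertion when its alignments to the left and right
amplicon flanks leave an unaligned gap of at least 10 bp between them that
spans the cut position. Junction boundaries are canonicalized by maximizing
the locus alignment first: terminal mismatching columns of each flank
alignment are trimmed back, then the boundary is extended by exact matching.
Microhomology makes boundaries ambiguous; this convention pushes the insert
boundaries inward and the annotation stage recovers the shared bases from the
donor context, so they are never counted twice.

Pairs that fail merging can still reveal an insertion when both mates align to
their flank at the 5' end and the two 3' insertion portions map to the same
reference sequence at loci 10 bp to 3 kb apart (inner-edge distance). Such
events carry a length lower bound, not a length, and are excluded from size
histograms.

The inserted sequence is segmented into ordered donor fragments by a greedy
cover: repeatedly take the alignment hit covering the largest uncovered
proportion of the insert, trim overlaps between adjacent chosen hits at the
overlap midpoint, and stop when less than 10 bp remains uncoverable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from breakins.align import AlignmentHit, align_query
from breakins.model import AmpliconDesign, ReferenceGenome
from breakins.preprocess import MergedRead, ReadPair, phred_scores

MIN_INSERT_LEN = 10
UNMERGED_MIN_SEP = 10
UNMERGED_MAX_SEP = 3_000
UNMERGED_GAP_MARKER = "N" * 10
MIN_SEGMENT_LEN = 10


@dataclass
class DonorSegment:
    """One aligned donor interval of an insert."""

    subject: str
    start: int
    end: int
    strand: str
    insert_start: int
    insert_end: int
    percent_identity: float = 100.0
    source_class: str | None = None

    @property
    def span(self) -> int:
        return self.insert_end - self.insert_start


@dataclass
class InsertionEvent:
    """One read-pair-supported candidate insertion (>= 10 bp at the break)."""

    event_id: str
    sample_id: str
    left_junction: int          # amplicon offset where locus alignment ends
    right_junction: int         # amplicon offset where locus alignment resumes
    insert_seq: str
    segments: list[DonorSegment] = field(default_factory=list)
    read_seq: str = ""
    batch_id: str = "batch1"
    read_support: int = 1
    copies: int = 1             # identical read copies collapsed into this event
    mergeable: bool = True
    quality: float = 0.0
    length_lower_bound: bool = False
    unmapped: bool = False

    @property
    def n_donors(self) -> int:
        return len(self.segments)

    @property
    def insert_len(self) -> int:
        return len(self.insert_seq)


_MATCH, _MISMATCH = 2, -3
_MIN_FLANK_SCORE = 20


def _left_boundary(read: str, amplicon: str) -> tuple[int, float]:
    """Locus-maximizing left flank boundary by diagonal scoring from the start.

    The amplicon prefix up to the left junction aligns to the read prefix on
    the main diagonal (amplicon products start at the amplicon start), so the
    boundary is the prefix position maximizing the cumulative match/mismatch
    score. Returns (boundary, best score); boundary is both the read offset
    where the locus alignment ends and the amplicon offset of the junction.
    """
    best, best_i, score = 0.0, 0, 0.0
    for i in range(min(len(read), len(amplicon))):
        score += _MATCH if read[i] == amplicon[i] else _MISMATCH
        if score > best:
            best, best_i = score, i + 1
    return best_i, best


def _right_boundary(read: str, amplicon: str) -> tuple[int, float]:
    """Symmetric suffix-diagonal boundary: returns (k, score) where the locus
    alignment covers the last k bases of both read and amplicon."""
    best, best_k, score = 0.0, 0, 0.0
    for k in range(1, min(len(read), len(amplicon)) + 1):
        score += _MATCH if read[-k] == amplicon[-k] else _MISMATCH
        if score > best:
            best, best_k = score, k
    return best_k, best


def locus_intervals_of_read(read: str, amplicon: str) -> list[tuple[int, int]]:
    """Read intervals covered by the flank alignments (for region-aware filtering)."""
    out = []
    qe, score_l = _left_boundary(read, amplicon)
    if score_l >= _MIN_FLANK_SCORE:
        out.append((0, qe))
    k, score_r = _right_boundary(read, amplicon)
    if score_r >= _MIN_FLANK_SCORE:
        out.append((len(read) - k, len(read)))
    return out


def call_merged(
    read: MergedRead,
    design: AmpliconDesign,
    genome: ReferenceGenome,
    sample_id: str = "",
) -> tuple[InsertionEvent | None, str]:
    """Call an insertion from a merged read; returns (event or None, reason).

    Reasons for None: ``unalignable`` (no flank alignment), ``not_at_break``
    (gap does not span the cut), ``rejoin`` (no unaligned gap),
    ``short_indel`` (gap below 10 bp).
    """
    amplicon = design.amplicon_seq(genome)
    qe, score_l = _left_boundary(read.seq, amplicon)
    k, score_r = _right_boundary(read.seq, amplicon)
    if score_l < _MIN_FLANK_SCORE or score_r < _MIN_FLANK_SCORE:
        return None, "unalignable"
    lj = qe
    qs = len(read.seq) - k
    rj = len(amplicon) - k
    if qs <= qe and lj >= rj:
        return None, "rejoin"
    insert = read.seq[qe:qs] if qs > qe else ""
    if not (lj <= design.break_point <= rj):
        return None, "not_at_break"
    if len(insert) < MIN_INSERT_LEN:
        return None, ("short_indel" if (insert or lj < rj) else "rejoin")
    scores = phred_scores(read.qual)
    event = InsertionEvent(
        event_id=read.read_id,
        sample_id=sample_id,
        left_junction=lj,
        right_junction=rj,
        insert_seq=insert,
        read_seq=read.seq,
        mergeable=True,
        quality=sum(scores) / len(scores) if scores else 0.0,
    )
    return event, "insertion"


def call_unmerged(
    pair: ReadPair,
    design: AmpliconDesign,
    genome: ReferenceGenome,
    sample_id: str = "",
) -> tuple[InsertionEvent | None, str]:
    """Call an insertion from an unmergeable pair.

    Each mate must align to its amplicon flank at the 5' end with an unaligned
    3' insertion portion; the two portions must map to the same reference
    sequence 10 bp - 3 kb apart. The insert is the two portions joined with an
    unknown-gap marker and its length is a lower bound only.
    """
    from breakins.model import revcomp

    amplicon = design.amplicon_seq(genome)
    s1 = pair.seq1
    rc2 = revcomp(pair.seq2)
    qe1, score_l = _left_boundary(s1, amplicon)
    k2, score_r = _right_boundary(rc2, amplicon)
    if score_l < _MIN_FLANK_SCORE or score_r < _MIN_FLANK_SCORE:
        return None, "unalignable"
    lj = qe1
    qs2 = len(rc2) - k2
    rj = len(amplicon) - k2
    portion1 = s1[qe1:]
    portion2 = rc2[:qs2]
    if len(portion1) < MIN_INSERT_LEN or len(portion2) < MIN_INSERT_LEN:
        return None, "short_portion"
    if not (lj <= design.break_point <= rj):
        return None, "not_at_break"

    def top_hit(portion: str) -> AlignmentHit | None:
        hits = align_query(portion, genome, "standard")
        if not hits:
            hits = align_query(portion, genome, "short")
        return hits[0] if hits else None

    h1, h2 = top_hit(portion1), top_hit(portion2)
    if h1 is None or h2 is None:
        return None, "portion_unmapped"
    if h1.subject_name != h2.subject_name:
        return None, "different_sequences"
    if h2.subject_start >= h1.subject_end:
        sep = h2.subject_start - h1.subject_end
    elif h1.subject_start >= h2.subject_end:
        sep = h1.subject_start - h2.subject_end
    else:
        sep = 0
    if sep < UNMERGED_MIN_SEP:
        return None, "donor_separation_below_min"
    if sep > UNMERGED_MAX_SEP:
        return None, "donor_separation_above_max"
    insert = portion1 + UNMERGED_GAP_MARKER + portion2
    lo = min(h1.subject_start, h2.subject_start)
    hi = max(h1.subject_end, h2.subject_end)
    seg = DonorSegment(
        subject=h1.subject_name, start=lo, end=hi, strand=h1.strand,
        insert_start=0, insert_end=len(insert),
        percent_identity=min(h1.percent_identity, h2.percent_identity),
    )
    scores = phred_scores(pair.qual1) + phred_scores(pair.qual2)
    event = InsertionEvent(
        event_id=pair.read_id,
        sample_id=sample_id,
        left_junction=lj,
        right_junction=rj,
        insert_seq=insert,
        segments=[seg],
        read_seq=s1 + UNMERGED_GAP_MARKER + rc2,
        mergeable=False,
        quality=sum(scores) / len(scores),
        length_lower_bound=True,
    )
    return event, "insertion"


def _uncovered_overlap(hit: AlignmentHit, covered: list[bool]) -> int:
    return sum(1 for i in range(hit.query_start, hit.query_end) if not covered[i])


def segment_donors(
    event: InsertionEvent,
    genome: ReferenceGenome,
) -> InsertionEvent:
    """Segment the insert into ordered donor fragments by greedy cover.

    Standard-preset hits are used first; when none exist the short preset is
    the fallback. An insert with no hits in either preset is retained with
    zero donors and flagged unmapped.
    """
    if event.length_lower_bound:
        return event  # unmerged events already carry their bounding segment
    insert = event.insert_seq
    hits = align_query(insert, genome, "standard", query_id=event.event_id)
    if not hits:
        try:
            hits = align_query(insert, genome, "short", query_id=event.event_id)
        except ValueError:
            hits = []
    if not hits:
        event.segments = []
        event.unmapped = True
        return event

    covered = [False] * len(insert)
    chosen: list[AlignmentHit] = []
    remaining = list(hits)
    while remaining:
        # contribution of a hit = its score prorated to the still-uncovered
        # part of its span; among equal-identity alternatives this reduces to
        # the largest covered proportion of the insert
        scored = [(_uncovered_overlap(h, covered), h) for h in remaining]
        scored.sort(key=lambda t: (
            -(t[1].score * t[0] / max(1, t[1].query_span)), -t[0],
            -t[1].percent_identity,
            t[1].subject_name, t[1].subject_start, t[1].strand, t[1].query_start,
        ))
        best_cov, best = scored[0]
        if best_cov < MIN_SEGMENT_LEN:
            break
        chosen.append(best)
        for i in range(best.query_start, best.query_end):
            covered[i] = True
        remaining = [h for h in remaining if h is not best]
        if sum(1 for c in covered if not c) < MIN_SEGMENT_LEN:
            break

    if not chosen:
        event.segments = []
        event.unmapped = True
        return event

    chosen.sort(key=lambda h: h.query_start)
    segs: list[DonorSegment] = []
    for h in chosen:
        segs.append(DonorSegment(
            subject=h.subject_name, start=h.subject_start, end=h.subject_end,
            strand=h.strand, insert_start=h.query_start, insert_end=h.query_end,
            percent_identity=h.percent_identity,
        ))
    # trim overlaps between adjacent chosen segments at the overlap midpoint
    for a, b in zip(segs, segs[1:]):
        if a.insert_end > b.insert_start:
            overlap = a.insert_end - b.insert_start
            trim_a = overlap // 2
            trim_b = overlap - trim_a
            a.insert_end -= trim_a
            if a.strand == "+":
                a.end -= trim_a
            else:
                a.start += trim_a
            b.insert_start += trim_b
            if b.strand == "+":
                b.start += trim_b
            else:
                b.end -= trim_b
    event.segments = [s for s in segs if s.span >= 1]
    event.unmapped = False
    return event
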