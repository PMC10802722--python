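"""Junction profiling, donor source classes, Ty1 realignment, frequency tracks.

Junctions of a unique insertion are characterized by three quantities per
side: trimming (locus bases missing relative to the intact amplicon),
untemplated extra nucleotides (insert bases not assigned to any donor and not
explainable by the donor neighborhood), and microhomology (the longest
sequence perfectly shared by the locus flank terminal and the donor context
beyond its chosen boundary). Because junction calling maximizes the locus
alignment first, microhomology bases sit inside the locus alignment and are
recovered here from the donor context — never counted as both locus and donor.
A junction with untemplated bases has microhomology 0 by definition (the
perfect-match definition precludes coexistence at one boundary).

Ty-classed inserts are realigned onto one canonical Ty1 element with the
permissive preset; when an insert maps perfectly to both identical terminal
repeats, the right LTR alignment is reported.

Frequency tracks count, for every donor-subject position i, the number of
unique insertions covering it (n_t,i). Per-position insertion frequency is
reported per 100,000 independent NHEJ products as 1e5 * n_t,i / n_colonies
and the percentage among all insertions of that subject as
100 * n_t,i / n_t,total.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from breakins.align import align_query
from breakins.call import DonorSegment, InsertionEvent
from breakins.model import AmpliconDesign, ReferenceGenome, intervals_overlap, revcomp

log = logging.getLogger(__name__)

#: how far around the chosen donor boundary insert bases may still be
#: explained by the donor ("near the original donor location")
DONOR_NEIGHBORHOOD_BP = 20

MH_CAP = 10


@dataclass
class JunctionProfile:
    trim_left: int
    trim_right: int
    extra_left: int
    extra_right: int
    mh_left: int
    mh_right: int


@dataclass
class FrequencyTrack:
    """Per-position insertion counts over one donor subject."""

    subject: str
    n_t: np.ndarray
    n_colonies: int

    @property
    def n_t_total(self) -> int:
        return int(self.n_t.sum())

    def frequency_per_1e5(self) -> np.ndarray:
        return 1e5 * self.n_t / self.n_colonies

    def percentage(self) -> np.ndarray:
        total = self.n_t_total
        if total == 0:
            log.warning("frequency track %s has no insertions; percentage all zero", self.subject)
            return np.zeros_like(self.n_t, dtype=float)
        return 100.0 * self.n_t / total


def _oriented_left_context(genome: ReferenceGenome, seg: DonorSegment, k: int) -> str:
    """k bases preceding the segment start, in insert orientation."""
    seq = genome.sequences[seg.subject]
    if seg.strand == "+":
        return seq[max(0, seg.start - k) : seg.start]
    return revcomp(seq[seg.end : seg.end + k])


def _oriented_right_context(genome: ReferenceGenome, seg: DonorSegment, k: int) -> str:
    """k bases following the segment end, in insert orientation."""
    seq = genome.sequences[seg.subject]
    if seg.strand == "+":
        return seq[seg.end : seg.end + k]
    return revcomp(seq[max(0, seg.start - k) : seg.start])


def compute_trimming(
    event: InsertionEvent,
    design: AmpliconDesign,
    genome: ReferenceGenome,
) -> tuple[int, int, int, int]:
    """(trim_left, trim_right, extra_left, extra_right) of a unique insertion.

    Trimming is the distance between the break point and the locus-alignment
    boundary on each side. Extra nucleotides are insert bases outside every
    donor segment span that also cannot be explained by extending the adjacent
    donor boundary within its neighborhood.
    """
    trim_left = design.break_point - event.left_junction
    trim_right = event.right_junction - design.break_point
    if not event.segments:
        return trim_left, trim_right, len(event.insert_seq), 0
    first, last = event.segments[0], event.segments[-1]
    extra_left = first.insert_start
    extra_right = len(event.insert_seq) - last.insert_end
    # absorb leading/trailing bases contiguously explained by the donor context
    if extra_left:
        ctx = _oriented_left_context(genome, first, min(extra_left, DONOR_NEIGHBORHOOD_BP))
        lead = event.insert_seq[:first.insert_start]
        while extra_left and ctx and lead[-1] == ctx[-1]:
            extra_left -= 1
            lead, ctx = lead[:-1], ctx[:-1]
    if extra_right:
        ctx = _oriented_right_context(genome, last, min(extra_right, DONOR_NEIGHBORHOOD_BP))
        tail = event.insert_seq[last.insert_end:]
        while extra_right and ctx and tail[0] == ctx[0]:
            extra_right -= 1
            tail, ctx = tail[1:], ctx[1:]
    return trim_left, trim_right, extra_left, extra_right


def compute_microhomology(
    event: InsertionEvent,
    design: AmpliconDesign,
    genome: ReferenceGenome,
    cap: int = MH_CAP,
) -> tuple[int, int]:
    """Microhomology lengths (left, right) of a unique insertion's junctions.

    mh_left is the longest string that is simultaneously a terminal extension
    of the locus flank at the left junction and of the first donor segment
    beyond its chosen boundary (perfect match both ways); symmetric on the
    right. A side with untemplated extra bases reports 0.
    """
    if not event.segments:
        return 0, 0
    amplicon = design.amplicon_seq(genome)
    first, last = event.segments[0], event.segments[-1]
    mh_left = 0
    if first.insert_start == 0:  # donor abuts the left junction
        flank = amplicon[: event.left_junction]
        ctx = _oriented_left_context(genome, first, cap)
        m = 0
        while m < cap and m < len(flank) and m < len(ctx) and flank[-1 - m] == ctx[-1 - m]:
            m += 1
        mh_left = m
    mh_right = 0
    if last.insert_end == len(event.insert_seq):
        flank = amplicon[event.right_junction : event.right_junction + cap]
        ctx = _oriented_right_context(genome, last, cap)
        m = 0
        while m < cap and m < len(flank) and m < len(ctx) and flank[m] == ctx[m]:
            m += 1
        mh_right = m
    return mh_left, mh_right


def junction_profile(
    event: InsertionEvent, design: AmpliconDesign, genome: ReferenceGenome
) -> JunctionProfile:
    t_l, t_r, x_l, x_r = compute_trimming(event, design, genome)
    mh_l, mh_r = compute_microhomology(event, design, genome)
    return JunctionProfile(t_l, t_r, x_l, x_r, mh_l, mh_r)


def classify_source(
    segment: DonorSegment,
    genome: ReferenceGenome,
    design: AmpliconDesign | None = None,
) -> str:
    """Donor source class of one mapped segment (total: exactly one class).

    Precedence: mtDNA and 2-micron by subject class; Ty then rDNA by >= 1 bp
    overlap with their annotation intervals; the break locus by overlap with
    the amplicon; nuclear otherwise. A donor hitting a solo LTR interval is
    classed Ty.
    """
    subject_class = genome.source_class_map.get(segment.subject, "nuclear")
    if subject_class in ("mtDNA", "plasmid_2micron", "Ty", "rDNA", "locus"):
        return subject_class
    for cls in ("Ty", "rDNA"):
        for seq_name, s, e in genome.class_intervals.get(cls, []):
            if seq_name == segment.subject and intervals_overlap(segment.start, segment.end, s, e):
                return cls
    if (
        design is not None
        and segment.subject == design.locus_name
        and intervals_overlap(segment.start, segment.end, design.amplicon_start, design.amplicon_end)
    ):
        return "locus"
    return "nuclear"


def annotate_sources(
    event: InsertionEvent, genome: ReferenceGenome, design: AmpliconDesign | None = None
) -> InsertionEvent:
    for seg in event.segments:
        seg.source_class = classify_source(seg, genome, design)
    return event


def ty1_realign(
    event: InsertionEvent,
    ty1_ref: ReferenceGenome,
    min_identity: float = 60.0,
) -> list[DonorSegment]:
    """Recoordinate the event's Ty-classed segments onto the canonical element.

    Each segment's insert sequence is realigned with the permissive preset;
    among alternatives the largest insert coverage wins, and perfect ties
    (identical terminal repeats) resolve to the rightmost subject position —
    the right LTR. Segments with no acceptable realignment are returned with
    their genomic coordinates and flagged by ``source_class`` left unchanged.
    """
    out: list[DonorSegment] = []
    ty_name = next(iter(ty1_ref.sequences))
    for seg in event.segments:
        if seg.source_class != "Ty":
            out.append(seg)
            continue
        piece = event.insert_seq[seg.insert_start : seg.insert_end]
        try:
            hits = align_query(piece, ty1_ref, "ty-loose")
        except ValueError:
            hits = []
        hits = [h for h in hits if h.percent_identity >= min_identity]
        if not hits:
            log.warning("Ty segment of %s has no realignment at >= %.0f%% identity",
                        event.event_id, min_identity)
            out.append(seg)
            continue
        best_cov = max(h.query_end - h.query_start for h in hits)
        candidates = [h for h in hits if h.query_end - h.query_start == best_cov]
        # perfect ties between the two LTRs resolve to the right LTR
        candidates.sort(key=lambda h: (-h.score, -h.subject_start, h.strand))
        h = candidates[0]
        out.append(
            DonorSegment(
                subject=ty_name,
                start=h.subject_start,
                end=h.subject_end,
                strand=h.strand,
                insert_start=seg.insert_start + h.query_start,
                insert_end=seg.insert_start + h.query_end,
                percent_identity=h.percent_identity,
                source_class="Ty",
            )
        )
    return out


def nucleotide_frequency(
    events: list[InsertionEvent],
    subject: str,
    subject_len: int,
    n_colonies: int,
    include_multi_donor: bool = False,
) -> FrequencyTrack:
    """Per-position insertion counts over ``subject`` from unique insertions.

    Every qualifying segment of every event increments n_t over the subject
    positions it covers. By default only single-donor insertions contribute;
    ``include_multi_donor`` adds each donor of complex events.
    """
    if n_colonies <= 0:
        raise ValueError("n_colonies must be positive")
    n_t = np.zeros(subject_len, dtype=np.int64)
    for ev in events:
        if not include_multi_donor and ev.n_donors != 1:
            continue
        for seg in ev.segments:
            if seg.subject == subject:
                n_t[seg.start : seg.end] += 1
    return FrequencyTrack(subject=subject, n_t=n_t, n_colonies=n_colonies)
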