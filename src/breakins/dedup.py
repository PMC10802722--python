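"""Collapse candidate events into unique insertions without UMIs.

Four rules applied in order, each followed by transitive closure (union-find):

1. **Junction rule** — two events are duplicates when the global alignment of
   their combined junction keys (11 bp of locus + 19 bp of insert at each
   junction, 60 bp at defaults) has identity >= 95%, coverage >= 95% and at
   most 6 bp of mismatches plus indels, all three conjunctively (over a 60 bp
   key the identity condition is the strictest and binds).
2. **Location rule** — events with the same donor count and 1:1-pairable
   donors (same subject and strand, in insert-span order) are duplicates when
   the locus-side boundary distance sum is <= 6 bp (single donor) or <= 10 bp
   (multi-donor) and the donor-side sum likewise.
3. **Long-form rule** — among clusters with fewer than 10 read pairs and more
   than 300 bp of locus-plus-donor sequence, any two whose full event
   sequences align at > 80% identity (strict) merge.
4. **Contamination rule** — a cluster with <= 10 read pairs in one sample is
   discarded when a junction-duplicate cluster in another sample of the same
   batch has > 500 read pairs.

The pairwise relations are completed to equivalences by transitive closure,
which makes the partition independent of event input order. One representative
read pair is selected per unique insertion: mergeable pairs first, then higher
mean sequencing quality, then more identical copies, with the event id as the
final determinism tie-break.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import edlib

from breakins.call import InsertionEvent


@dataclass(frozen=True)
class DedupThresholds:
    jkey_identity: float = 0.95
    jkey_coverage: float = 0.95
    jkey_maxdiff: int = 6
    loc_sum_single: int = 6
    loc_sum_multi: int = 10
    long_identity: float = 0.80
    long_minlen: int = 300
    long_maxreads: int = 10
    contam_low: int = 10
    contam_high: int = 500


@dataclass
class InsertionCluster:
    """A unique insertion after deduplication."""

    cluster_id: str
    members: list[InsertionEvent]
    representative: InsertionEvent
    sample_id: str
    batch_id: str
    unique: bool = True

    @property
    def read_support(self) -> int:
        return sum(ev.copies for ev in self.members)


def junction_key(event: InsertionEvent, amplicon: str, locus_bp: int = 11, donor_bp: int = 19) -> str:
    """Combined junction key: locus flank + insert start, insert end + locus flank.

    Inserts shorter than the donor flank contribute their whole sequence,
    giving a shorter, pad-free key.
    """
    lj, rj = event.left_junction, event.right_junction
    ins = event.insert_seq
    left = amplicon[max(0, lj - locus_bp) : lj] + ins[:donor_bp]
    right = ins[-donor_bp:] + amplicon[rj : rj + locus_bp]
    return left + right


def keys_are_duplicates(key_a: str, key_b: str, th: DedupThresholds) -> bool:
    """Junction-rule predicate on two combined keys (global alignment)."""
    if not key_a or not key_b:
        return False
    if key_a == key_b:
        return True
    dist = edlib.align(key_a, key_b, task="distance")["editDistance"]
    longer = max(len(key_a), len(key_b))
    identity = 1.0 - dist / longer
    coverage = min(len(key_a), len(key_b)) / longer
    return (
        identity >= th.jkey_identity
        and coverage >= th.jkey_coverage
        and dist <= th.jkey_maxdiff
    )


def location_distances(a: InsertionEvent, b: InsertionEvent) -> tuple[int, int] | None:
    """(locus-side sum, donor-side sum) of boundary distances, or None if unpairable.

    Donors are paired 1:1 in insert-span order and must match by subject and
    strand. The locus-side sum is |d left-junction| + |d right-junction| plus
    the insert-span coordinate differences at internal donor boundaries; the
    donor-side sum adds |d start| + |d end| over every paired donor. For a
    single donor this reduces to the d_1a + d_1b / d_1c + d_1d rule.
    """
    if a.n_donors != b.n_donors or a.n_donors == 0:
        return None
    for sa, sb in zip(a.segments, b.segments):
        if sa.subject != sb.subject or sa.strand != sb.strand:
            return None
    locus_sum = abs(a.left_junction - b.left_junction) + abs(a.right_junction - b.right_junction)
    for sa, sb in zip(a.segments[:-1], b.segments[:-1]):
        locus_sum += abs(sa.insert_end - sb.insert_end)
    for sa, sb in zip(a.segments[1:], b.segments[1:]):
        locus_sum += abs(sa.insert_start - sb.insert_start)
    donor_sum = 0
    for sa, sb in zip(a.segments, b.segments):
        donor_sum += abs(sa.start - sb.start) + abs(sa.end - sb.end)
    return locus_sum, donor_sum


def locations_are_duplicates(a: InsertionEvent, b: InsertionEvent, th: DedupThresholds) -> bool:
    d = location_distances(a, b)
    if d is None:
        return False
    locus_sum, donor_sum = d
    bound = th.loc_sum_single if a.n_donors == 1 else th.loc_sum_multi
    return locus_sum <= bound and donor_sum <= bound


def longform_eligible(cluster_events: list[InsertionEvent], rep: InsertionEvent, th: DedupThresholds) -> bool:
    support = sum(ev.copies for ev in cluster_events)
    return support < th.long_maxreads and len(rep.read_seq) > th.long_minlen


def longform_are_duplicates(a: InsertionEvent, b: InsertionEvent, th: DedupThresholds) -> bool:
    if not a.read_seq or not b.read_seq:
        return False
    dist = edlib.align(a.read_seq, b.read_seq, task="distance")["editDistance"]
    identity = 1.0 - dist / max(len(a.read_seq), len(b.read_seq))
    return identity > th.long_identity  # strictly greater


def select_representative(members: list[InsertionEvent]) -> InsertionEvent:
    """Priority: mergeable, then mean quality, then identical copies, then id."""
    return sorted(
        members,
        key=lambda ev: (not ev.mergeable, -ev.quality, -ev.copies, ev.event_id),
    )[0]


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            # canonical root: smaller index, for order-independence
            if ri < rj:
                self.parent[rj] = ri
            else:
                self.parent[ri] = rj

    def groups(self) -> dict[int, list[int]]:
        out: dict[int, list[int]] = {}
        for i in range(len(self.parent)):
            out.setdefault(self.find(i), []).append(i)
        return out


def dedup_events(
    events: list[InsertionEvent],
    amplicon: str,
    batch_map: dict[str, str] | None = None,
    thresholds: DedupThresholds | None = None,
    locus_bp: int = 11,
    donor_bp: int = 19,
) -> tuple[list[InsertionCluster], list[InsertionCluster]]:
    """Run the full four-rule stack; returns (unique clusters, discarded contaminants).

    Rules 1-3 operate within a sample; the contamination rule compares samples
    of the same batch. The result is canonically ordered and independent of
    the input order of ``events``.
    """
    th = thresholds or DedupThresholds()
    if batch_map is None:
        batch_map = {}
    events = sorted(events, key=lambda ev: ev.event_id)
    n = len(events)
    keys = [junction_key(ev, amplicon, locus_bp, donor_bp) for ev in events]
    uf = _UnionFind(n)
    by_sample: dict[str, list[int]] = {}
    for i, ev in enumerate(events):
        by_sample.setdefault(ev.sample_id, []).append(i)

    # rule 1: junction keys
    for idxs in by_sample.values():
        for ai in range(len(idxs)):
            for bi in range(ai + 1, len(idxs)):
                i, j = idxs[ai], idxs[bi]
                if keys_are_duplicates(keys[i], keys[j], th):
                    uf.union(i, j)
    # rule 2: donor locations
    for idxs in by_sample.values():
        for ai in range(len(idxs)):
            for bi in range(ai + 1, len(idxs)):
                i, j = idxs[ai], idxs[bi]
                if uf.find(i) != uf.find(j) and locations_are_duplicates(events[i], events[j], th):
                    uf.union(i, j)
    # rule 3: long low-support clusters at > 80% full-sequence identity
    groups = uf.groups()
    eligible: list[tuple[int, InsertionEvent]] = []
    for root, idxs in groups.items():
        members = [events[i] for i in idxs]
        rep = select_representative(members)
        if longform_eligible(members, rep, th):
            eligible.append((root, rep))
    for ai in range(len(eligible)):
        for bi in range(ai + 1, len(eligible)):
            (ra, reva), (rb, revb) = eligible[ai], eligible[bi]
            if reva.sample_id != revb.sample_id:
                continue
            if longform_are_duplicates(reva, revb, th):
                uf.union(ra, rb)

    # build clusters
    clusters: list[InsertionCluster] = []
    for root, idxs in sorted(uf.groups().items()):
        members = [events[i] for i in idxs]
        rep = select_representative(members)
        clusters.append(
            InsertionCluster(
                cluster_id=f"cl_{rep.event_id}",
                members=members,
                representative=rep,
                sample_id=rep.sample_id,
                batch_id=batch_map.get(rep.sample_id, "batch1"),
            )
        )

    # rule 4: cross-sample contamination within a batch
    contaminants: list[InsertionCluster] = []
    kept: list[InsertionCluster] = []
    rep_keys = {c.cluster_id: junction_key(c.representative, amplicon, locus_bp, donor_bp) for c in clusters}
    for c in clusters:
        discarded = False
        if c.read_support <= th.contam_low:
            for other in clusters:
                if other is c or other.sample_id == c.sample_id:
                    continue
                if other.batch_id != c.batch_id:
                    continue
                if other.read_support > th.contam_high and keys_are_duplicates(
                    rep_keys[c.cluster_id], rep_keys[other.cluster_id], th
                ):
                    discarded = True
                    break
        if discarded:
            c.unique = False
            contaminants.append(c)
        else:
            kept.append(c)
    return kept, contaminants
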