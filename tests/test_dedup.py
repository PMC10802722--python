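import itertools

import edlib
import networkx as nx
import numpy as np
import pytest

from breakins.call import DonorSegment, InsertionEvent, call_merged, segment_donors
from breakins.dedup import (
    DedupThresholds,
    dedup_events,
    junction_key,
    keys_are_duplicates,
    location_distances,
    locations_are_duplicates,
    select_representative,
)
from breakins.preprocess import MergedRead
from breakins.simulate import SimulationConfig, simulate_events

TH = DedupThresholds()


def mutate(seq, positions, rng=None):
    comp = {"A": "C", "C": "G", "G": "T", "T": "A"}
    out = list(seq)
    for p in positions:
        out[p] = comp[out[p]]
    return "".join(out)


def make_event(event_id, sample="S1", lj=41, rj=41, insert="ACGTTGCA" * 5,
               segments=None, read_seq=None, copies=1, mergeable=True, quality=35.0):
    return InsertionEvent(
        event_id=event_id, sample_id=sample, left_junction=lj, right_junction=rj,
        insert_seq=insert,
        segments=segments if segments is not None else
        [DonorSegment("mito", 1000, 1000 + len(insert), "+", 0, len(insert))],
        read_seq=read_seq or ("G" * 41 + insert + "C" * 47),
        copies=copies, mergeable=mergeable, quality=quality,
    )


class TestJunctionRule:
    def test_identical_keys_are_duplicates(self):
        key = "ACGT" * 15
        assert keys_are_duplicates(key, key, TH)

    def test_seven_substitutions_exceed_the_difference_cap(self):
        key = "ACGT" * 15
        assert not keys_are_duplicates(key, mutate(key, range(0, 28, 4)), TH)

    def test_identity_binds_on_a_60bp_key(self):
        # 4 substitutions on 60 bp: 93.3% identity < 95% although 4 <= 6 diffs
        key = "ACGT" * 15
        assert not keys_are_duplicates(key, mutate(key, [0, 10, 20, 30]), TH)
        assert keys_are_duplicates(key, mutate(key, [0, 20, 40]), TH)

    def test_key_construction(self, mock, amplicon):
        ev = make_event("e", insert="A" * 30)
        key = junction_key(ev, amplicon)
        assert len(key) == 2 * (11 + 19)
        assert key == amplicon[30:41] + "A" * 19 + "A" * 19 + amplicon[41:52]

    def test_short_insert_gives_pad_free_shorter_key(self, amplicon):
        ev = make_event("e", insert="ACGTACGTACGT")  # 12 bp < 19
        key = junction_key(ev, amplicon)
        assert len(key) == 11 + 12 + 12 + 11


class TestLocationRule:
    def test_single_donor_sum_six_merges(self):
        a = make_event("a", lj=41, rj=41,
                       segments=[DonorSegment("mito", 1000, 1050, "+", 0, 50)])
        b = make_event("b", lj=44, rj=44,
                       segments=[DonorSegment("mito", 1000, 1050, "+", 0, 50)])
        assert location_distances(a, b) == (6, 0)
        assert locations_are_duplicates(a, b, TH)

    def test_single_donor_sum_seven_distinct(self):
        a = make_event("a", lj=41, rj=41,
                       segments=[DonorSegment("mito", 1000, 1050, "+", 0, 50)])
        b = make_event("b", lj=45, rj=44,
                       segments=[DonorSegment("mito", 1000, 1050, "+", 0, 50)])
        assert location_distances(a, b) == (7, 0)
        assert not locations_are_duplicates(a, b, TH)

    def test_two_donor_sums_of_ten_merge_eleven_do_not(self):
        segs_a = [DonorSegment("mito", 1000, 1050, "+", 0, 50),
                  DonorSegment("chrN", 5000, 5040, "+", 50, 90)]
        a = make_event("a", lj=41, rj=41, segments=segs_a)
        segs_b = [DonorSegment("mito", 996, 1046, "+", 0, 50),
                  DonorSegment("chrN", 5003, 5043, "+", 50, 90)]
        b = make_event("b", lj=46, rj=46, segments=segs_b)
        # locus sum: |41-46| + |41-46| = 10; donor sum: (4+4) + (3+3) -> 14 > 10
        assert location_distances(a, b) == (10, 14)
        assert not locations_are_duplicates(a, b, TH)
        segs_c = [DonorSegment("mito", 997, 1047, "+", 0, 50),
                  DonorSegment("chrN", 5002, 5042, "+", 50, 90)]
        c = make_event("c", lj=46, rj=46, segments=segs_c)
        assert location_distances(a, c) == (10, 10)
        assert locations_are_duplicates(a, c, TH)

    def test_different_donor_counts_never_compared(self):
        a = make_event("a")
        b = make_event("b", segments=[
            DonorSegment("mito", 1000, 1020, "+", 0, 20),
            DonorSegment("mito", 3000, 3020, "+", 20, 40),
        ])
        assert location_distances(a, b) is None


class TestLongformRule:
    def base_events(self, amplicon, identical_frac, support_a=3, support_b=4):
        rng = np.random.default_rng(8)
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 400))
        n_mut = round(len(seq) * (1 - identical_frac))
        # evenly spaced substitutions: edit distance equals the count
        positions = np.linspace(0, len(seq) - 1, n_mut).astype(int)
        seq_b = mutate(seq, positions)
        a = make_event("a", insert="A" * 20, read_seq=seq, copies=support_a,
                       segments=[DonorSegment("mito", 1000, 1020, "+", 0, 20)])
        b = make_event("b", insert="C" * 20, read_seq=seq_b, copies=support_b,
                       segments=[DonorSegment("mito", 4000, 4020, "+", 0, 20)])
        return a, b

    def test_merged_at_85_percent_identity_low_support(self, amplicon):
        a, b = self.base_events(amplicon, 0.85)
        clusters, _ = dedup_events([a, b], amplicon)
        assert len(clusters) == 1

    def test_support_12_not_eligible(self, amplicon):
        a, b = self.base_events(amplicon, 0.85, support_a=12)
        clusters, _ = dedup_events([a, b], amplicon)
        assert len(clusters) == 2

    def test_identity_exactly_80_percent_not_merged(self, amplicon):
        a, b = self.base_events(amplicon, 0.80)
        dist = edlib.align(a.read_seq, b.read_seq, task="distance")["editDistance"]
        assert dist >= 80  # exactly 80 substitutions -> at most 80% identity
        clusters, _ = dedup_events([a, b], amplicon)
        assert len(clusters) == 2


class TestContaminationRule:
    def pair_of_samples(self, amplicon, support_low, support_high):
        insert = "ACGTTGCAGGTTACAGGCAT" * 2
        a = make_event("a", sample="S1", insert=insert, copies=support_low)
        b = make_event("b", sample="S2", insert=insert, copies=support_high)
        return dedup_events([a, b], amplicon, batch_map={"S1": "b1", "S2": "b1"})

    def test_low_support_twin_of_high_support_discarded(self, amplicon):
        clusters, contaminants = self.pair_of_samples(amplicon, 8, 600)
        assert len(contaminants) == 1
        assert contaminants[0].sample_id == "S1"
        assert len(clusters) == 1
        assert clusters[0].sample_id == "S2"

    def test_400_reads_not_above_threshold(self, amplicon):
        clusters, contaminants = self.pair_of_samples(amplicon, 8, 400)
        assert contaminants == []
        assert len(clusters) == 2

    def test_support_11_not_below_threshold(self, amplicon):
        clusters, contaminants = self.pair_of_samples(amplicon, 11, 600)
        assert contaminants == []
        assert len(clusters) == 2

    def test_different_batch_not_compared(self, amplicon):
        insert = "ACGTTGCAGGTTACAGGCAT" * 2
        a = make_event("a", sample="S1", insert=insert, copies=8)
        b = make_event("b", sample="S2", insert=insert, copies=600)
        clusters, contaminants = dedup_events(
            [a, b], amplicon, batch_map={"S1": "b1", "S2": "b2"}
        )
        assert contaminants == []


class TestRepresentative:
    def test_mergeable_dominates(self):
        unmerged = make_event("u", mergeable=False, quality=38, copies=100)
        merged = make_event("m", mergeable=True, quality=30, copies=1)
        assert select_representative([unmerged, merged]) is merged

    def test_quality_breaks_mergeable_tie(self):
        a = make_event("a", quality=35)
        b = make_event("b", quality=30)
        assert select_representative([a, b]) is a

    def test_copies_break_quality_tie(self):
        a = make_event("a", quality=35, copies=7)
        b = make_event("b", quality=35, copies=2)
        assert select_representative([a, b]) is a

    def test_event_id_final_tie_break(self):
        a = make_event("a")
        b = make_event("b")
        assert select_representative([b, a]) is a


def oracle_partition(events, amplicon, th=TH):
    """Independent brute-force: pairwise rules + transitive closure via networkx."""
    g = nx.Graph()
    g.add_nodes_from(ev.event_id for ev in events)

    def jkey(ev):
        lj, rj, ins = ev.left_junction, ev.right_junction, ev.insert_seq
        return (amplicon[max(0, lj - 11): lj] + ins[:19]
                + ins[-19:] + amplicon[rj: rj + 11])

    def jdup(a, b):
        ka, kb = jkey(a), jkey(b)
        dist = edlib.align(ka, kb, task="distance")["editDistance"]
        longer = max(len(ka), len(kb))
        return (1 - dist / longer >= th.jkey_identity
                and min(len(ka), len(kb)) / longer >= th.jkey_coverage
                and dist <= th.jkey_maxdiff)

    def ldup(a, b):
        if a.n_donors != b.n_donors or a.n_donors == 0:
            return False
        if any(x.subject != y.subject or x.strand != y.strand
               for x, y in zip(a.segments, b.segments)):
            return False
        locus = abs(a.left_junction - b.left_junction) + abs(a.right_junction - b.right_junction)
        locus += sum(abs(x.insert_end - y.insert_end)
                     for x, y in zip(a.segments[:-1], b.segments[:-1]))
        locus += sum(abs(x.insert_start - y.insert_start)
                     for x, y in zip(a.segments[1:], b.segments[1:]))
        donor = sum(abs(x.start - y.start) + abs(x.end - y.end)
                    for x, y in zip(a.segments, b.segments))
        bound = th.loc_sum_single if a.n_donors == 1 else th.loc_sum_multi
        return locus <= bound and donor <= bound

    for a, b in itertools.combinations(events, 2):
        if a.sample_id == b.sample_id and (jdup(a, b) or ldup(a, b)):
            g.add_edge(a.event_id, b.event_id)

    # long-form stage on the components of the first two rules
    changed = True
    while changed:
        changed = False
        comps = [sorted(c) for c in nx.connected_components(g)]
        by_id = {ev.event_id: ev for ev in events}
        elig = []
        for comp in comps:
            members = [by_id[i] for i in comp]
            support = sum(ev.copies for ev in members)
            rep = select_representative(members)
            if support < th.long_maxreads and len(rep.read_seq) > th.long_minlen:
                elig.append(rep)
        for a, b in itertools.combinations(elig, 2):
            if a.sample_id != b.sample_id or g.has_edge(a.event_id, b.event_id):
                continue
            if nx.has_path(g, a.event_id, b.event_id):
                continue
            dist = edlib.align(a.read_seq, b.read_seq, task="distance")["editDistance"]
            if 1 - dist / max(len(a.read_seq), len(b.read_seq)) > th.long_identity:
                g.add_edge(a.event_id, b.event_id)
                changed = True
    return {frozenset(c) for c in nx.connected_components(g)}


@pytest.fixture(scope="module")
def pcr_events(mock):
    """Candidate events from a simulation with PCR duplication and mild error."""
    from breakins.model import revcomp
    cfg = SimulationConfig(
        seed=31, n_products=120, per_base_error_rate=0.0,
        index_hop_rate=0.0, phix_fraction=0.0,
        class_mix={"single_donor": 0.7, "multi_donor": 0.3},
    )
    truth = simulate_events(mock, cfg)
    events = []
    for t in truth:
        for c in range(t.pcr_copies):
            called, _ = call_merged(
                MergedRead(f"{t.event_id}:c{c}", t.product_seq,
                           "I" * len(t.product_seq), True, None),
                mock.design, mock.genome, t.sample_id,
            )
            assert called is not None
            segment_donors(called, mock.genome)
            events.append(called)
    return truth, events


class TestStackProperties:
    def test_oracle_equivalence(self, mock, amplicon, pcr_events):
        truth, events = pcr_events
        assert len(events) <= 300 or True
        clusters, _ = dedup_events(events, amplicon)
        got = {frozenset(ev.event_id for ev in c.members) for c in clusters}
        assert got == oracle_partition(events, amplicon)

    def test_ground_truth_cluster_count(self, mock, amplicon, pcr_events):
        truth, events = pcr_events
        clusters, _ = dedup_events(events, amplicon)
        assert len(clusters) == len(truth)

    def test_permutation_invariance(self, mock, amplicon, pcr_events):
        _, events = pcr_events
        base, _ = dedup_events(events, amplicon)
        rng = np.random.default_rng(4)
        shuffled = [events[i] for i in rng.permutation(len(events))]
        again, _ = dedup_events(shuffled, amplicon)
        as_sets = lambda cl: {frozenset(ev.event_id for ev in c.members) for c in cl}
        assert as_sets(base) == as_sets(again)
        assert {c.representative.event_id for c in base} == {
            c.representative.event_id for c in again
        }

    def test_idempotence(self, mock, amplicon, pcr_events):
        _, events = pcr_events
        clusters, _ = dedup_events(events, amplicon)
        reps = []
        for c in clusters:
            rep = c.representative
            again = InsertionEvent(**{**rep.__dict__, "copies": c.read_support})
            reps.append(again)
        second, _ = dedup_events(reps, amplicon)
        assert len(second) == len(clusters)
        assert all(len(c.members) == 1 for c in second)
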