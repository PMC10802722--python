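import numpy as np
import pytest

from breakins.annotate import (
    FrequencyTrack,
    classify_source,
    compute_microhomology,
    compute_trimming,
    junction_profile,
    nucleotide_frequency,
    ty1_realign,
)
from breakins.call import DonorSegment, InsertionEvent, call_merged, segment_donors
from breakins.model import revcomp
from breakins.preprocess import MergedRead


def called_from_truth(mock, truth_event):
    ev, reason = call_merged(
        MergedRead(truth_event.event_id, truth_event.product_seq,
                   "I" * len(truth_event.product_seq), True, None),
        mock.design, mock.genome, truth_event.sample_id,
    )
    assert reason == "insertion"
    segment_donors(ev, mock.genome)
    return ev


class TestTrimming:
    def test_truth_trims_and_extras_recovered_exactly(self, mock, clean_dataset):
        _, events, _ = clean_dataset
        insertions = [e for e in events if e.event_class in ("single_donor", "multi_donor")]
        assert insertions
        for t in insertions:
            ev = called_from_truth(mock, t)
            t_l, t_r, x_l, x_r = compute_trimming(ev, mock.design, mock.genome)
            assert (t_l, t_r) == (t.trim_left, t.trim_right), t.event_id
            assert (x_l, x_r) == (len(t.extra_left), len(t.extra_right)), t.event_id

    def test_intact_flanks_give_zero(self, mock, clean_dataset):
        _, events, _ = clean_dataset
        t = next(e for e in events
                 if e.event_class == "single_donor" and e.trim_left == 0 and e.trim_right == 0)
        ev = called_from_truth(mock, t)
        trims = compute_trimming(ev, mock.design, mock.genome)[:2]
        assert trims == (0, 0)


class TestMicrohomology:
    def test_truth_microhomology_recovered(self, mock, clean_dataset):
        _, events, _ = clean_dataset
        insertions = [e for e in events if e.event_class in ("single_donor", "multi_donor")]
        for t in insertions:
            ev = called_from_truth(mock, t)
            mh = compute_microhomology(ev, mock.design, mock.genome)
            assert mh == (t.mh_left, t.mh_right), t.event_id

    def test_no_shared_terminal_base_gives_zero(self, mock, amplicon):
        # find a mito window whose context shares no terminal base with the flank
        mito = mock.genome.sequences["mito"]
        b = mock.design.break_point
        for s in range(2000, 2400):
            if mito[s - 1] != amplicon[b - 1] and mito[s + 60] != amplicon[b]:
                break
        ev = InsertionEvent("e", "S1", b, b, mito[s : s + 60],
                            segments=[DonorSegment("mito", s, s + 60, "+", 0, 60)])
        assert compute_microhomology(ev, mock.design, mock.genome) == (0, 0)

    def test_fuzz_equals_exhaustive_oracle(self, mock, amplicon):
        """500 random donor placements: caller equals enumeration of all overlaps."""
        rng = np.random.default_rng(44)
        b = mock.design.break_point
        genome = mock.genome
        names = ["mito", "chrN", "two_micron"]
        checked = 0
        while checked < 500:
            name = names[rng.integers(0, 3)]
            seq = genome.sequences[name]
            length = int(rng.integers(20, 120))
            s = int(rng.integers(15, len(seq) - length - 15))
            strand = "+" if rng.random() < 0.5 else "-"
            t_l = int(rng.integers(0, 6))
            t_r = int(rng.integers(0, 6))
            insert = genome.fetch(name, s, s + length, strand)
            ev = InsertionEvent(
                "e", "S1", b - t_l, b + t_r, insert,
                segments=[DonorSegment(name, s, s + length, strand, 0, length)],
            )
            got = compute_microhomology(ev, mock.design, mock.genome)
            # oracle: enumerate every overlap length directly
            if strand == "+":
                left_ctx, right_ctx = seq[s - 10 : s], seq[s + length : s + length + 10]
            else:
                left_ctx = revcomp(seq[s + length : s + length + 10])
                right_ctx = revcomp(seq[s - 10 : s])
            flank_l = amplicon[: b - t_l]
            flank_r = amplicon[b + t_r : b + t_r + 10]
            mh_l = 0
            for k in range(1, 11):
                if flank_l[-k:] == left_ctx[-k:]:
                    mh_l = k
            mh_r = 0
            for k in range(1, 11):
                if flank_r[:k] == right_ctx[:k]:
                    mh_r = k
            assert got == (mh_l, mh_r)
            checked += 1

    def test_junction_with_extra_bases_reports_zero(self, mock, clean_dataset):
        _, events, _ = clean_dataset
        with_extra = [e for e in events
                      if e.event_class in ("single_donor", "multi_donor") and e.extra_left]
        assert with_extra
        for t in with_extra:
            ev = called_from_truth(mock, t)
            assert compute_microhomology(ev, mock.design, mock.genome)[0] == 0

    def test_profile_invariant_mh_and_extra_exclusive(self, mock, clean_dataset):
        _, events, _ = clean_dataset
        for t in events:
            if t.event_class not in ("single_donor", "multi_donor"):
                continue
            p = junction_profile(called_from_truth(mock, t), mock.design, mock.genome)
            if p.mh_left > 0:
                assert p.extra_left == 0
            if p.mh_right > 0:
                assert p.extra_right == 0


class TestClassify:
    def seg(self, subject, start, end):
        return DonorSegment(subject, start, end, "+", 0, end - start)

    def test_by_subject_class(self, mock):
        assert classify_source(self.seg("mito", 100, 200), mock.genome) == "mtDNA"
        assert classify_source(self.seg("two_micron", 10, 50), mock.genome) == "plasmid_2micron"

    def test_interval_classes_with_one_bp_overlap(self, mock):
        ty_s, ty_e = mock.ty_interval
        rd_s, rd_e = mock.rdna_interval
        assert classify_source(self.seg("chrN", ty_s - 30, ty_s + 1), mock.genome) == "Ty"
        assert classify_source(self.seg("chrN", rd_s + 5, rd_s + 50), mock.genome) == "rDNA"
        assert classify_source(self.seg("chrN", ty_s - 50, ty_s), mock.genome) == "nuclear"

    def test_locus_class_requires_design(self, mock):
        d = mock.design
        seg = self.seg("chrN", d.amplicon_start + 5, d.amplicon_start + 30)
        assert classify_source(seg, mock.genome, d) == "locus"
        assert classify_source(seg, mock.genome) == "nuclear"

    def test_every_segment_gets_exactly_one_class(self, mock, clean_result):
        _, result = clean_result
        for c in result.clusters:
            for seg in c.representative.segments:
                assert seg.source_class in (
                    "mtDNA", "Ty", "rDNA", "nuclear", "plasmid_2micron", "locus",
                )


class TestTy1Realign:
    def make_ty_event(self, mock, piece):
        ev = InsertionEvent("e", "S1", 41, 41, piece,
                            segments=[DonorSegment("chrN", 0, len(piece), "+", 0, len(piece),
                                                   source_class="Ty")])
        return ev

    def test_terminal_repeat_reports_right_ltr(self, mock):
        ty1 = mock.ty1_reference()
        ltr = mock.ty_ltr_len
        (l_s, l_e), (r_s, r_e) = mock.ty1_ltr_intervals()
        piece = mock.ty1_seq[50 : 50 + 80]  # inside the (identical) LTRs
        segs = ty1_realign(self.make_ty_event(mock, piece), ty1)
        assert segs[0].subject == "Ty1"
        assert segs[0].start >= r_s  # right repeat coordinates
        assert (segs[0].start - r_s, segs[0].end - r_s) == (50, 130)

    def test_internal_region_unaffected_by_tie_break(self, mock):
        ty1 = mock.ty1_reference()
        ltr = mock.ty_ltr_len
        piece = mock.ty1_seq[ltr + 500 : ltr + 580]
        segs = ty1_realign(self.make_ty_event(mock, piece), ty1)
        assert (segs[0].start, segs[0].end) == (ltr + 500, ltr + 580)

    def test_diverged_insert_accepted_above_identity_floor(self, mock):
        ty1 = mock.ty1_reference()
        ltr = mock.ty_ltr_len
        piece = list(mock.ty1_seq[ltr + 800 : ltr + 880])
        comp = {"A": "C", "C": "G", "G": "T", "T": "A"}
        for p in range(0, 36, 3):  # clustered divergence in the first half
            piece[p] = comp[piece[p]]
        segs = ty1_realign(self.make_ty_event(mock, "".join(piece)), ty1)
        assert segs[0].subject == "Ty1"
        assert segs[0].percent_identity >= 60.0

    def test_unalignable_ty_segment_kept_with_genomic_coordinates(self, mock):
        ty1 = mock.ty1_reference()
        segs = ty1_realign(self.make_ty_event(mock, "ATATATATATATATATATAT"), ty1)
        assert segs[0].subject == "chrN"


class TestFrequencyTrack:
    def test_quoted_formulas(self):
        track = FrequencyTrack("mito", np.array([5, 0, 45]), n_colonies=100_000)
        assert track.frequency_per_1e5()[0] == pytest.approx(5.0)
        assert track.n_t_total == 50
        assert track.percentage()[0] == pytest.approx(10.0)

    def test_overlapping_insertions_count_per_position(self):
        events = [
            InsertionEvent("a", "S1", 41, 41, "A" * 10,
                           segments=[DonorSegment("mito", 10, 20, "+", 0, 10)]),
            InsertionEvent("b", "S1", 41, 41, "A" * 10,
                           segments=[DonorSegment("mito", 15, 25, "+", 0, 10)]),
        ]
        track = nucleotide_frequency(events, "mito", 30, n_colonies=100)
        assert list(track.n_t[10:15]) == [1] * 5
        assert list(track.n_t[15:20]) == [2] * 5
        assert list(track.n_t[20:25]) == [1] * 5

    def test_conservation_of_inserted_length(self, mock, clean_result):
        """Sum of track increments equals total inserted donor length."""
        _, result = clean_result
        reps = [c.representative for c in result.clusters]
        total = 0
        for subject in mock.genome.sequences:
            track = nucleotide_frequency(
                reps, subject, len(mock.genome.sequences[subject]),
                n_colonies=1000, include_multi_donor=True,
            )
            total += track.n_t_total
        expected = sum(seg.end - seg.start for rep in reps for seg in rep.segments
                       if not rep.length_lower_bound)
        assert total == expected

    def test_zero_total_percentage_all_zero_with_warning(self, caplog):
        track = FrequencyTrack("mito", np.zeros(10, dtype=int), n_colonies=10)
        assert track.percentage().sum() == 0

    def test_multi_donor_excluded_by_default(self):
        ev = InsertionEvent("a", "S1", 41, 41, "A" * 20, segments=[
            DonorSegment("mito", 10, 20, "+", 0, 10),
            DonorSegment("mito", 100, 110, "+", 10, 20),
        ])
        assert nucleotide_frequency([ev], "mito", 200, 10).n_t_total == 0
        assert nucleotide_frequency([ev], "mito", 200, 10,
                                    include_multi_donor=True).n_t_total == 20

    def test_n_colonies_must_be_positive(self):
        with pytest.raises(ValueError):
            nucleotide_frequency([], "mito", 10, 0)
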