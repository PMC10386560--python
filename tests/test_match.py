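import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from svheart import (BeatSeries, compute_recall_precision, match_beats,
                     select_ibis)
from svheart.io import MatchedBeats
from _oracles import (brute_force_match, brute_force_select_ibis,
                      random_peak_instance)


class TestMatchBeats:
    def test_hand_traced_example(self):
        # m=[300,600,900], n=[315,590,612,1000] (sample units):
        # j=1 interval [0,420] -> 315; j=2 interval [480,720],
        # candidates {590,612}, nearest 590; j=3 interval [780,900] empty.
        m = np.array([300.0, 600.0, 900.0])
        n = np.array([315.0, 590.0, 612.0, 1000.0])
        matched = match_beats(m, n)
        np.testing.assert_array_equal(matched.m_valid, [300.0, 600.0])
        np.testing.assert_array_equal(matched.n_valid, [315.0, 590.0])
        assert matched.n_ecg_total == 3 and matched.n_sv_total == 4
        recall, precision = compute_recall_precision(matched)
        assert recall == pytest.approx(2 / 3, abs=1e-3)
        assert precision == pytest.approx(0.5)

    def test_perfect_detector_matches_everything(self):
        m = np.cumsum(np.full(20, 0.9))
        matched = match_beats(m, m.copy())
        np.testing.assert_array_equal(matched.m_valid, m)
        np.testing.assert_array_equal(matched.n_valid, m)
        assert compute_recall_precision(matched) == (1.0, 1.0)

    def test_no_sv_peaks_gives_empty_match(self):
        matched = match_beats(np.array([1.0, 2.0, 3.0]), np.array([]))
        assert len(matched) == 0

    def test_matched_pairs_lie_inside_their_intervals(self):
        # consecutive acceptance intervals are disjoint by construction
        # (upper bound m_j + 0.4d < lower bound m_{j+1} - 0.4d), so every
        # matched SV peak must fall inside its own R peak's interval
        rng = np.random.default_rng(5)
        for _ in range(50):
            m, n = random_peak_instance(rng)
            matched = match_beats(m, n)
            for mj, nj in zip(matched.m_valid, matched.n_valid):
                j = int(np.flatnonzero(m == mj)[0])
                if j == 0:
                    lo, hi = 0.0, m[0] + 0.4 * (m[1] - m[0])
                elif j < len(m) - 1:
                    lo = mj - 0.4 * (mj - m[j - 1])
                    hi = mj + 0.4 * (m[j + 1] - mj)
                else:
                    lo, hi = mj - 0.4 * (mj - m[j - 1]), mj
                assert lo <= nj <= hi

    def test_equidistant_tie_takes_earlier_peak(self):
        m = np.array([0.0, 10.0, 20.0])
        n = np.array([9.0, 11.0])
        matched = match_beats(m, n)
        assert matched.n_valid.tolist() == [9.0]

    def test_inclusive_interval_bounds(self):
        m = np.array([0.0, 10.0])
        n = np.array([4.0])  # exactly at 0 + 0.4*(10-0)
        matched = match_beats(m, n)
        assert matched.m_valid.tolist() == [0.0]

    def test_rejects_unsorted_or_short_input(self):
        with pytest.raises(ValueError, match="increasing"):
            match_beats(np.array([2.0, 1.0, 3.0]), np.array([1.0]))
        with pytest.raises(ValueError, match="at least 2"):
            match_beats(np.array([1.0]), np.array([1.0]))

    def test_beat_series_units_must_agree(self):
        m = BeatSeries(np.array([300, 600]), "ecg", 300.0, unit="samples")
        n = BeatSeries(np.array([1.0, 2.0]), "sv", 300.0, unit="s")
        with pytest.raises(ValueError, match="unit"):
            match_beats(m, n)


class TestMatchProperties:
    def test_random_instances_agree_with_brute_force(self):
        rng = np.random.default_rng(2024)
        for _ in range(300):
            m, n = random_peak_instance(rng)
            matched = match_beats(m, n)
            bm, bn, _ = brute_force_match(m, n)
            np.testing.assert_allclose(matched.m_valid, bm)
            np.testing.assert_allclose(matched.n_valid, bn)
            # structural invariants
            assert len(matched.m_valid) == len(matched.n_valid)
            assert len(np.unique(matched.n_valid)) == len(matched.n_valid)

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(st.lists(st.floats(0.3, 2.0), min_size=2, max_size=30),
           st.lists(st.floats(0.0, 40.0), min_size=0, max_size=40))
    def test_hypothesis_instances_agree_with_brute_force(self, rr, raw_n):
        m = np.cumsum(np.asarray(rr))
        n = np.unique(np.asarray(raw_n))
        matched = match_beats(m, n)
        bm, bn, _ = brute_force_match(m, n)
        np.testing.assert_allclose(matched.m_valid, bm)
        np.testing.assert_allclose(matched.n_valid, bn)


class TestSelectIbis:
    def test_hand_traced_false_interval_exclusion(self):
        # original R peaks [300,600,900,1200] samples at 300 Hz; 900 was
        # discarded during matching, so the 600-sample interval is a
        # "false interval" and only the 300-sample one survives (1.0 s)
        all_ecg = np.array([300.0, 600.0, 900.0, 1200.0])
        matched = MatchedBeats(
            m_valid=np.array([300.0, 600.0, 1200.0]),
            n_valid=np.array([310.0, 612.0, 1213.0]),
            n_ecg_total=4, n_sv_total=3, unit="samples", rate_hz=300.0)
        ibis = select_ibis(all_ecg, matched)
        np.testing.assert_allclose(ibis.ibi_ecg, [1.0])
        np.testing.assert_allclose(ibis.ibi_sv, [(612 - 310) / 300.0])
        assert ibis.kept_index.tolist() == [0]

    def test_no_discarded_peaks_keeps_all_intervals(self):
        m = np.cumsum(np.full(10, 0.8))
        matched = match_beats(m, m - 0.01)
        ibis = select_ibis(m, matched)
        assert len(ibis) == 9
        np.testing.assert_allclose(ibis.ibi_ecg, np.diff(m))

    def test_fewer_than_two_matches_gives_empty_lists(self):
        matched = MatchedBeats(np.array([1.0]), np.array([1.1]),
                               n_ecg_total=3, n_sv_total=2)
        ibis = select_ibis(np.array([1.0, 2.0, 3.0]), matched)
        assert len(ibis) == 0

    def test_m_valid_must_be_subset_of_originals(self):
        matched = MatchedBeats(np.array([1.0, 2.5]), np.array([1.1, 2.6]),
                               n_ecg_total=2, n_sv_total=2)
        with pytest.raises(ValueError, match="original"):
            select_ibis(np.array([1.0, 2.0]), matched)

    def test_random_instances_agree_with_brute_force(self):
        rng = np.random.default_rng(99)
        for _ in range(200):
            m, n = random_peak_instance(rng, n_beats=30, drop=0.2)
            matched = match_beats(m, n)
            if len(matched) < 2:
                continue
            ibis = select_ibis(m, matched)
            be, bs, bidx = brute_force_select_ibis(
                list(m), list(matched.m_valid), list(matched.n_valid))
            np.testing.assert_allclose(ibis.ibi_ecg, be)
            np.testing.assert_allclose(ibis.ibi_sv, bs)
            assert ibis.kept_index.tolist() == bidx
            # exclusion never lengthens the lists
            assert len(ibis) <= len(matched) - 1
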