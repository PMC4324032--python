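"""Sliding-window smoothing, extrema, peak merging, heights, ChIPScores and
replicate reconciliation, checked against brute-force re-computation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import zurchip as z
from zurchip.peaks import _flanking_minima

W = 29


def make_track(values, spacing=11, replicate="rep1"):
    values = np.asarray(values, dtype=float)
    return z.RatioTrack(
        1 + spacing * np.arange(len(values)), values, np.zeros(len(values)),
        replicate=replicate,
    )


def params(**kw):
    return z.PeakCallingParams(**kw)


# ---------------------------------------------------------------- oracles --
def brute_moving_mean(v, w, circular):
    n, h = len(v), w // 2
    out = np.empty(n)
    for i in range(n):
        if circular:
            out[i] = np.mean(v[np.arange(i - h, i + h + 1) % n])
        else:
            out[i] = np.mean(v[max(0, i - h): i + h + 1])
    return out


def brute_extrema(v, w, circular):
    n, h = len(v), w // 2

    def window(i):
        if circular:
            return v[np.arange(i - h, i + h + 1) % n]
        return v[max(0, i - h): i + h + 1]

    def collapse(cands):
        cand_set = set(cands)
        keep = []
        for i in cands:
            j = (i - 1) % n if circular else i - 1
            if j >= 0 and j in cand_set and v[j] == v[i]:
                continue
            keep.append(i)
        if circular and cands and not keep:  # one tying run spans the circle
            keep = [min(cands)]
        return sorted(keep)

    maxima = collapse([i for i in range(n) if v[i] == window(i).max()])
    minima = collapse([i for i in range(n) if v[i] == window(i).min()])
    return maxima, minima


# ------------------------------------------------------------------ smooth --
class TestSmooth:
    def test_constant_track_unchanged(self):
        track = make_track(np.full(100, 2.5))
        for rounds in (1, 2, 5):
            s = z.smooth(track, params(smoothing_rounds=rounds))
            assert np.array_equal(s.m, track.m)

    def test_impulse_spreads_over_window(self):
        v = np.zeros(100)
        v[50] = 29.0
        s = z.smooth(make_track(v), params(window_probes=29, smoothing_rounds=1))
        expected = np.zeros(100)
        expected[50 - 14: 50 + 15] = 1.0
        assert np.array_equal(s.m, expected)

    @pytest.mark.parametrize("circular", [True, False])
    def test_matches_bruteforce(self, circular):
        rng = np.random.default_rng(7)
        v = rng.normal(size=300)
        s = z.smooth(
            make_track(v), params(smoothing_rounds=1, circular=circular)
        )
        assert np.array_equal(s.m, brute_moving_mean(v, W, circular))

    def test_window_larger_than_track_raises(self):
        with pytest.raises(ValueError, match="larger than track"):
            z.smooth(make_track(np.zeros(10)), params())

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(
        st.lists(
            st.floats(-10, 10, allow_nan=False), min_size=5, max_size=80
        ),
        st.sampled_from([3, 5, 9]),
        st.booleans(),
    )
    def test_moving_mean_property(self, values, w, circular):
        values = np.asarray(values)
        if w > len(values):
            return
        s = z.smooth(
            make_track(values), params(window_probes=w, smoothing_rounds=1,
                                       circular=circular)
        )
        assert np.allclose(s.m, brute_moving_mean(values, w, circular), atol=1e-12)


# ---------------------------------------------------------------- extrema --
class TestFindExtrema:
    def test_monotone_track_extrema_at_ends(self):
        track = make_track(np.linspace(0, 1, 100))
        maxima, minima = z.find_extrema(track, params(circular=False))
        assert list(maxima) == [99]
        assert list(minima) == [0]

    def test_triangular_bump(self):
        v = np.array([0.0, 1.0, 2.0, 3.0, 2.0, 1.0, 0.0])
        maxima, minima = z.find_extrema(
            make_track(v), params(window_probes=3, circular=False)
        )
        assert list(maxima) == [3]
        assert list(minima) == [0, 6]

    def test_plateau_tie_goes_leftmost(self):
        v = np.array([0.0, 1.0, 2.0, 2.0, 2.0, 1.0, 0.0, 0.5, 0.2])
        maxima, _ = z.find_extrema(
            make_track(v), params(window_probes=5, circular=False)
        )
        assert 2 in maxima
        assert 3 not in maxima and 4 not in maxima

    @pytest.mark.parametrize("circular", [True, False])
    def test_matches_bruteforce_with_ties(self, circular):
        rng = np.random.default_rng(11)
        # quantized values force plenty of exact ties
        v = np.round(rng.normal(size=400), 1)
        maxima, minima = z.find_extrema(
            make_track(v), params(window_probes=9, circular=circular)
        )
        bmax, bmin = brute_extrema(v, 9, circular)
        assert list(maxima) == bmax
        assert list(minima) == bmin

    def test_constant_circular_track_single_run(self):
        maxima, minima = z.find_extrema(make_track(np.ones(50)), params())
        assert list(maxima) == [0]
        assert list(minima) == [0]


# ------------------------------------------------------------------ merge --
class TestMergePeaks:
    def test_maxima_within_window_merge(self):
        reps = z.merge_peaks(np.array([100, 350]), np.array([1.0, 2.0]))
        assert len(reps) == 1

    def test_maxima_beyond_window_stay_separate(self):
        reps = z.merge_peaks(np.array([100, 500]), np.array([1.0, 2.0]))
        assert len(reps) == 2

    def test_empty_input(self):
        assert len(z.merge_peaks(np.array([]), np.array([]))) == 0

    def test_representative_is_highest_then_leftmost(self):
        pos = np.array([100, 200, 300])
        reps = z.merge_peaks(pos, np.array([1.0, 5.0, 2.0]))
        assert list(pos[reps]) == [200]
        reps = z.merge_peaks(pos, np.array([5.0, 5.0, 2.0]))
        assert list(pos[reps]) == [100]

    def test_circular_wrap_merges_across_origin(self):
        pos = np.array([10, 9950])
        reps = z.merge_peaks(pos, np.array([1.0, 2.0]), genome_length=10_000)
        assert len(reps) == 1
        reps = z.merge_peaks(
            pos, np.array([1.0, 2.0]),
            z.PeakCallingParams(circular=False), genome_length=None,
        )
        assert len(reps) == 2


# ----------------------------------------------------------------- height --
class TestPeakHeight:
    @pytest.mark.parametrize(
        "smax,left,right,expected",
        [
            (2.0, 0.0, 0.0, 2.0),
            (3.0, 1.0, 2.0, 1.5),  # mean of the two flanking minima
            (1.0, None, 2.0, 0.0),  # single flank, clipped at zero
            (3.0, None, 2.0, 1.0),
            (0.0, 0.0, 0.0, 0.0),
        ],
    )
    def test_height_rule(self, smax, left, right, expected):
        assert z.peak_height(smax, left, right) == pytest.approx(expected)

    def test_flat_track_all_heights_zero(self):
        peaks, _ = z.call_peaks(make_track(np.ones(100)), params(), 1100)
        assert all(p.height == 0.0 for p in peaks)

    def test_flanking_minima_wrap(self):
        mins = np.array([100, 500, 900])
        assert _flanking_minima(50, mins, circular=True) == (2, 0)
        assert _flanking_minima(50, mins, circular=False) == (None, 0)
        assert _flanking_minima(950, mins, circular=False) == (2, None)


# -------------------------------------------------------------- ChIPScore --
class TestChipScores:
    def test_score_identities(self):
        heights = [1.0, 2.0, 3.0, 4.0, 5.0]
        peaks = [
            z.Peak("r", 100 * (i + 1), None, None, h, h)
            for i, h in enumerate(heights)
        ]
        scored = z.chip_scores(peaks)
        by_height = {p.height: p.chip_score for p in scored}
        assert by_height[3.0] == pytest.approx(0.0)  # the median scores 0
        assert by_height[4.0] == pytest.approx(1.0)  # the upper quartile scores 1
        assert by_height[5.0] == pytest.approx(2.0)  # (5-3)/(4-3)

    def test_too_few_peaks_raises(self):
        peaks = [z.Peak("r", i, None, None, 1.0, 1.0) for i in range(3)]
        with pytest.raises(ValueError, match="4 peaks"):
            z.chip_scores(peaks)

    def test_degenerate_distribution_raises(self):
        peaks = [z.Peak("r", i, None, None, 1.0, 1.0) for i in range(10)]
        with pytest.raises(ValueError, match="degenerate"):
            z.chip_scores(peaks)


# -------------------------------------------------------------- consensus --
def scored_peak(rep, pos, score):
    return z.Peak(rep, pos, None, None, 1.0, 1.0, chip_score=score)


class TestConsensusPeaks:
    def test_matched_pair_averages_score_and_position(self):
        cons = z.consensus_peaks(
            [scored_peak("r1", 1000, 6.0)], [scored_peak("r2", 1100, 5.0)]
        )
        assert len(cons) == 1
        assert cons[0].chip_score == pytest.approx(5.5)
        assert cons[0].max_position == 1050

    def test_cutoff_required_in_both_replicates(self):
        cons = z.consensus_peaks(
            [scored_peak("r1", 1000, 6.0)], [scored_peak("r2", 1000, 3.9)]
        )
        assert cons == []

    def test_distant_peaks_unmatched(self):
        cons = z.consensus_peaks(
            [scored_peak("r1", 1000, 6.0)], [scored_peak("r2", 1400, 6.0)]
        )
        assert cons == []

    def test_greedy_matching_uses_each_peak_once(self):
        r1 = [scored_peak("r1", 1000, 6.0), scored_peak("r2", 1200, 6.0)]
        r2 = [scored_peak("r2", 1010, 6.0)]
        cons = z.consensus_peaks(r1, r2)
        assert len(cons) == 1
        assert cons[0].rep1.max_position == 1000

    def test_wraparound_match(self):
        cons = z.consensus_peaks(
            [scored_peak("r1", 10, 6.0)], [scored_peak("r2", 9990, 6.0)],
            genome_length=10_000,
        )
        assert len(cons) == 1
        assert cons[0].max_position == 10_000

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(st.lists(st.floats(0, 20, allow_nan=False), min_size=0, max_size=12))
    def test_raising_cutoff_never_adds_consensus_peaks(self, scores):
        r1 = [scored_peak("r1", 500 * (i + 1), s) for i, s in enumerate(scores)]
        r2 = [scored_peak("r2", 500 * (i + 1) + 50, s + 0.5) for i, s in enumerate(scores)]
        counts = []
        for cutoff in (0.0, 2.0, 4.0, 8.0):
            p = params(score_cutoff=cutoff)
            counts.append(len(z.consensus_peaks(r1, r2, p)))
        assert counts == sorted(counts, reverse=True)


# ------------------------------------------------------------- invariance --
class TestScaleEquivariance:
    def test_constant_shift_leaves_heights_and_scores_unchanged(self):
        rng = np.random.default_rng(3)
        v = rng.normal(size=600)
        base, _ = z.call_peaks(make_track(v), params(), 6700)
        shifted, _ = z.call_peaks(make_track(v + 5.0), params(), 6700)
        assert len(base) == len(shifted)
        for p, q in zip(base, shifted):
            assert p.max_position == q.max_position
            assert p.height == pytest.approx(q.height, abs=1e-9)
        s1 = z.chip_scores(base)
        s2 = z.chip_scores(shifted)
        for p, q in zip(s1, s2):
            assert p.chip_score == pytest.approx(q.chip_score, abs=1e-6)
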