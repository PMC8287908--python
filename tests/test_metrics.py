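"""Hungarian matching, F1 scores, the F1 integral, and RMSE."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import gridspot as gs
from gridspot.metrics import MatchResult, f1_score_at


def brute_force_match(pred, truth, cutoff):
    """Exhaustive assignment enumeration oracle.

    Returns (tp, total matched distance) of the lexicographically best
    assignment: maximal number of pairs within the cutoff, then minimal
    total distance.
    """
    pred = np.asarray(pred, dtype=float).reshape(-1, 2)
    truth = np.asarray(truth, dtype=float).reshape(-1, 2)
    if len(pred) == 0 or len(truth) == 0:
        return 0, 0.0
    small, large, transposed = (
        (pred, truth, False) if len(pred) <= len(truth) else (truth, pred, True)
    )
    d = np.linalg.norm(small[:, None, :] - large[None, :, :], axis=-1)
    best = (0, np.inf)
    for perm in itertools.permutations(range(len(large)), len(small)):
        dists = [d[i, j] for i, j in enumerate(perm) if d[i, j] <= cutoff]
        cand = (len(dists), sum(dists))
        if cand[0] > best[0] or (cand[0] == best[0] and cand[1] < best[1]):
            best = cand
    return best


class TestMatchAtCutoff:
    def test_identity_matching(self):
        pts = np.array([[1.0, 2.0], [5.0, 5.0], [9.0, 0.0]])
        m = gs.match_at_cutoff(pts, pts, 3.0)
        assert m.tp == 3 and m.fp == 0 and m.fn == 0
        assert np.allclose(m.distances, 0.0)

    def test_empty_prediction(self):
        truth = np.arange(10.0).reshape(5, 2)
        m = gs.match_at_cutoff([], truth, 3.0)
        assert m.tp == 0 and m.fp == 0 and m.fn == 5

    def test_prefers_maximal_matching_over_greedy_distance(self):
        # assigning pred (0,3) to its nearest truth (0,4) would leave
        # (0,5) unmatchable; the optimal assignment keeps both pairs
        truth = [[0.0, 0.0], [0.0, 4.0]]
        pred = [[0.0, 3.0], [0.0, 5.0]]
        m = gs.match_at_cutoff(pred, truth, 3.5)
        assert m.tp == 2 and m.fp == 0 and m.fn == 0
        assert sorted(round(d, 9) for d in m.distances) == [1.0, 3.0]

    def test_nonstrict_cutoff_comparison(self):
        m = gs.match_at_cutoff([[0.0, 0.0]], [[0.0, 2.0]], 2.0)
        assert m.tp == 1

    def test_agrees_with_exhaustive_enumeration(self):
        rng = np.random.default_rng(11)
        for _ in range(200):
            n_p, n_t = rng.integers(0, 7, size=2)
            pred = rng.uniform(0, 10, (n_p, 2))
            truth = rng.uniform(0, 10, (n_t, 2))
            cutoff = rng.uniform(0.5, 5.0)
            m = gs.match_at_cutoff(pred, truth, cutoff)
            tp, dist = brute_force_match(pred, truth, cutoff)
            assert m.tp == tp
            assert m.distances.sum() == pytest.approx(dist, abs=1e-9)

    def test_swapping_pred_truth_exchanges_fp_fn(self):
        rng = np.random.default_rng(3)
        pred, truth = rng.uniform(0, 8, (4, 2)), rng.uniform(0, 8, (6, 2))
        a = gs.match_at_cutoff(pred, truth, 2.5)
        b = gs.match_at_cutoff(truth, pred, 2.5)
        assert (a.tp, a.fp, a.fn) == (b.tp, b.fn, b.fp)
        assert gs.f1_at_cutoff(a) == pytest.approx(gs.f1_at_cutoff(b))


class TestF1:
    @pytest.mark.parametrize(
        "tp,fp,fn,expected",
        [(2, 1, 1, 2 * 2 / 6), (0, 0, 0, 0.0), (5, 0, 0, 1.0), (0, 3, 2, 0.0)],
    )
    def test_f1_formula(self, tp, fp, fn, expected):
        match = MatchResult([(i, i, 0.0) for i in range(tp)], fp=fp, fn=fn,
                            cutoff=3.0)
        assert gs.f1_at_cutoff(match) == pytest.approx(expected)

    def test_f1_nondecreasing_in_cutoff(self):
        rng = np.random.default_rng(5)
        pred, truth = rng.uniform(0, 12, (6, 2)), rng.uniform(0, 12, (6, 2))
        scores = [f1_score_at(pred, truth, c) for c in np.linspace(0, 6, 40)]
        assert all(b >= a - 1e-12 for a, b in zip(scores, scores[1:]))


class TestF1Integral:
    def test_perfect_prediction_scores_one(self):
        rng = np.random.default_rng(1)
        pts = rng.uniform(0, 512, (25, 2))
        assert gs.f1_integral(pts, pts) == pytest.approx(1.0, abs=1e-9)

    def test_all_misses_score_zero(self):
        truth = np.array([[20.0 * i, 20.0 * j]
                          for i in range(1, 4) for j in range(1, 4)])
        assert gs.f1_integral(truth + 10.0, truth) == 0.0

    def test_single_pair_step_function(self):
        # independent oracle: for one pred/truth pair at distance d the F1
        # curve is a unit step at d; integrate that step analytically over
        # the 50-point trapezoid
        d = 1.5
        cutoffs = np.linspace(0.0, 3.0, 50)
        step = (cutoffs >= d).astype(float)
        expected = np.trapezoid(step, cutoffs) / 3.0
        assert expected == pytest.approx(0.5, abs=1e-12)
        got = gs.f1_integral([[0.0, d]], [[0.0, 0.0]])
        assert got == pytest.approx(expected, abs=1e-12)

    @given(st.integers(0, 2**32 - 1), st.integers(0, 6), st.integers(0, 6))
    @settings(max_examples=40, deadline=None)
    def test_bounded_in_unit_interval(self, seed, n_pred, n_truth):
        rng = np.random.default_rng(seed)
        score = gs.f1_integral(rng.uniform(0, 20, (n_pred, 2)),
                               rng.uniform(0, 20, (n_truth, 2)))
        assert 0.0 <= score <= 1.0

    def test_permuted_prediction_still_scores_one(self):
        rng = np.random.default_rng(9)
        pts = rng.uniform(0, 100, (12, 2))
        assert gs.f1_integral(pts[::-1], pts) == pytest.approx(1.0, abs=1e-9)


class TestRmse:
    def test_perfect_localization(self):
        m = MatchResult([(0, 0, 0.0), (1, 1, 0.0), (2, 2, 0.0)], 0, 0, 3.0)
        assert gs.rmse_true_positives(m) == 0.0

    def test_rmse_of_two_distances(self):
        m = MatchResult([(0, 0, 1.0), (1, 1, 2.0)], 0, 0, 3.0)
        assert gs.rmse_true_positives(m) == pytest.approx(np.sqrt(2.5),
                                                          abs=1e-12)

    def test_undefined_without_true_positives(self):
        m = MatchResult([], fp=2, fn=3, cutoff=3.0)
        assert np.isnan(gs.rmse_true_positives(m))


class TestEvaluate:
    def test_two_image_statistics(self):
        truth = np.array([[5.0, 5.0]])
        report = gs.evaluate([truth, truth + 10.0], [truth, truth])
        assert report.f1_integral_mean == pytest.approx(0.5)
        assert report.f1_integral_sd == pytest.approx(np.sqrt(0.5), abs=1e-9)

    def test_singleton_sd_is_zero(self):
        truth = np.array([[5.0, 5.0]])
        report = gs.evaluate([truth], [truth])
        assert report.f1_integral_sd == 0.0

    def test_identical_sets_score_one(self):
        rng = np.random.default_rng(2)
        truths = [rng.uniform(0, 50, (6, 2)) for _ in range(4)]
        report = gs.evaluate(truths, truths)
        assert report.f1_integral_mean == pytest.approx(1.0, abs=1e-9)
        assert report.f1_integral_sd == pytest.approx(0.0, abs=1e-9)
        assert report.rmse_mean == pytest.approx(0.0, abs=1e-9)

    def test_rmse_aggregated_over_images_with_tp_only(self):
        truth = np.array([[5.0, 5.0]])
        report = gs.evaluate([truth + 1.0, truth + 100.0], [truth, truth])
        assert report.per_image["rmse"].isna().sum() == 1
        assert report.rmse_mean == pytest.approx(np.sqrt(2.0), abs=1e-9)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length mismatch"):
            gs.evaluate([np.zeros((1, 2))], [])
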