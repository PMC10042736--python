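"""ROC construction, threshold selection and per-condition summaries."""

import numpy as np
import pandas as pd
import pytest

from nucexpel.roc import (
    build_roc,
    classify_and_summarize,
    evaluate_detection,
    select_threshold,
)


def mann_whitney_auc(pos, neg):
    """Independent oracle: pair statistic P(pos>neg) + 0.5 P(pos=neg)."""
    p = np.asarray(pos)[:, None]
    n = np.asarray(neg)[None, :]
    return ((p > n).sum() + 0.5 * (p == n).sum()) / (p.size * n.size)


class TestBuildRoc:
    def test_perfect_separation(self):
        roc = build_roc([10.0] * 5, [0.0] * 5)
        assert roc.auc == 1.0

    def test_identical_populations(self):
        roc = build_roc([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert roc.auc == pytest.approx(0.5)

    def test_pair_counting_worked_example(self):
        # pos {3,1}, neg {2,0}: 3 of 4 pairs correctly ordered
        roc = build_roc([3.0, 1.0], [2.0, 0.0])
        assert roc.auc == pytest.approx(0.75)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            build_roc([], [1.0])

    def test_nonfinite_score_named(self):
        with pytest.raises(ValueError, match="index 1"):
            build_roc([1.0, np.nan], [0.0])

    def test_curves_monotone_in_threshold(self, rng):
        for _ in range(30):
            pos = rng.normal(1, 1, rng.integers(2, 40))
            neg = rng.normal(0, 1, rng.integers(2, 40))
            roc = build_roc(pos, neg)
            assert (np.diff(roc.tpr) <= 1e-15).all()
            assert (np.diff(roc.fpr) <= 1e-15).all()

    def test_trapezoid_equals_pair_statistic_with_ties(self, rng):
        """AUC oracle: trapezoid AUC == Mann-Whitney statistic to 1e-12."""
        for _ in range(200):
            npos = int(rng.integers(1, 30))
            nneg = int(rng.integers(1, 30))
            # integer grid forces ties within and across classes
            pos = rng.integers(0, 6, npos).astype(float)
            neg = rng.integers(0, 6, nneg).astype(float)
            roc = build_roc(pos, neg)
            assert abs(roc.auc - mann_whitney_auc(pos, neg)) <= 1e-12

    def test_matches_sklearn_reference(self, rng):
        from sklearn.metrics import roc_auc_score

        pos = rng.normal(1.0, 1.0, 50)
        neg = rng.normal(0.0, 1.0, 70)
        roc = build_roc(pos, neg)
        ref = roc_auc_score(np.r_[np.ones(50), np.zeros(70)], np.r_[pos, neg])
        assert roc.auc == pytest.approx(ref, abs=1e-12)


class TestSelectThreshold:
    def test_youden_midpoint_of_separating_gap(self):
        roc = build_roc([10.0, 12.0], [0.0, 2.0])
        thr = select_threshold(roc, "youden")
        assert thr == pytest.approx((2.0 + 10.0) / 2)

    def test_fixed_fpr_empirical_recount(self, rng):
        neg = rng.normal(0, 1, 100)
        pos = rng.normal(2, 1, 100)
        roc = build_roc(pos, neg)
        thr = select_threshold(roc, "fixed_fpr", alpha=0.05)
        assert (neg > thr).mean() <= 0.05

    def test_fixed_passthrough(self):
        roc = build_roc([1.0], [0.0])
        assert select_threshold(roc, "fixed", fixed_value=1.23) == 1.23

    def test_fixed_fpr_below_floor_rejected(self):
        roc = build_roc([1.0], [0.0])
        with pytest.raises(ValueError, match="floor"):
            select_threshold(roc, "fixed_fpr", alpha=-0.1)


class TestClassifyAndSummarize:
    def test_half_above_threshold(self):
        df = pd.DataFrame(
            {"cell_id": range(4), "condition": "a", "score": [5.0, 5, 0, 0]}
        )
        res = classify_and_summarize(df, 1.0)
        assert res.summary["percent_expulsion"].iloc[0] == 50.0

    def test_ties_called_negative(self):
        df = pd.DataFrame({"cell_id": [0], "condition": "a", "score": [1.0]})
        res = classify_and_summarize(df, 1.0)
        assert res.summary["n_positive_calls"].iloc[0] == 0

    def test_unscorable_excluded_from_denominator(self):
        df = pd.DataFrame(
            {
                "cell_id": range(3),
                "condition": "a",
                "score": [5.0, np.nan, 0.0],
                "unscorable": [False, True, False],
            }
        )
        res = classify_and_summarize(df, 1.0)
        row = res.summary.iloc[0]
        assert row["n_cells"] == 2
        assert row["percent_expulsion"] == 50.0
        assert row["n_unscorable"] == 1


class TestEvaluateDetection:
    def _setup(self, calls):
        from conftest import make_config
        from nucexpel.metric import normalize_traces
        from nucexpel.segment import segment_movie
        from nucexpel.simulate import simulate_movie
        from nucexpel.track import track_cells

        cfg = make_config(n_cells=12, fraction_expelling=0.5, seed=17)
        movie, truth = simulate_movie(cfg)
        frames = segment_movie(movie.channel("nuclear"))
        traces = track_cells(frames)
        return truth, traces

    def test_perfect_and_all_negative_calls(self, small_wt_movie):
        from nucexpel.metric import normalize_traces, score_traces
        from nucexpel.segment import segment_movie
        from nucexpel.track import track_cells
        from nucexpel.roc import match_traces_to_truth

        cfg, movie, truth = small_wt_movie
        frames = segment_movie(movie.channel("nuclear"))
        traces = track_cells(frames)
        etr, _ = normalize_traces(traces)
        tab = score_traces(etr)
        tab["condition"] = "t"
        match = match_traces_to_truth(traces, truth)
        truth_call = {
            tid: bool(truth.cells.iloc[g]["expelled"]) for tid, g in match.items()
        }
        # calls copied from ground truth -> perfect confusion matrix
        perfect = tab.copy()
        perfect["score"] = [
            10.0 if truth_call.get(c, False) else 0.0 for c in perfect["cell_id"]
        ]
        res = classify_and_summarize(perfect, 1.0)
        summary = evaluate_detection(res, truth, traces)
        assert summary["sensitivity"] == 1.0
        assert summary["specificity"] == 1.0
        # all-negative calls: sensitivity 0, specificity 1
        negative = tab.copy()
        negative["score"] = 0.0
        res0 = classify_and_summarize(negative, 1.0)
        s0 = evaluate_detection(res0, truth, traces)
        assert s0["sensitivity"] == 0.0
        assert s0["specificity"] == 1.0

    def test_random_calls_give_binomial_false_positive_count(self, small_wt_movie):
        """Calling cells at random rate p yields ~p * n_negatives FPs."""
        from nucexpel.metric import normalize_traces, score_traces
        from nucexpel.segment import segment_movie
        from nucexpel.track import track_cells

        cfg, movie, truth = small_wt_movie
        frames = segment_movie(movie.channel("nuclear"))
        traces = track_cells(frames)
        etr, _ = normalize_traces(traces)
        tab = score_traces(etr)
        tab["condition"] = "t"
        p = 0.3
        rng = np.random.default_rng(123)
        fps, n_negs = [], []
        for _ in range(40):
            rand = tab.copy()
            rand["score"] = np.where(rng.uniform(size=len(rand)) < p, 10.0, 0.0)
            res = classify_and_summarize(rand, 1.0)
            s = evaluate_detection(res, truth, traces)
            fps.append(s["FP"])
            n_negs.append(s["FP"] + s["TN"])
        n_neg = n_negs[0]
        expect = p * n_neg
        sd = np.sqrt(p * (1 - p) * n_neg / len(fps))
        assert abs(np.mean(fps) - expect) <= 4 * sd
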