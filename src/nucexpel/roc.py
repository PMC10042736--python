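"""ROC threshold calibration for the expulsion score.

The positive population is a condition known to undergo nuclear expulsion
(Padi4-wild-type-like); the negative population is the matched knockout-like
condition that dies without expelling.  Whole conditions are used as the
calibration classes — label noise from non-expelling positive cells is
accepted, which is exactly why realistic false-positive rates sit in the
15-20% range rather than at zero.

A cell is called positive when score > threshold (strict; ties negative).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ROCResult",
    "ExpulsionResult",
    "build_roc",
    "select_threshold",
    "classify_and_summarize",
    "evaluate_detection",
    "MatchingError",
]


class MatchingError(RuntimeError):
    """No trace could be matched to any ground-truth cell."""


@dataclass
class ROCResult:
    thresholds: np.ndarray  # ascending, with -inf/+inf endpoints
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float
    chosen_threshold: float | None = None
    selection_method: str | None = None

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"threshold": self.thresholds, "tpr": self.tpr, "fpr": self.fpr}
        )


@dataclass
class ExpulsionResult:
    """Per-cell calls plus per-condition summaries."""

    cells: pd.DataFrame  # cell_id, condition, score, call
    summary: pd.DataFrame  # condition, n_cells, n_positive_calls, percent_expulsion, n_unscorable
    threshold: float


def _check_scores(scores, name: str) -> np.ndarray:
    arr = np.asarray(scores, dtype=float)
    if arr.size == 0:
        raise ValueError(f"{name} score list is empty")
    bad = np.flatnonzero(~np.isfinite(arr))
    if bad.size:
        raise ValueError(f"non-finite score for {name} cell index {bad[0]}")
    return arr


def build_roc(pos_scores, neg_scores) -> ROCResult:
    """ROC over all distinct score thresholds plus infinite endpoints.

    TPR(thr) = P(pos > thr), FPR(thr) = P(neg > thr).  The trapezoid AUC of
    this curve equals the Mann-Whitney pair statistic
    P(pos > neg) + 0.5 P(pos = neg) exactly, ties included.
    """
    pos = _check_scores(pos_scores, "positive")
    neg = _check_scores(neg_scores, "negative")
    thresholds = np.concatenate(
        [[-np.inf], np.unique(np.concatenate([pos, neg])), [np.inf]]
    )
    pos_sorted = np.sort(pos)
    neg_sorted = np.sort(neg)
    tpr = 1.0 - np.searchsorted(pos_sorted, thresholds, side="right") / pos.size
    fpr = 1.0 - np.searchsorted(neg_sorted, thresholds, side="right") / neg.size
    # thresholds ascend => fpr descends; integrate TPR d(FPR) left-to-right
    auc = float(np.trapezoid(tpr[::-1], fpr[::-1]))
    return ROCResult(thresholds=thresholds, tpr=tpr, fpr=fpr, auc=auc)


def select_threshold(
    roc: ROCResult,
    method: str = "youden",
    alpha: float | None = None,
    fixed_value: float | None = None,
) -> float:
    """Choose the operating threshold on a fitted ROC.

    youden      — maximize J = TPR - FPR; among ties take the highest
                  threshold, then return the midpoint of the flat interval up
                  to the next distinct score (for separated populations this
                  is the midpoint of the separating gap).
    fixed_fpr   — smallest threshold with FPR <= alpha.
    fixed       — pass ``fixed_value`` through unchanged.
    """
    thr = roc.thresholds
    if method == "youden":
        j = roc.tpr - roc.fpr
        best = float(np.max(j))
        tied = np.flatnonzero(j == best)
        pick = tied[-1]  # ties -> higher threshold
        if not np.isfinite(thr[pick]):
            finite = np.flatnonzero(np.isfinite(thr))
            pick = finite[0] if len(finite) else pick
        t_star = thr[pick]
        above = thr[(thr > t_star) & np.isfinite(thr)]
        chosen = float((t_star + above[0]) / 2.0) if len(above) else float(t_star)
    elif method == "fixed_fpr":
        if alpha is None:
            raise ValueError("fixed_fpr needs alpha")
        floor = float(np.min(roc.fpr))
        if alpha < floor:
            raise ValueError(
                f"alpha={alpha} is below the achievable FPR floor {floor}"
            )
        ok = np.flatnonzero(roc.fpr <= alpha)
        chosen = float(thr[ok[0]])  # thresholds ascending; first = smallest
        if not np.isfinite(chosen):
            chosen = float(thr[ok[1]]) if len(ok) > 1 else chosen
    elif method == "fixed":
        if fixed_value is None or not np.isfinite(fixed_value):
            raise ValueError("fixed method needs a finite fixed_value")
        chosen = float(fixed_value)
    else:
        raise ValueError(f"unknown selection method {method!r}")
    roc.chosen_threshold = chosen
    roc.selection_method = method if method != "fixed_fpr" else f"fixed_fpr({alpha})"
    return chosen


def classify_and_summarize(scores: pd.DataFrame, threshold: float) -> ExpulsionResult:
    """Call each cell (score > threshold) and summarize per condition.

    ``scores`` needs columns cell_id, condition, score and optionally
    ``unscorable``; unscorable cells are excluded from the percent-expulsion
    denominator and reported separately.
    """
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    df = scores.copy()
    if "unscorable" not in df:
        df["unscorable"] = ~np.isfinite(df["score"])
    df["unscorable"] = df["unscorable"].astype(bool) | ~np.isfinite(df["score"])
    df["call"] = (~df["unscorable"]) & (df["score"] > threshold)
    rows = []
    for cond, grp in df.groupby("condition", sort=True):
        scorable = grp[~grp["unscorable"]]
        n = len(scorable)
        npos = int(scorable["call"].sum())
        rows.append(
            (cond, n, npos, 100.0 * npos / n if n else float("nan"),
             int(grp["unscorable"].sum()))
        )
    summary = pd.DataFrame(
        rows,
        columns=["condition", "n_cells", "n_positive_calls",
                 "percent_expulsion", "n_unscorable"],
    )
    return ExpulsionResult(cells=df, summary=summary, threshold=float(threshold))


def match_traces_to_truth(traces, truth, max_distance: float = 15.0) -> dict[int, int]:
    """Greedy one-to-one matching of traces to ground-truth cells.

    Distance = mean centroid distance over the trace's frames; pairs beyond
    ``max_distance`` are forbidden.  Returns {trace cell_id: truth cell_id}.
    """
    pairs = []
    for tr in traces:
        f = tr.frames
        diffs = truth.centroids[:, f, :] - tr.centroids[None, :, :]
        d = np.linalg.norm(diffs, axis=2).mean(axis=1)
        for g in np.flatnonzero(d <= max_distance):
            pairs.append((float(d[g]), tr.cell_id, int(g)))
    pairs.sort()
    match: dict[int, int] = {}
    used_truth = set()
    for _, tid, gid in pairs:
        if tid in match or gid in used_truth:
            continue
        match[tid] = gid
        used_truth.add(gid)
    if traces and truth.n_cells and not match:
        raise MatchingError("no trace overlaps any ground-truth cell")
    return match


def evaluate_detection(result: ExpulsionResult, truth, traces,
                       max_distance: float = 15.0) -> dict:
    """Confusion summary of per-cell calls against simulator ground truth."""
    match = match_traces_to_truth(traces, truth, max_distance)
    calls = result.cells.set_index("cell_id")
    tp = fp = fn = tn = 0
    unmatched = 0
    for tr in traces:
        if tr.cell_id not in calls.index:
            continue
        row = calls.loc[tr.cell_id]
        if bool(row.get("unscorable", False)):
            continue
        gid = match.get(tr.cell_id)
        if gid is None:
            unmatched += 1
            continue
        truth_pos = bool(truth.cells.iloc[gid]["expelled"])
        call = bool(row["call"])
        tp += call and truth_pos
        fp += call and not truth_pos
        fn += (not call) and truth_pos
        tn += (not call) and (not truth_pos)
    sens = tp / (tp + fn) if tp + fn else float("nan")
    spec = tn / (tn + fp) if tn + fp else float("nan")
    return {
        "TP": tp, "FP": fp, "FN": fn, "TN": tn,
        "sensitivity": sens, "specificity": spec,
        "balanced_accuracy": np.nanmean([sens, spec]),
        "n_unmatched": unmatched,
    }
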