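"""Standard synthetic benchmark: paired positive/negative condition movies.

The positive ("wild-type-like") condition is all-apoptotic with a true
expelling fraction of 0.85; the negative ("knockout-like") condition is
apoptosis only — condensation and fragmentation with zero true expulsion.
Large populations are built from multiple independent 512x512 fields of
150 cells each so nuclei stay well separated at realistic density.

The full pipeline (simulate -> segment/merge -> track -> normalize -> score ->
ROC calibrate -> classify) runs in memory; every stage draws its randomness
from seeds derived from the single benchmark seed by counter.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .metric import (
    DEFAULT_BASELINE_WINDOW,
    DEFAULT_INTERVALS,
    normalize_traces,
    score_traces,
)
from .roc import build_roc, classify_and_summarize, select_threshold
from .segment import SegmentationParams, segment_movie
from .simulate import SimulationConfig, simulate_movie
from .track import TrackingParams, track_cells

__all__ = [
    "wt_like_config",
    "ko_like_config",
    "derive_seed",
    "run_condition",
    "calibrate_and_report",
    "FIELD_CELLS",
]

FIELD_CELLS = 150  # cells per 512x512 field


def _base_config(**overrides) -> SimulationConfig:
    cfg = SimulationConfig(
        frame_height=512,
        frame_width=512,
        n_cells=FIELD_CELLS,
        n_frames=60,
    )
    return dataclasses.replace(cfg, **overrides)


def wt_like_config(**overrides) -> SimulationConfig:
    """Positive condition: every cell apoptotic, 85% truly expelling."""
    return _base_config(fraction_apoptotic=1.0, fraction_expelling=0.85, **overrides)


def ko_like_config(**overrides) -> SimulationConfig:
    """Negative condition: apoptosis with fragmentation, zero true expulsion."""
    return _base_config(fraction_apoptotic=1.0, fraction_expelling=0.0, **overrides)


def derive_seed(*parts: int) -> int:
    """Deterministic sub-seed (< 2^31) from an integer tuple."""
    return int(np.random.SeedSequence(list(parts)).generate_state(1)[0] % (2**31))


def run_condition(
    config: SimulationConfig,
    n_cells_total: int,
    seed: int,
    condition: str,
    intervals=DEFAULT_INTERVALS,
    baseline_window=DEFAULT_BASELINE_WINDOW,
    seg_params: SegmentationParams | None = None,
    track_params: TrackingParams | None = None,
) -> pd.DataFrame:
    """Simulate, track and score ``n_cells_total`` cells of one condition.

    Cells are split across independent fields of ``config.n_cells`` each
    (field seeds derived by counter from ``seed``).  Returns the per-cell
    score table with a ``condition`` column; only traces that overlap the
    baseline window are scored, so late-born fragments do not inflate the
    denominator.
    """
    per_field = config.n_cells
    n_fields = int(np.ceil(n_cells_total / per_field))
    tables = []
    for k in range(n_fields):
        n_here = min(per_field, n_cells_total - k * per_field)
        cfg = dataclasses.replace(
            config, n_cells=n_here, seed=derive_seed(seed, k)
        )
        movie, _ = simulate_movie(cfg)
        frames = segment_movie(movie.channel("nuclear"), seg_params, "auto")
        traces = track_cells(frames, track_params)
        etraces, _ = normalize_traces(traces, baseline_window)
        tab = score_traces(etraces, intervals)
        tab["condition"] = condition
        tab["field"] = k
        tab["cell_id"] = tab["cell_id"] + 100_000 * k  # unique across fields
        tables.append(tab)
    return pd.concat(tables, ignore_index=True)


def calibrate_and_report(
    seed: int,
    n_cells: int = 2000,
    method: str = "youden",
    alpha: float | None = None,
    intervals=DEFAULT_INTERVALS,
) -> dict:
    """Paired positive/negative benchmark with ROC-calibrated threshold.

    Simulates ``n_cells`` per condition, fits the ROC with the positive
    condition's scores against the negative's, selects the threshold, and
    reports percent expulsion per condition.
    """
    wt = run_condition(wt_like_config(), n_cells, derive_seed(seed, 101),
                       "positive", intervals)
    ko = run_condition(ko_like_config(), n_cells, derive_seed(seed, 202),
                       "negative", intervals)
    wt_scores = wt.loc[~wt["unscorable"], "score"].to_numpy()
    ko_scores = ko.loc[~ko["unscorable"], "score"].to_numpy()
    roc = build_roc(wt_scores, ko_scores)
    threshold = select_threshold(roc, method=method, alpha=alpha)
    result = classify_and_summarize(pd.concat([wt, ko], ignore_index=True), threshold)
    summ = result.summary.set_index("condition")
    return {
        "seed": seed,
        "n_cells": n_cells,
        "auc": roc.auc,
        "threshold": threshold,
        "selection_method": roc.selection_method,
        "percent_expulsion_positive": float(
            summ.loc["positive", "percent_expulsion"]
        ),
        "percent_expulsion_negative": float(
            summ.loc["negative", "percent_expulsion"]
        ),
        "n_scored_positive": int(summ.loc["positive", "n_cells"]),
        "n_scored_negative": int(summ.loc["negative", "n_cells"]),
        "result": result,
        "roc": roc,
    }
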