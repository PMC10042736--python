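"""Chromatin-expansion traces and the max-gradient expulsion score.

A cell's area trace is normalized to its own pre-treatment baseline
(median area over the baseline window), giving the dimensionless chromatin
expansion e(t).  The expulsion score is the maximum numerical gradient of
e over a grid of time intervals,

    score = max over t, w in intervals of [e(t+w) - e(t)] / w ,

i.e. the steepest sustained increase in chromatin area, in expansion units
per frame.  Apoptotic condensation alone gives scores near zero or below;
nuclear expulsion gives large positive scores.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .track import CellTrace

__all__ = [
    "BaselineError",
    "ExpansionTrace",
    "ExpulsionScore",
    "normalize_trace",
    "normalize_traces",
    "expulsion_score",
    "score_traces",
    "median_expansion",
    "DEFAULT_INTERVALS",
    "DEFAULT_BASELINE_WINDOW",
]

log = logging.getLogger(__name__)

# Dyadic interval grid: short windows catch ionophore-fast expansion,
# long ones catch slow apoptotic (Raptinal-like) kinetics.
DEFAULT_INTERVALS: tuple[int, ...] = (1, 2, 4, 8)
DEFAULT_BASELINE_WINDOW: tuple[int, int] = (0, 10)  # half-open [start, stop)


class BaselineError(ValueError):
    """Trace cannot be baseline-normalized (reason in args[0])."""


@dataclass
class ExpansionTrace:
    cell_id: int
    frames: np.ndarray
    e: np.ndarray  # normalized area, dimensionless
    baseline_area: float  # pixels^2
    baseline_window: tuple[int, int]


@dataclass
class ExpulsionScore:
    cell_id: int
    score: float  # max gradient, expansion units / frame
    argmax_time: int | None  # t at which the max gradient starts
    argmax_interval: int | None  # the interval w attaining it
    n_frames: int
    unscorable: bool = False


def normalize_trace(
    trace: CellTrace, baseline_window: tuple[int, int] = DEFAULT_BASELINE_WINDOW
) -> ExpansionTrace:
    """e(t) = area(t) / median(area over baseline_window ∩ trace frames).

    Raises BaselineError("no-baseline") if the trace does not overlap the
    window, or BaselineError("nonpositive-baseline") if the median is <= 0.
    """
    lo, hi = baseline_window
    in_base = (trace.frames >= lo) & (trace.frames < hi)
    if not in_base.any():
        raise BaselineError("no-baseline")
    med = float(np.median(trace.areas[in_base]))
    if med <= 0:
        raise BaselineError("nonpositive-baseline")
    return ExpansionTrace(
        cell_id=trace.cell_id,
        frames=trace.frames.copy(),
        e=trace.areas / med,
        baseline_area=med,
        baseline_window=(lo, hi),
    )


def normalize_traces(
    traces: list[CellTrace],
    baseline_window: tuple[int, int] = DEFAULT_BASELINE_WINDOW,
) -> tuple[list[ExpansionTrace], Counter]:
    """Normalize a batch; excluded traces are tallied by reason, not raised."""
    out: list[ExpansionTrace] = []
    excluded: Counter = Counter()
    for tr in traces:
        try:
            out.append(normalize_trace(tr, baseline_window))
        except BaselineError as err:
            excluded[err.args[0]] += 1
    if excluded:
        log.info("normalize_traces excluded %s", dict(excluded))
    return out, excluded


def expulsion_score(
    etrace: ExpansionTrace, intervals: tuple[int, ...] = DEFAULT_INTERVALS
) -> ExpulsionScore:
    """Maximum forward difference [e(t+w) - e(t)]/w over the interval grid.

    Only frame pairs actually present in the trace are used (tracking gaps
    contribute nothing).  Ties are broken by earliest t, then smallest w.
    A trace shorter than every interval is flagged unscorable.
    """
    if any(w < 1 for w in intervals):
        raise ValueError("intervals must be >= 1 frame")
    frames = etrace.frames
    e = etrace.e
    pos = {int(f): k for k, f in enumerate(frames)}
    best = None  # (score, t, w)
    for w in sorted(set(int(w) for w in intervals)):
        for k, f in enumerate(frames):
            j = pos.get(int(f) + w)
            if j is None:
                continue
            g = (e[j] - e[k]) / w
            if best is None or g > best[0] or (
                g == best[0] and (f, w) < (best[1], best[2])
            ):
                best = (g, int(f), w)
    if best is None:
        return ExpulsionScore(etrace.cell_id, float("nan"), None, None,
                              len(frames), unscorable=True)
    return ExpulsionScore(etrace.cell_id, float(best[0]), best[1], best[2],
                          len(frames))


def score_traces(
    etraces: list[ExpansionTrace], intervals: tuple[int, ...] = DEFAULT_INTERVALS
) -> pd.DataFrame:
    """Score a batch of expansion traces into a tidy per-cell table."""
    rows = []
    for et in etraces:
        s = expulsion_score(et, intervals)
        rows.append((s.cell_id, s.score, s.argmax_time, s.argmax_interval,
                     s.n_frames, s.unscorable, float(np.nanmax(et.e))))
    return pd.DataFrame(
        rows,
        columns=["cell_id", "score", "argmax_time", "argmax_interval",
                 "n_frames", "unscorable", "max_expansion"],
    )


def median_expansion(
    etraces: list[ExpansionTrace],
    align: str = "absolute_frame",
    onsets: dict[int, int] | None = None,
) -> pd.DataFrame:
    """Per-frame median of e(t) over all traces present at that frame.

    ``align="onset_aligned"`` shifts each trace so its expulsion onset
    (``onsets[cell_id]``, typically the score's argmax_time) sits at 0; traces
    without an onset are dropped.  Frames with no contributing trace are
    omitted.  Returns columns (frame, median_e, n).
    """
    if not etraces:
        raise ValueError("median_expansion requires at least one trace")
    if align not in ("absolute_frame", "onset_aligned"):
        raise ValueError(f"unknown alignment {align!r}")
    frames_all = []
    e_all = []
    for et in etraces:
        f = et.frames.astype(int)
        if align == "onset_aligned":
            if onsets is None or et.cell_id not in onsets or onsets[et.cell_id] is None:
                continue
            f = f - int(onsets[et.cell_id])
        frames_all.append(f)
        e_all.append(et.e)
    if not frames_all:
        raise ValueError("no traces with a defined onset to align")
    df = pd.DataFrame({
        "frame": np.concatenate(frames_all),
        "e": np.concatenate(e_all),
    })
    out = df.groupby("frame")["e"].agg(median_e="median", n="size").reset_index()
    return out
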