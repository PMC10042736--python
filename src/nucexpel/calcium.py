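"""Per-cell calcium dynamics measured inside the nuclear (chromatin) mask.

The calcium-indicator channel is averaged over each tracked cell's nuclear
mask frame by frame, normalized to the cell's own pre-treatment baseline,
and scanned for a sustained spike.  Spike timing is then compared with the
cell's expulsion onset (the start frame of the maximal expansion gradient):
negative lag means the calcium spike precedes expulsion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .metric import DEFAULT_BASELINE_WINDOW
from .segment import LabeledFrame
from .simulate import MovieStack
from .track import CellTrace

__all__ = [
    "CalciumTrace",
    "SpikeEvent",
    "measure_calcium",
    "detect_spike",
    "spike_expulsion_lag",
]


@dataclass
class CalciumTrace:
    cell_id: int
    frames: np.ndarray
    raw: np.ndarray  # mean calcium intensity inside the nuclear mask
    baseline: float
    c: np.ndarray  # normalized series: fold over baseline (or bg-subtracted)
    mode: str = "fold"


@dataclass
class SpikeEvent:
    cell_id: int
    spike_frame: int
    peak_fold: float
    lag_vs_expulsion: int | None = None  # spike_frame - expulsion onset


def measure_calcium(
    stack: MovieStack,
    frames: list[LabeledFrame],
    traces: list[CellTrace],
    baseline_window: tuple[int, int] = DEFAULT_BASELINE_WINDOW,
    mode: str = "fold",
    channel: str = "calcium",
) -> list[CalciumTrace]:
    """Mean calcium inside each cell's mask, per frame, baseline-normalized.

    ``mode="fold"`` gives c(t) = raw/baseline; ``mode="bgsub"`` gives
    c(t) = raw - baseline.  Cells without baseline frames or with
    non-positive baseline are skipped.  Frames where the cell has no mask
    (tracking gap) are simply absent from the trace — missing, not zero.
    """
    if mode not in ("fold", "bgsub"):
        raise ValueError(f"unknown mode {mode!r}")
    ca = stack.channel(channel)  # raises if the channel is missing
    by_index = {lf.index: lf for lf in frames}
    # mean intensity per label per frame, computed once
    label_means: dict[int, dict[int, float]] = {}
    for t, lf in by_index.items():
        if lf.n_labels:
            means = ndi.mean(ca[t], lf.labels, lf.ids)
            label_means[t] = dict(zip((int(i) for i in lf.ids), np.atleast_1d(means)))
        else:
            label_means[t] = {}

    lo, hi = baseline_window
    out: list[CalciumTrace] = []
    for tr in traces:
        vals, kept = [], []
        for f, lab in zip(tr.frames, tr.labels):
            m = label_means.get(int(f), {}).get(int(lab))
            if m is not None:
                vals.append(float(m))
                kept.append(int(f))
        if not vals:
            continue
        raw = np.array(vals)
        kf = np.array(kept)
        in_base = (kf >= lo) & (kf < hi)
        if not in_base.any():
            continue
        baseline = float(np.median(raw[in_base]))
        if baseline <= 0:
            continue
        c = raw / baseline if mode == "fold" else raw - baseline
        out.append(CalciumTrace(tr.cell_id, kf, raw, baseline, c, mode))
    return out


def detect_spike(
    ctrace: CalciumTrace, spike_fold: float = 1.5, min_run: int = 2
) -> SpikeEvent | None:
    """First frame where c(t) >= spike_fold for min_run consecutive frames.

    Consecutive means consecutive frame indices; a tracking gap breaks the
    run.  Returns None when no qualifying run exists.
    """
    if min_run < 1:
        raise ValueError("min_run must be >= 1")
    f, c = ctrace.frames, ctrace.c
    n = len(f)
    run_start = None
    run_len = 0
    for k in range(n):
        hit = c[k] >= spike_fold
        contiguous = k > 0 and f[k] == f[k - 1] + 1
        if hit:
            if run_start is not None and contiguous:
                run_len += 1
            else:
                run_start, run_len = int(f[k]), 1
            if run_len >= min_run:
                return SpikeEvent(
                    ctrace.cell_id, run_start, peak_fold=float(np.max(c))
                )
        else:
            run_start, run_len = None, 0
    return None


def spike_expulsion_lag(
    spikes: list[SpikeEvent],
    onsets: dict[int, int | None],
    expelling_cells: set[int] | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Per-cell spike-vs-expulsion lags and a population summary.

    ``onsets`` maps cell_id to expulsion onset (the score's argmax_time).
    lag = spike_frame - onset; negative lag = spike first.  The fraction of
    cells with the spike preceding onset is computed over expelling cells
    (``expelling_cells``, default: all cells with an onset).  With no
    co-occurring events the summary has count 0.
    """
    rows = []
    for sp in spikes:
        onset = onsets.get(sp.cell_id)
        if onset is None:
            continue
        lag = int(sp.spike_frame) - int(onset)
        if expelling_cells is not None and sp.cell_id not in expelling_cells:
            continue
        sp.lag_vs_expulsion = lag
        rows.append((sp.cell_id, sp.spike_frame, onset, lag))
    df = pd.DataFrame(rows, columns=["cell_id", "spike_frame", "onset", "lag"])
    if len(df) == 0:
        return df, {"n": 0, "median_lag": None, "fraction_spike_first": None}
    return df, {
        "n": int(len(df)),
        "median_lag": float(df["lag"].median()),
        "fraction_spike_first": float((df["lag"] < 0).mean()),
    }
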