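"""Frame-to-frame linking of labeled nuclei into per-cell traces.

Linking is greedy nearest-neighbour on centroid distance: candidate
(trace, region) pairs within ``max_link_distance`` are sorted by distance,
ties broken by smaller area difference then lower label id, and assigned
one-to-one.  Traces missing from up to ``max_gap`` consecutive frames stay
alive; beyond that they are closed as lost.  Deterministic by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .segment import LabeledFrame

__all__ = ["TrackingParams", "CellTrace", "track_cells", "traces_to_frame"]

END_REASONS = ("movie_end", "lost", "lysed")


@dataclass
class TrackingParams:
    max_link_distance: float = 12.0  # pixels
    max_gap: int = 2  # frames a cell may vanish and still be re-linked


@dataclass
class CellTrace:
    """One tracked cell: per-frame centroid, area and mean nuclear intensity.

    ``labels`` records the region label at each frame so downstream stages
    (e.g. calcium measurement) can recover the cell's mask pixels.
    """

    cell_id: int
    frames: np.ndarray  # strictly increasing frame indices
    labels: np.ndarray
    centroids: np.ndarray  # (n, 2) row, col
    areas: np.ndarray  # pixels^2
    mean_intensity: np.ndarray  # nuclear channel
    end_reason: str = "movie_end"

    def __len__(self) -> int:
        return len(self.frames)


class _Builder:
    __slots__ = ("cell_id", "frames", "labels", "cents", "areas", "mi")

    def __init__(self, cell_id: int):
        self.cell_id = cell_id
        self.frames: list[int] = []
        self.labels: list[int] = []
        self.cents: list[np.ndarray] = []
        self.areas: list[float] = []
        self.mi: list[float] = []

    def add(self, frame: int, label: int, cent, area: float, mi: float):
        self.frames.append(frame)
        self.labels.append(int(label))
        self.cents.append(np.asarray(cent, float))
        self.areas.append(float(area))
        self.mi.append(float(mi))

    def finish(self, end_reason: str) -> CellTrace:
        return CellTrace(
            cell_id=self.cell_id,
            frames=np.array(self.frames, dtype=int),
            labels=np.array(self.labels, dtype=int),
            centroids=np.vstack(self.cents),
            areas=np.array(self.areas),
            mean_intensity=np.array(self.mi),
            end_reason=end_reason,
        )


def track_cells(
    frames: list[LabeledFrame], params: TrackingParams | None = None
) -> list[CellTrace]:
    """Link labeled frames into traces; see module docstring for the rule."""
    if not frames:
        raise ValueError("empty frame sequence")
    params = params or TrackingParams()

    done: list[CellTrace] = []
    active: list[_Builder] = []
    next_id = 0

    first = frames[0]
    for j in range(first.n_labels):
        b = _Builder(next_id)
        next_id += 1
        b.add(first.index, first.ids[j], first.centroids[j], first.areas[j],
              first.mean_intensity[j])
        active.append(b)

    for lf in frames[1:]:
        t = lf.index
        # close traces that have been unmatched for more than max_gap frames
        still = []
        for b in active:
            if t - b.frames[-1] - 1 > params.max_gap:
                done.append(b.finish("lost"))
            else:
                still.append(b)
        active = still

        n_obj = lf.n_labels
        if n_obj and active:
            last_c = np.vstack([b.cents[-1] for b in active])
            last_a = np.array([b.areas[-1] for b in active])
            d = np.linalg.norm(last_c[:, None, :] - lf.centroids[None, :, :], axis=2)
            cand = np.argwhere(d <= params.max_link_distance)
            order = sorted(
                (
                    (
                        d[i, j],
                        abs(last_a[i] - lf.areas[j]),
                        int(lf.ids[j]),
                        active[i].cell_id,
                        i,
                        j,
                    )
                    for i, j in cand
                ),
            )
            used_tr = set()
            used_obj = set()
            for _, _, _, _, i, j in order:
                if i in used_tr or j in used_obj:
                    continue
                used_tr.add(i)
                used_obj.add(j)
                active[i].add(t, lf.ids[j], lf.centroids[j], lf.areas[j],
                              lf.mean_intensity[j])
        else:
            used_obj = set()
        for j in range(n_obj):
            if j not in used_obj:
                b = _Builder(next_id)
                next_id += 1
                b.add(t, lf.ids[j], lf.centroids[j], lf.areas[j],
                      lf.mean_intensity[j])
                active.append(b)

    done.extend(b.finish("movie_end") for b in active)
    done.sort(key=lambda tr: tr.cell_id)
    return done


def traces_to_frame(traces: list[CellTrace]) -> pd.DataFrame:
    """Long-format table: one row per (cell, frame)."""
    rows = []
    for tr in traces:
        for k in range(len(tr)):
            rows.append(
                (tr.cell_id, int(tr.frames[k]), int(tr.labels[k]),
                 tr.centroids[k, 0], tr.centroids[k, 1], tr.areas[k],
                 tr.mean_intensity[k], tr.end_reason)
            )
    return pd.DataFrame(
        rows,
        columns=["cell_id", "frame", "label", "row", "col",
                 "area_px2", "mean_ch0", "end_reason"],
    )
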