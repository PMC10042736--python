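"""Reading and writing of movies, label images and trace/score tables."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .segment import LabeledFrame
from .simulate import MovieStack
from .track import CellTrace, traces_to_frame

__all__ = [
    "save_movie",
    "load_movie",
    "save_labels",
    "save_traces",
    "load_traces",
    "save_ground_truth",
]


def save_movie(stack: MovieStack, path) -> None:
    """Write a channel-first (C, T, Y, X) TIFF with metadata."""
    meta = {
        "axes": "CTYX",
        "channel_names": stack.channel_names,
        "frame_interval_min": stack.frame_interval,
        "pixel_size_um": stack.pixel_size,
    }
    tifffile.imwrite(str(path), stack.data, metadata=meta)


def load_movie(path) -> MovieStack:
    with tifffile.TiffFile(str(path)) as tf:
        data = tf.asarray()
        meta = tf.shaped_metadata[0] if tf.shaped_metadata else {}
    if data.ndim == 3:  # single channel
        data = data[None]
    return MovieStack(
        data=np.asarray(data, dtype=np.float32),
        channel_names=list(meta.get("channel_names", [f"ch{i}" for i in range(data.shape[0])])),
        frame_interval=float(meta.get("frame_interval_min", 1.0)),
        pixel_size=meta.get("pixel_size_um"),
    )


def save_labels(frames: list[LabeledFrame], path) -> None:
    """16-bit label-image stack, one plane per frame."""
    arr = np.stack([f.labels.astype(np.uint16) for f in frames])
    tifffile.imwrite(str(path), arr, metadata={"axes": "TYX"})


def save_traces(traces: list[CellTrace], path) -> None:
    traces_to_frame(traces).to_csv(path, index=False, float_format="%.6g")


def load_traces(path) -> list[CellTrace]:
    df = pd.read_csv(path)
    out = []
    for cid, grp in df.groupby("cell_id", sort=True):
        grp = grp.sort_values("frame")
        out.append(
            CellTrace(
                cell_id=int(cid),
                frames=grp["frame"].to_numpy(int),
                labels=grp["label"].to_numpy(int),
                centroids=grp[["row", "col"]].to_numpy(float),
                areas=grp["area_px2"].to_numpy(float),
                mean_intensity=grp["mean_ch0"].to_numpy(float),
                end_reason=str(grp["end_reason"].iloc[0]),
            )
        )
    return out


def save_ground_truth(truth, outdir: Path, stem: str = "ground_truth") -> Path:
    outdir = Path(outdir)
    path = outdir / f"{stem}.csv"
    truth.to_csv(path)
    return path


def write_json(obj, path) -> None:
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=default))
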