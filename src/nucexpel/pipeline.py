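"""End-to-end orchestration: simulate -> track -> score -> calibrate -> calcium.

One JSON-able config drives every stage; all randomness flows from the single
config seed.  The run manifest records the seed, a parameter echo, and a
SHA-256 content hash of every artifact written, so identical config + seed
reproduce identical manifests bit for bit.
"""

from __future__ import annotations

import hashlib
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .calcium import detect_spike, measure_calcium, spike_expulsion_lag
from .io import save_ground_truth, save_labels, save_movie, save_traces, write_json
from .metric import (
    DEFAULT_BASELINE_WINDOW,
    DEFAULT_INTERVALS,
    median_expansion,
    normalize_traces,
    score_traces,
)
from .roc import build_roc, classify_and_summarize, select_threshold
from .segment import SegmentationParams, segment_movie
from .simulate import SimulationConfig, simulate_movie
from .track import TrackingParams, track_cells

__all__ = ["run_pipeline", "render_summary", "DEFAULT_PIPELINE_CONFIG"]

log = logging.getLogger(__name__)

DEFAULT_PIPELINE_CONFIG: dict = {
    "seed": 0,
    "outdir": "pipeline_out",
    "stages": {"calcium": True, "calibrate": True},
    "conditions": [
        {"name": "positive", "role": "positive",
         "simulation": {"fraction_apoptotic": 1.0, "fraction_expelling": 0.85}},
        {"name": "negative", "role": "negative",
         "simulation": {"fraction_apoptotic": 1.0, "fraction_expelling": 0.0}},
    ],
    "simulation": {},  # shared SimulationConfig overrides
    "segmentation": {},  # SegmentationParams overrides
    "tracking": {},  # TrackingParams overrides
    "scoring": {"intervals": list(DEFAULT_INTERVALS),
                "baseline_window": list(DEFAULT_BASELINE_WINDOW)},
    "roc": {"method": "youden", "alpha": None},
    "calcium": {"spike_fold": 1.5, "min_run": 2, "mode": "fold"},
}


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _merged(defaults: dict, override: dict | None) -> dict:
    out = dict(defaults)
    out.update(override or {})
    return out


def run_pipeline(config: dict) -> dict:
    """Execute the enabled stages in order and return the run manifest.

    Any stage failure propagates with the stage name in the log; inputs are
    validated before compute starts.  The manifest lists every artifact with
    its content hash.
    """
    cfg = _merged(DEFAULT_PIPELINE_CONFIG, config)
    for key in ("stages", "scoring", "roc", "calcium"):
        cfg[key] = _merged(DEFAULT_PIPELINE_CONFIG[key], config.get(key))
    seed = int(cfg["seed"])
    outdir = Path(cfg["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    stages = cfg["stages"]
    intervals = tuple(cfg["scoring"]["intervals"])
    baseline_window = tuple(cfg["scoring"]["baseline_window"])
    seg_params = SegmentationParams(**cfg.get("segmentation") or {})
    track_params = TrackingParams(**cfg.get("tracking") or {})

    artifacts: list[Path] = []
    stage_log: list[str] = []
    all_scores = []
    etraces_by_cond = {}
    roles = {}

    for ci, cond in enumerate(cfg["conditions"]):
        name = cond["name"]
        roles[name] = cond.get("role", "test")
        sim_kwargs = _merged(cfg.get("simulation") or {}, cond.get("simulation"))
        sim_kwargs.setdefault("calcium_enabled", bool(stages.get("calcium", False)))
        sim_cfg = SimulationConfig.from_dict(
            {**sim_kwargs, "seed": int(
                np.random.SeedSequence([seed, ci]).generate_state(1)[0] % (2**31)
            )}
        )
        sim_cfg.validate()

        log.info("stage simulate [%s]", name)
        movie, truth = simulate_movie(sim_cfg)
        (outdir / name).mkdir(exist_ok=True)
        mv = outdir / name / "movie.tif"
        save_movie(movie, mv)
        gt = save_ground_truth(truth, outdir / name)
        cj = outdir / name / "sim_config.json"
        cj.write_text(sim_cfg.to_json())
        artifacts += [mv, gt, cj]
        stage_log.append(f"simulate[{name}]: {truth.n_cells} cells, "
                         f"{movie.n_frames} frames")

        log.info("stage track [%s]", name)
        frames = segment_movie(movie.channel("nuclear"), seg_params, "auto")
        traces = track_cells(frames, track_params)
        lb = outdir / name / "labels.tif"
        save_labels(frames, lb)
        tr = outdir / name / "traces.csv"
        save_traces(traces, tr)
        artifacts += [lb, tr]
        stage_log.append(f"track[{name}]: {len(traces)} traces")

        log.info("stage score [%s]", name)
        etraces, excluded = normalize_traces(traces, baseline_window)
        tab = score_traces(etraces, intervals)
        tab["condition"] = name
        sc = outdir / name / "scores.csv"
        tab.to_csv(sc, index=False, float_format="%.6g")
        artifacts.append(sc)
        stage_log.append(
            f"score[{name}]: {len(etraces)} scored, excluded {dict(excluded)}"
        )
        all_scores.append(tab)
        etraces_by_cond[name] = etraces

        if stages.get("calcium", False):
            log.info("stage calcium [%s]", name)
            ctraces = measure_calcium(movie, frames, traces, baseline_window,
                                      mode=cfg["calcium"]["mode"])
            spikes = [
                s for s in (
                    detect_spike(ct, cfg["calcium"]["spike_fold"],
                                 cfg["calcium"]["min_run"])
                    for ct in ctraces
                ) if s is not None
            ]
            onsets = {
                int(r.cell_id): (int(r.argmax_time) if pd.notna(r.argmax_time) else None)
                for r in tab.itertuples()
            }
            lag_df, lag_summary = spike_expulsion_lag(spikes, onsets)
            ca_rows = pd.DataFrame(
                [(ct.cell_id, f, r, c)
                 for ct in ctraces for f, r, c in zip(ct.frames, ct.raw, ct.c)],
                columns=["cell_id", "frame", "raw", "normalized"],
            )
            cp = outdir / name / "calcium_traces.csv"
            ca_rows.to_csv(cp, index=False, float_format="%.6g")
            lp = outdir / name / "calcium_lags.csv"
            lag_df.to_csv(lp, index=False)
            ls = outdir / name / "calcium_summary.json"
            write_json(lag_summary, ls)
            artifacts += [cp, lp, ls]
            stage_log.append(
                f"calcium[{name}]: {len(ctraces)} traces, {len(spikes)} spikes"
            )

    scores = pd.concat(all_scores, ignore_index=True)
    threshold = None
    roc_auc = None
    if stages.get("calibrate", True):
        pos = [n for n, r in roles.items() if r == "positive"]
        neg = [n for n, r in roles.items() if r == "negative"]
        if not pos or not neg:
            raise ValueError("calibrate stage needs a positive and a negative condition")
        ps = scores.query("condition in @pos and ~unscorable")["score"].to_numpy()
        ns = scores.query("condition in @neg and ~unscorable")["score"].to_numpy()
        roc = build_roc(ps, ns)
        threshold = select_threshold(
            roc, cfg["roc"]["method"], alpha=cfg["roc"].get("alpha"),
            fixed_value=cfg["roc"].get("fixed_value"),
        )
        roc_auc = roc.auc
        rp = outdir / "roc.csv"
        roc.as_frame().to_csv(rp, index=False, float_format="%.8g")
        artifacts.append(rp)
        stage_log.append(f"calibrate: auc={roc.auc:.4f} threshold={threshold:.4f}")

        result = classify_and_summarize(scores, threshold)
        summary_paths = render_summary(result, etraces_by_cond, outdir)
        artifacts += summary_paths
        stage_log.append("report: summary tables written")

    manifest = {
        "package_version": __version__,
        "seed": seed,
        "parameters": {k: v for k, v in cfg.items() if k != "outdir"},
        "threshold": threshold,
        "auc": roc_auc,
        "stage_log": stage_log,
        "artifacts": {
            str(p.relative_to(outdir)): _sha256(p) for p in sorted(artifacts)
        },
    }
    write_json(manifest, outdir / "manifest.json")
    return manifest


def render_summary(result, etraces_by_cond: dict, outdir: Path,
                   bins=None, plot: bool = False) -> list[Path]:
    """Figure-style summary tables: expansion histogram, median curves,
    percent-expulsion per condition.  Optional matplotlib plots."""
    outdir = Path(outdir)
    paths = []
    cells = result.cells
    if bins is None:
        bins = np.linspace(0.0, 6.0, 25)
    hist_rows = []
    for cond, grp in cells[~cells["unscorable"]].groupby("condition"):
        counts, edges = np.histogram(grp["max_expansion"].clip(upper=bins[-1]), bins=bins)
        for lo, hi, n in zip(edges[:-1], edges[1:], counts):
            hist_rows.append((cond, lo, hi, int(n)))
    hist = pd.DataFrame(hist_rows, columns=["condition", "bin_lo", "bin_hi", "count"])
    hp = outdir / "expansion_histogram.csv"
    hist.to_csv(hp, index=False, float_format="%.6g")
    paths.append(hp)

    med_rows = []
    for cond, etr in etraces_by_cond.items():
        if not etr:
            continue
        med = median_expansion(etr)
        med["condition"] = cond
        med_rows.append(med)
    if med_rows:
        med_all = pd.concat(med_rows, ignore_index=True)
        mp = outdir / "median_expansion.csv"
        med_all.to_csv(mp, index=False, float_format="%.6g")
        paths.append(mp)

    sp = outdir / "percent_expulsion.csv"
    result.summary.to_csv(sp, index=False, float_format="%.6g")
    paths.append(sp)

    if plot:  # pragma: no cover - optional figures
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, axes = plt.subplots(1, 3, figsize=(13, 3.5))
        for cond, grp in hist.groupby("condition"):
            axes[0].stairs(grp["count"], np.r_[grp["bin_lo"], grp["bin_hi"].iloc[-1]],
                           label=cond)
        axes[0].set(xlabel="max chromatin expansion", ylabel="cells")
        axes[0].legend()
        if med_rows:
            for cond, grp in med_all.groupby("condition"):
                axes[1].plot(grp["frame"], grp["median_e"], label=cond)
            axes[1].set(xlabel="frame", ylabel="median expansion")
            axes[1].legend()
        axes[2].bar(result.summary["condition"], result.summary["percent_expulsion"])
        axes[2].set(ylabel="% expulsion")
        fig.tight_layout()
        fig.savefig(outdir / "summary.png", dpi=120)
        plt.close(fig)
        paths.append(outdir / "summary.png")
    return paths
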