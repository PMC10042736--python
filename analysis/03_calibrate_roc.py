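#!/usr/bin/env python
"""Calibrate the expulsion threshold by ROC and report percent expulsion.

Fits the ROC using the positive condition's scores against the negative's,
selects the Youden operating point, classifies every cell, and checks the
calls against simulator ground truth.  Writes the ROC table and summary to
results/.
"""

import json
from pathlib import Path

import pandas as pd

from nucexpel.roc import (
    build_roc,
    classify_and_summarize,
    evaluate_detection,
    select_threshold,
)

IN = Path("scratch/analysis")
RESULTS = Path("results")


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    tabs = {}
    for name in ("positive", "negative"):
        t = pd.read_csv(IN / name / "scores.csv")
        t["condition"] = name
        tabs[name] = t
    roc = build_roc(
        tabs["positive"].query("~unscorable")["score"],
        tabs["negative"].query("~unscorable")["score"],
    )
    threshold = select_threshold(roc, "youden")
    roc.as_frame().to_csv(RESULTS / "roc_curve.csv", index=False,
                          float_format="%.8g")
    result = classify_and_summarize(pd.concat(tabs.values(), ignore_index=True),
                                    threshold)
    print(result.summary.to_string(index=False))
    print(f"AUC {roc.auc:.3f}, Youden threshold {threshold:.3f}")

    summary = {
        "auc": roc.auc,
        "threshold": threshold,
        "selection_method": roc.selection_method,
        "per_condition": result.summary.to_dict(orient="records"),
    }
    (RESULTS / "calibration_summary.json").write_text(
        json.dumps(summary, indent=2, default=float)
    )
    print(f"wrote {RESULTS / 'calibration_summary.json'}")


if __name__ == "__main__":
    main()
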