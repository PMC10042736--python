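# nucexpel

Quantification of **apoptosis-induced nuclear expulsion** in single-cell
fluorescence time-lapse movies.

Dying tumor cells that express the calcium-dependent enzyme Padi4 can expel
their decondensed chromatin into the extracellular space. In a movie of an
H2B-GFP-like chromatin reporter this appears as a stereotyped sequence —
baseline, apoptotic condensation/fragmentation, then a rapid several-fold
expansion of the chromatin signal area — often preceded by a nuclear
calcium spike. `nucexpel` is for imaging groups who need to score this
phenotype over thousands of single cells: it segments and tracks nuclei,
converts each cell's area trace into a baseline-normalized chromatin
expansion `e(t)`, computes the per-cell **expulsion score**

```
score = max over t, w ∈ {1,2,4,8} of  [e(t+w) − e(t)] / w
```

(the maximum numerical gradient of expansion over a grid of time
intervals), calibrates a detection threshold from the ROC of a positive
(wild-type-like) against a negative (knockout-like) population, and
reports percent expulsion per condition plus calcium-spike-to-expulsion
timing. Because the original imaging data are not public, a seeded
simulator with per-cell ground truth is part of the package and backs the
entire test and benchmark suite.

## Worked example

```python
from nucexpel import (SimulationConfig, simulate_movie, segment_movie,
                      track_cells, normalize_traces, score_traces,
                      build_roc, select_threshold, classify_and_summarize)
import dataclasses, pandas as pd

wt = SimulationConfig(frame_height=512, frame_width=512, n_cells=150,
                      fraction_apoptotic=1.0, fraction_expelling=0.85,
                      calcium_enabled=True, seed=1)
ko = dataclasses.replace(wt, fraction_expelling=0.0, seed=2)

tables = {}
for name, cfg in [("positive", wt), ("negative", ko)]:
    movie, truth = simulate_movie(cfg)
    frames = segment_movie(movie.channel("nuclear"))   # per-object half-max
    traces = track_cells(frames)
    etraces, _ = normalize_traces(traces)              # e(t), baseline frames 0-9
    tab = score_traces(etraces)
    tab["condition"] = name
    tables[name] = tab

roc = build_roc(tables["positive"]["score"], tables["negative"]["score"])
thr = select_threshold(roc, "youden")
result = classify_and_summarize(pd.concat(tables.values()), thr)
print(f"AUC {roc.auc:.3f}, threshold {thr:.3f}")
print(result.summary.to_string(index=False))
```

Output from this configuration (seeds as shown):

```
AUC 0.917, threshold 0.498
condition  n_cells  n_positive_calls  percent_expulsion  n_unscorable
 negative      150                 0           0.000000             0
 positive      150               125          83.333333             0
```

86.0% of positive-condition cells truly expel in this realization; the
calibrated detector calls 83.3% — and 0% of the negative condition, whose
cells condense and fragment but never expand. Measuring the calcium channel
inside the same nuclear masks and timing sustained ≥1.5× spikes against
each cell's expulsion onset gives a median lag of −8 frames (spike first),
recovering the simulator's configured 8-frame lead; negative-condition
cells spike too but are never called expelling, so their lag summary is
empty. The numbered drivers under `analysis/` rerun exactly this sequence
(`01_simulate_conditions.py` … `05_population_benchmark.py`) and write the
tables to `results/`.

A command-line interface mirrors the stages
(`nucexpel simulate | track | score | calibrate | report | calcium | run`);
`nucexpel run --config pipeline.json` executes the whole pipeline and
writes a manifest with content hashes that reproduce bit-for-bit for a
given config and seed.

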