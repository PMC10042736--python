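# Methods

## The phenotype and the statistic

Apoptotic tumor cells carrying a chromatin reporter (H2B-GFP or H2B-mCherry)
can, in a Padi4-dependent manner, expel their decondensed nucleus into the
extracellular space. In a time-lapse movie this reads out as a
characteristic area signature of the chromatin signal: stable baseline →
apoptotic condensation (area shrinks, signal brightens) and often
fragmentation into apoptotic bodies → rapid decondensation in which the
signal area grows several-fold within a few frames while the signal dims.

`nucexpel` quantifies this per cell. Each tracked cell's area trace
`area(t)` is normalized to its own pre-treatment baseline,

    e(t) = area(t) / median(area over the baseline window),

and the **expulsion score** is the maximum numerical gradient of `e` over a
grid of time intervals `W`:

    score = max over t, w in W of [ e(t+w) − e(t) ] / w .

The score is a per-frame expansion rate: condensation and tracking jitter
give values near zero (or negative), expulsion gives large positive values.
A detection threshold is calibrated on the ROC built from a known-positive
population (wild-type-like) against a known-negative one (knockout-like),
and a cell is called expelling when `score > threshold` (ties negative).

`W = {1, 2, 4, 8}` frames by default: a dyadic grid spans both
ionophore-fast and slower drug-induced kinetics. The gradient is a plain
forward difference, not a smoothed derivative — it is exactly "maximum
increase in size per unit time" and is checkable against exhaustive search.

## Synthetic movies and what they do (not) emulate

Real imaging data for this phenotype are not public, so the package ships a
simulator that is itself first-class, tested code. Defaults describe the
benchmark conditions used throughout:

| parameter | default | meaning |
|---|---|---|
| frame size / count | 256–512 px², 60 frames | one field of view, single z-plane |
| frame_interval | 3 min | metadata only; scores are per frame |
| baseline radius | 7 ± 1 px | nuclear equivalent radius |
| fraction_apoptotic | 1.0 | all cells die (drug-treated assay) |
| fraction_expelling | 0.85 | positive condition; 0 for negative |
| condensation_fold | 0.6 | apoptotic area shrinkage |
| expansion_fold | 3.0 | target area fold-change at full decondensation |
| expansion_duration | 6 frames | onset-to-plateau time |
| fragmentation_prob | 0.5 | chance of splitting into 2–4 apoptotic bodies |
| background / amplitude | 20 / 300 | camera units; Poisson + Gaussian read noise (σ=2) |
| drift_sd | 0.3 px/frame | random-walk cell motion (starved, low motility) |
| calcium_spike_lead | 8 frames | spike precedes expulsion onset |
| calcium_spike_fold | 3.0 | sustained fold-change of the indicator |

Design choices that matter:

- **Blob profile.** Nuclei are anisotropic *super-Gaussian* blobs,
  `exp(−(q/2)⁴)` with `q` the Mahalanobis quadratic form, calibrated so the
  area above half-maximum equals the nominal area. A pure Gaussian was
  rejected: its thresholded area varies logarithmically with the threshold,
  so no segmentation could recover ground-truth areas to 10%. The
  super-Gaussian keeps a soft, nontrivial shoulder while bounding the
  area-vs-threshold sensitivity to a few percent.
- **Intensity conservation.** Total integrated blob intensity is constant
  through condensation and expansion: condensed nuclei brighten ~1.7×,
  fully decondensed chromatin dims ~3×. Chromatin is redistributed, not
  synthesized — and this brightness mixing is exactly what makes global
  thresholding fail (below).
- **Concave expansion ramp.** Area grows along a saturating exponential
  (fastest at onset, plateau at `expansion_fold`). This is the observed
  shape of a rapid burst and pins the maximal gradient — hence the score's
  `argmax_time` — to the onset frame, which is what makes spike-vs-onset
  lags recoverable to ±1–2 frames.
- **Fragmentation.** Bodies are placed 0.25–0.7 baseline radii from the
  parent centroid so that their pairwise distances stay below the default
  fragment-merge radius; one dying cell then remains one tracked object.
- **Seeding.** One master seed; per-cell substreams are derived by counter
  (`SeedSequence(seed, spawn_key=(1, i))`), so adding cells leaves earlier
  cells' trajectories bit-identical. Output is a pure function of config.

Not emulated: photobleaching, 3-D structure, cell division or birth,
neighbor contact/overlap, uneven illumination, and the fibrous texture of
expelled chromatin. Passing benchmarks therefore demonstrate the
*algorithmic* correctness of the pipeline under realistic noise, drift and
fragmentation — not robustness to every artifact of real microscopy.

## Segmentation and tracking

Frames are Gaussian-smoothed (σ = 1 px) and thresholded. The default
threshold is **per-object half-max**: objects are detected above a
permissive background-referenced floor (background = image median, noise =
scaled MAD), then each connected object is re-cut at
`background + 0.5 × (object peak − background)`. Global methods (Otsu, Li —
both available as options) fail structurally here: once expulsion begins, a
frame mixes bright condensed nuclei with ~3× dimmer decondensed chromatin,
the histogram becomes trimodal, and Otsu places its threshold *between the
two foreground classes*, deleting every expanded cell at onset. The
per-object cut is brightness-invariant and, with the half-max-calibrated
blob profile, recovers ground-truth areas within 10% down to 5 px radius.

Regions below `min_area` (20 px²) are dropped. Apoptotic bodies are merged
by single-linkage closure of centroids within `merge_radius` (default 2×
the median baseline equivalent radius, estimated from frame 0); merging
iterates with recomputed area-weighted centroids to a fixed point, which
makes it idempotent. Linking is greedy nearest-neighbor on centroid
distance (candidates sorted by distance, then |Δarea|, then label id;
links beyond 12 px forbidden; gaps up to 2 frames bridged). At the
benchmark's low motility this coincides with optimal assignment.

The expulsion-phase mask is whatever the threshold covers — no convex
hull — because the measured quantity is the area of chromatin signal.

## ROC calibration

`build_roc` sweeps all distinct scores (±∞ endpoints); trapezoid AUC equals
the Mann–Whitney pair statistic exactly, ties counted ½. The default
operating point is Youden's J (ties → higher threshold, then the midpoint
of the flat interval, i.e. of the separating gap when populations
separate); `fixed_fpr(α)` and a fixed passthrough are provided. Calibration
classes are whole conditions — every positive-condition cell counts as
class 1 even though ~15% truly die without expelling — which is why
false-positive rates up to 15–20% are the realistic regime for this design
and why reports always print the threshold and rule used.

## Calcium timing

The calcium channel is averaged inside each cell's nuclear mask per frame
and normalized to the cell's baseline median (`fold` mode; a
background-subtracted mode is also provided since published curves could be
either). A spike is the first frame with `c(t) ≥ 1.5` sustained for 2
consecutive frames (gaps break the run). Expulsion onset is operationalized
as the score's `argmax_time` — the start of the maximal-gradient interval —
since the score is the only time the detector already produces. The lag is
`spike_frame − onset`; negative means calcium first. On simulated movies
the median lag recovers `−calcium_spike_lead` to within ±2 frames for
leads of 4–16 frames.

## Numerical and degenerate-input conventions

Coordinates are 0-based (row, col); areas in px²; frames 0-based; the
baseline window is half-open `[0, 10)` (frames before treatment at frame
10). Score ties break to earliest `t`, then smallest `w`. Traces that never
overlap the baseline window (e.g. objects born mid-movie) are excluded and
tallied, not scored — this also keeps late-appearing fragments out of the
percent-expulsion denominator. Blank or constant frames segment to zero
labels; non-finite pixels and empty score lists are input errors. Unscorable
cells (trace shorter than every interval) are excluded from denominators
and reported separately.

## Problem sizes

The standard population benchmark uses 2,000 cells per condition per seed
(three seeds), built from independent 512×512 fields of 150 cells; this
keeps nuclei well separated at realistic density while the full
simulate→track→score→calibrate chain stays in the minutes range. Calcium
lag recovery uses 20 runs × 25 cells per lead. These sizes are the
package's benchmark definition; all are configurable.

## Known limitations

- Greedy linking has no motion model; it would fragment tracks at high
  motility or density.
- The half-max rule assumes one dominant peak per object; genuinely
  touching nuclei need `split_touching` (marker-based watershed).
- Expulsion onset = argmax of the gradient, which for very slow expansion
  can sit a frame or two after the visual onset.
- The simulator's calcium channel is a flat-top cell-body blob; subcellular
  calcium structure is out of scope.
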