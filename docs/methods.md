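# Methods

This note documents the models, parameters and design choices behind
`celstain`, in the spirit of a package vignette: what is computed, under
which assumptions, and what the synthetic benchmarks do and do not show.

## Probe noise scores

A probe's score is the log fold-change against a control,
s_j = log2((v_j + c)/(v'_j + c)). The pseudocount c is the platform's
estimated detection limit; it bounds scores for near-zero intensities and
sets the scale below which differences are considered noise. Default
c = 16, appropriate for ST-style arrays; it is exposed everywhere because
it is platform-dependent. Scores default to absolute values for detection
(a stain can in principle depress intensities, and thresholding |s| keeps
the criterion one-sided); signed scores are retained for diagnostic plots,
where the sign distinguishes inflation from depletion.

Three controls are supported, in decreasing order of preference:

1. a clean replicate, loess-normalized against the suspect array first;
2. the fitted biological control λ1·N + λ2·P for total-RNA arrays from
   4sU labeling experiments (T ≈ N + P up to fraction-size factors);
3. the per-probe median across all replicates when nothing cleaner exists
   (the classic error-image control).

A fourth channel uses absolute median-polish residuals (below) instead of
fold-changes.

## Window criterion

Stains are spatially contiguous, so per-probe scores are smoothed over a
(2k+1)×(2k+1) window with weights 1/d(p, j) (Euclidean distance in probe
units) and weight 2 for the center probe; windows truncate at array
borders. Defaults k = 25 and self-weight 2. Distances use unit grid
spacing; physical feature sizes are ignored.

Implementation: two translation-invariant correlations — numerator
kernel⊛s and denominator kernel⊛1, both zero-padded — whose ratio equals
the border-truncated weighted average exactly, because out-of-bounds
positions contribute zero weight to both sums. Direct (spatial-domain)
correlation is used rather than FFT so results track the naive double loop
to ~1e-13; the literal loop is retained as a test oracle. A degenerate 1×1
grid is allowed (the window is the self term); otherwise k must be smaller
than the larger grid dimension.

## Thresholding

ε(s_j) is true iff s_j > t, strictly: a probe exactly at the threshold is
clean. There is no automatic threshold selection — operating points should
be read off probe-noise plots, replicate scatter plots and the
count-vs-threshold table; a score-quantile default (99.9th percentile) is
provided as a labeled convenience only. Flag sets are monotone in t by
construction.

## Normalization

* **Quantile normalization** maps every array onto the mean of the
  per-array sorted intensity vectors. Tied input values receive the mean
  of the reference values over their tied ranks — symmetric and
  order-independent; with ties the output distributions therefore differ
  minutely from the tie-free reference.
* **Loess pairwise normalization** removes the trend of
  M = log2(t/c) on A = ½·log2(t·c): locally linear, span 2/3, two
  robustness iterations. Above 50,000 probes the trend is fitted on a
  seeded random subsample and linearly interpolated (with a lowess `delta`
  of 0.003× the A-range), keeping multi-million-probe grids tractable.
  Replicate fold-change scoring applies loess only — no quantile step —
  since the comparison is a single pair and quantile normalization would
  couple the suspect array's stain into the control. The alternative
  (quantile first, then loess) was considered and not adopted.
* **RNA-fraction model**: (λ1, λ2) minimize Σ(T − λ1·N − λ2·P)² subject to
  λ ≥ 0, solved by nonnegative least squares; where the unconstrained
  optimum is already nonnegative the two coincide. Collinear N, P is a
  rank-deficiency error.

## Summarization

Tukey median polish on each probeset's log2 probe×array matrix: row sweep
first, then column sweep, at most 10 rounds, stopping when the total
absolute residual changes by less than 0.01. The chip effect μ + c_j is
the probeset's expression value; residuals feed the residual score
channel. Median polish is the canonical RMA summarization step; a
full robust probe-level linear model would give similar but not identical
residuals, and no background correction is applied. Residual estimation is
meant to run per condition (the replicates of one condition at a time).

Intensities enter the log transform as log2(max(v, c)): a zeroed probe
contributes log2(0 + c), and sub-detection-limit values are treated as at
the limit. Values above c are untouched, so scaling a probeset ×2 on one
array shifts its chip effect by exactly +1.

Summarization batches equally-sized probesets into one 3-D stack and
polishes them in lockstep with per-probeset stopping, which is
numerically identical to the one-probeset-at-a-time fit (tested) and
orders of magnitude faster at tens of thousands of probesets.

## Correction

*Mean replacement*: a flagged probe takes the arithmetic mean of its
probeset's unflagged probes on the same array; between-array intensity
differences therefore never enter. A fully flagged probeset is zeroed —
no meaningful value can be inferred — and reported so downstream analyses
can exclude it. Replacement pools use every mapped probe of the probeset
(core or not). Flagged probes outside any probeset (controls, background
features) are never altered. The operation is idempotent for a fixed flag
mask and bit-preserves every unflagged intensity.

*Definition filtering*: flagged probes are dropped from the probeset map;
emptied probesets are removed and reported, and the dropped probe ids are
exported as a kill list. When a probeset empties, downstream tools get a
map without that probeset (rather than an empty one) — the less surprising
contract for summarizers that iterate over map entries.

## Synthetic data

`generate_baseline_arrays` emulates artefact-free replicate arrays: a true
per-probe log2 intensity ~ Normal(8, 2) shared across replicates plus
independent per-replicate log2 noise Normal(0, 0.25), intensities 2^value.
Probesets of 4 probes are assigned by striding the row-major probe order,
so probes of one probeset are never adjacent, as on real arrays. The
generator captures replicate consistency and probe-to-probe intensity
spread; it does *not* model probe-affinity structure within probesets
(sibling probes are independent draws, unlike real probesets whose probes
share a target), intensity gradients, optical background, or
cross-hybridization. Consequences: mean replacement is handicapped
relative to real data (a probeset's clean probes are weak predictors of
the flagged one here), and the replicate-MAD improvements after correction
are real but small; detection benchmarks are unaffected since they depend
only on planted-versus-background score separation.

Spiking replaces raw intensities (pre-normalization) with 2^z,
z ~ Normal(μ, σ), defaults μ = log2(850), σ = 1 — the log2-scale reading
of the log-normal level observed inside real drying stains; a natural-log
interpretation can be had by passing converted parameters. Random spiking
hits each core-mapped probe with probability δ. The contiguous-stain
generator plants a filled disc (~70% of the footprint) plus a diffuse halo
of radially decaying hit probability, a synthetic stand-in for real stain
shapes, covering ~2% of the grid by default. Projection between platforms
maps factor×factor blocks to one probe (max over masked probes in the
block), rescaled by the ratio of the two arrays' 75th intensity
percentiles; blocks at odd edges are truncated blocks.

## Evaluation

Confusion counts are taken over an eligible universe, by default the
core-mapped probes — the same probes eligible for spiking, so non-core
probes can neither score as false positives nor dilute recall. PR curves
have one point per distinct score value with thresholds descending; all
probes tied at a value enter together, with no intra-tie interpolation.
The point at value v corresponds to the flag set {s ≥ v}, i.e. the strict
criterion at a threshold infinitesimally below v. Precision at a target
recall is read at the highest threshold whose recall reaches the target;
recall always reaches 1 at the minimum threshold. Replicate agreement is
the mean absolute deviation from the scatter-plot diagonal over shared
probesets, with zeroed probesets excluded by the caller.

## Benchmark problem sizes

The shipped benchmark (`scripts/acceptance.py`, `tests/test_acceptance.py`)
uses ten seeded runs of three 300×300 replicate grids — 90,000 probes,
22,500 probesets per array — with a ~2%-coverage stain, k = 25, c = 16,
and precision measured at 85% recall; the fold-change-bias study uses
twenty seeded 80×80 runs at δ = 0.05. These sizes were chosen so the whole
study runs on a laptop in about a minute while keeping ≥1,500 planted
probes per run (binomial noise on precision ≈ 1%) and every probeset-count
class populated. Sub-seeds for the baseline, stain shape and planted
values are spawned from one run seed via `numpy` seed sequences; all
results are bit-reproducible given the seed.

## Known limitations

* Stains that depress rather than inflate intensities are detectable in
  principle (absolute scores) but not exercised by the simulator.
* The window criterion assumes roughly isotropic artefacts; elongated
  scratches would be better served by anisotropic kernels, which are out
  of scope.
* Binary Calvin/Command-Console CEL files are not read or written; inputs
  must be text CEL v3 or the TSV grid dialect.
* Median-polish residuals approximate, but do not reproduce, robust
  probe-level-model residuals.
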