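# Methods

## Model

A copy-number profile is a series of n probe-level log2 ratios ordered by
genomic position, modelled as x_i = μ_i + ε_i where μ is piecewise
constant: change-points τ = {τ_0 = 0, …, τ_m = n} (0-based, half-open
probe indices) delimit m segments with levels θ_j, each estimated by the
segment mean. The noise ε is treated as i.i.d. Gaussian with scale σ;
wave artefacts violate exactly this assumption by adding a smooth,
autocorrelated component to μ, and the whole point of the feature set is
to detect that violation rather than to remove it.

## Step fitting and the S statistic

Starting from τ = {0, n}, each iteration inserts the change-point that
minimizes the residual cost H = Σ(x_i − μ_i)². The greedy insertion uses
the identity that the globally best addition is always the most prominent
*counter-fit* point: inside every best-fit interval of length ≥ 2 we keep
the location minimizing the within-interval post-split SSE together with
its cost reduction d; the next best-fit point is the argmax of d, and
after the insertion only the two flanking sub-intervals are re-scanned.
Interval SSEs come from prefix sums of x and x², so one scan is O(length)
and the expected total work is O(n log n) (measured: the split-scan count
roughly doubles from n = 10,000 to n = 20,000 at fixed K). A direct
O(nK) formulation (full re-scan per iteration) is kept as
`step_fit_naive`; the two produce bit-identical change-point sequences
and S curves, which the test suite verifies on seeded instances.

After each iteration the counter-fit set (boundaries plus one counter
point per interval) gets its own cost Q, and S = Q/H is recorded. S_peak
and the iteration l attaining it (first maximum on ties) summarize the
curve; Δ̂ is the mean absolute level difference across the peak-iteration
change-points weighted by sqrt(τ_{j+1} − τ_{j−1}), and σ̂ = sqrt(H/n).

Numerical conventions: K defaults to 120 and is capped at n − 1; ties in
argmax d break towards the smaller interval index and ties in the split
scan towards the smaller location (this makes the incremental and naive
fitters comparable exactly); if H reaches 0 (noiseless data) S is defined
as +∞ and the curve terminates at that iteration. Step fitting runs
genome-wide on the concatenated series — chromosome boundaries are not
forced change-points — because S_peak and l are global shape summaries.

For an equal-step staircase the classical approximation
S_peak ≈ 1 + Δ²/(4σ²) holds only loosely here: because each counter
point sits at the SSE-optimal (not the midway) split of its interval, and
noise-optimal splits are biased towards interval edges, the measured peak
falls ~10–25% below that formula at high Δ/σ. This is a property of the
counter-fit definition used, not an implementation artefact — the naive
reference implementation shows the identical deficit.

## CBS

`max_t_statistic` scans every circular arc (i, j] of an interval and
maximizes the two-sample t between arc and complement with the pooled
(N − 2 df) variance; T = 0 when the mean difference is zero and +∞ for a
perfect split. Significance is assessed by within-interval permutations:
a split is accepted when the fraction of permuted series whose maximal
statistic reaches the observed one is ≤ α (default 0.01, 1000
permutations); accepted arcs split the interval into up to three pieces,
recursively, independently per chromosome. This replaces the hybrid tail
approximation of the reference CBS implementation with a plain
permutation test — simpler and exactly calibrated on exchangeable data
(measured type-I rate 0.011 at α = 0.01 over 1000 noise runs). Two exact
shortcuts keep it fast: the permutation loop stops once the exceedance
count already rules out acceptance, and arc lengths whose best possible
explained sum of squares (bounded through the range of the centred
cumulative sum) cannot reach the observed statistic are skipped. Very
long intervals (> 5000 probes) use a window-limited arc search; at the
default chromosome sizes this never triggers. No merge/undo step is
applied — wave-driven hyper-segmentation is exactly the signal the v
feature wants. One caveat follows from the permutation scheme: on
strongly autocorrelated input the test is anticonservative (permutations
destroy the autocorrelation), so wave-contaminated profiles segment down
to roughly the noise-correlation scale. That is desired for the
reliability features, but it makes the absolute wave-regime segment
counts implementation-relative; classifiers should be trained with
features from this CBS, as done here.

## Features

σ is the DLRS — the sd of successive probe differences divided by
sqrt(2) — computed within each CBS segment holding ≥ 3 probes and
averaged weighted by probe count. The derivative form is deliberately
insensitive to residual wave curvature, so σ estimates the probe-level
noise scale itself. medASP is the median over sliding windows (100
probes, stride 25) of the lag-1 Pearson autocorrelation; the original
baseline's exact windowing is not documented anywhere, so these values
are exposed as parameters.

## Classifier

An RBF-SVM with kernel exp(−0.4‖u−v‖²) and C = 1 on features
standardized by the training mean/sd (without standardization a fixed
gamma is meaningless when l and v reach hundreds while S_peak and σ are
O(1)). Labels come from the decision-function sign; P(unreliable) from a
Platt sigmoid fitted on the training decision values (fitted on the
training set directly, not out-of-fold — probabilities are reported for
ranking and ROC use, while all case decisions use labels). Cross-
validation refits the scaler and SVM per stratified fold and skips the
calibration it does not need. The trained model is serialized as a
self-contained JSON document (scaled support vectors, dual coefficients,
intercept, scaling statistics, sigmoid parameters, training minima of v
and σ, thresholds), so prediction has no dependency on a pickled
estimator.

Sub-categorization builds, for an unreliable sample, two dummy vectors:
d1 replaces v by the training minimum, d2 replaces σ by the training
minimum. d1 flipping to reliable indicates wave-driven hyper-segmentation
(case 1 if S_peak > thr2 = 2.5, else case 3); otherwise d2 flipping
indicates large DLRS (case 4); if neither flips, both artefact axes
contribute and the wave branch wins — d1 is checked first, a deliberate
tie order. Reliable samples split on thr1 = 1.5: case 2 above (many
CNAs), case 5 at or below (control-like).

## Synthetic cohorts

The generator produces what the features are designed to separate, with
every parameter exposed in `SimProfileSpec` and every draw a pure
function of the seed:

* n = 10,000 probes over 22 equal chromosomes; 5–40 CNA segments per
  sample with levels {±0.58, ±1.0} (single/double copy changes) on a
  diploid baseline, lengths log-uniform between 5 and 300 probes
  (a focal-to-broad spectrum that includes genuinely hard, low-SNR
  segments), placed without overlap inside single chromosomes;
  i.i.d. Gaussian noise, sd 0.15.
* Group B adds an AR(1) wave with coefficient 0.99 and stationary sd 1.3
  (exceeding even a full-copy change; correlation length ~100 probes), so
  the recovered step count decouples from the truth; a sum-of-sinusoids
  wave is available as an alternative.
* Group C passes the group-A profile through a 31-probe running median
  (reflected edges), which preserves the steps while adding small
  plateau-like waves that make CBS hyper-segment.
* `flat` is pure diploid noise; `highDLRS` multiplies the noise sd by 4.

The wave and filter scales were calibrated once, on pilot cohorts, so the
three groups reproduce the intended qualitative regimes — CBS tracking
truth in A, step count decoupled in B, CBS hyper-segmenting in C — and
then frozen. What the cohorts do *not* emulate: platform-specific probe
spacing, GC tracks, segment-level level wobble, FFPE noise signatures, or
waves of sample-varying scale. Passing tests on these cohorts therefore
demonstrate the mechanics and the regime contrasts, not performance on
any particular real platform; for real collections the custom-training
path (label a subset, `cnqc train`) is the supported route.

Recovery statistics: Spearman rank correlation plus a Huber M-estimator
regression (IRLS, tuning constant 1.345) of recovered on true counts —
robust to the occasional catastrophically segmented sample. The true
segment count convention counts all segments of the true piecewise
signal with chromosome boundaries forced, matching what the CBS count v
measures; correlations and slopes are unaffected by the convention,
intercepts are.

## Problem sizes used in the checks

Step-fitting statistics use 200-sample cohorts; CBS-based statistics use
50 samples at 500 permutations; the classifier checks use 100 samples
per group with ten-fold cross-validation and a 50:50 held-out split.
These sizes give sampling noise well inside the tolerances the checks
use (e.g. a Spearman rho over 200 samples has s.e. ~0.07).

## Known limitations

* The permutation CBS inflates segment counts on autocorrelated input
  relative to hybrid-p-value implementations (see above); v is
  implementation-relative.
* S_peak under-shoots the 1 + Δ²/4σ² staircase approximation at high
  SNR by design of the counter-fit (see above).
* Probability calibration is in-sample; with small custom training sets
  the probabilities (not the labels) can be optimistic.
* l saturates at K for profiles whose S curve rises monotonically
  (rough-noise regimes); the classifier, not a hard rule, resolves those
  cases.
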