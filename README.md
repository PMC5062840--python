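# cnqc — reliability assessment for genomic copy-number profiles

DNA copy-number profiles from microarray or sequencing experiments are
probe-level log2 ratios that should look piecewise constant: flat segments
separated by abrupt change-points at the boundaries of copy-number
alterations (CNAs). In practice many profiles carry **wave artefacts** —
slow, autocorrelated baseline distortions from GC bias, replication timing
or fixation damage — and/or a large **derivative log ratio spread (DLRS)**
from poor DNA quality. Both inflate or bury segmentation results and can
poison downstream CNA analyses. `cnqc` is a toolkit for curators and
analysts of large copy-number collections who need to decide, per sample,
whether a profile is reliable enough to keep.

## The method

A profile x = {x_i}, i = 1..n, is modelled as x_i = μ_i + ε_i with μ
piecewise constant between change-points τ and ε i.i.d. noise of scale σ.
Two complementary segmenters are run:

* **Circular binary segmentation (CBS)** finds, per chromosome and
  recursively, the circular arc (i, j] maximizing the two-sample
  t-statistic against its complement, accepting a split when a
  within-interval permutation test gives p ≤ α. Its genome-wide segment
  count **v** counts change-points from CNAs *and* from waves — waves make
  it hyper-segment.
* **Step fitting** (an O(n log n) greedy fitter) adds one best-fit
  change-point per iteration — the one minimizing the residual cost
  H = Σ(x_i − μ_i)² — while maintaining one *counter-fit* point inside
  each best-fit interval, with counter-fit cost Q. The step indicator
  **S = Q/H** peaks when the best fit has captured every genuine step and
  the counter-fit is forced to sit mid-segment; the peak height
  **S_peak** (≈ 1 + Δ²/4σ² for a clean staircase with step height Δ)
  measures how step-like the profile is, and the iteration **l** attaining
  it estimates the number of steps. Smooth waves barely raise S, so step
  fitting sees through them.

Each profile is summarized by the feature vector **(S_peak, l, v, σ)**
(σ = the probe-count-weighted mean DLRS within CBS segments). An RBF-SVM
(kernel exp(−0.4‖u−v‖²), cost C = 1, features standardized) trained on
labeled examples predicts *reliable* vs *unreliable*, and a dummy-sample
scheme sub-categorizes every call into one of five cases: (1)
hyper-segmented, (2) reliable with discernible CNAs, (3) heavy waves, (4)
large DLRS, (5) control-like/few CNAs. A sliding-window lag-1
autocorrelation baseline (medASP) is included for comparison.

A full synthetic-cohort generator reproduces the study regimes: group A
(reliable, many CNAs), group B (CNAs buried in AR(1) waves), group C
(median-filtered, hyper-segmenting), plus flat diploid and high-DLRS
profiles.

## Worked example

Simulate one reliable (A) and one wave-contaminated (B) profile and assess
them with the bundled model:

```bash
$ cnqc simulate --out demo --n-per-group 1 --groups A,B --seed 42
wrote 2 profiles to demo

$ cnqc predict demo/sim-A-0000.tsv --permutations 500 --seed 1
sample_id   label     prob_unreliable  case  case_description
sim-A-0000  reliable  0.000121         2     reliable, discernible CNAs with few waves

$ cnqc predict demo/sim-B-0000.tsv --permutations 500 --seed 1
sample_id   label       prob_unreliable  case  case_description
sim-B-0000  unreliable  0.999863         3     unreliable, indiscernible CNAs with heavy waves
```

The A sample is kept (case 2: step-like, moderate segment count); the same
underlying CNAs under heavy waves are rejected (case 3) with probability
of unreliability ≈ 1. `cnqc stepfit demo/sim-B-0000.tsv` shows why:
`S_peak=1.87 l=112 sigma_hat=0.43` — the wave-buried profile needs far
more steps (l = 112 vs 50) for a weaker peak, and its residual spread is
three times the generating noise.

Other subcommands: `features` (write the 4-feature row), `segment`
(SEG-style CBS table), `train` / `cv` (custom training sets, ten-fold
cross-validation), `medasp`.

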