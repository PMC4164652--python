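# Methods

`sbpseg` quantifies sleep apnea-hypopnea from a single beat-to-beat systolic
blood pressure (SBP) series. This note documents the model assumptions, the
estimation procedures, the numerical choices, and what the synthetic cohorts
can and cannot demonstrate.

## 1. Stationarity segmentation by maximal Kolmogorov-Smirnov distance

Physiological beat-to-beat series are nonstationary: the SBP level wanders on
minute scales, which invalidates correlation and Fourier analysis applied to
the raw signal. The pipeline first partitions the series into patches within
which the distribution of values is statistically constant.

**Procedure.** For a window of `n` beats, every interior beat `t` that leaves
at least `l0` beats on each side is a candidate cut. The two-sample KS
distance

    D(t) = sup_x | F_left(x) − F_right(x) |

is computed between the empirical CDFs of the two sides, and the window is
split at the `t*` maximizing `D` (smallest `t` on ties, for determinism) if
`D_max > D_crit(n, α)`. The rule recurses depth-first (left first) on both
halves until no window is segmentable. Windows shorter than `2·l0` are never
split, so every patch has length `≥ l0` (except a whole series shorter than
`2·l0`). The result is always an ordered, gap-free partition of `[0, N)`;
per-patch means use the sample mean and per-patch variances the unbiased
(`L − 1`) estimator, because patches near the minimum length are small.

**Significance calibration.** Because `D_max` is a maximum over many strongly
dependent candidate cuts — including very asymmetric ones — the textbook
two-sample KS null does not apply. `D_crit(n, α)` is instead the empirical
`(1 − α)` quantile of `D_max` under the null, obtained by running the
*identical* `l0`-restricted scan on i.i.d. standard Gaussian series. The KS
statistic is distribution-free for continuous data, so a Gaussian null
calibrates any continuous input; heavily tied (discretized) data would break
this and is not supported. The packaged curve for the defaults
(`α = 0.01`, `l0 = 33`) was calibrated on a geometric grid of 17 lengths from
66 to 16384 (2000 null series per point up to N = 2048, 1000 up to 5793, 500
above; per-point RNG seeded by `(seed, N)` so any single point can be
re-verified in isolation — a test does exactly that). Between grid points the
curve is interpolated linearly in `log N`; beyond the grid it is held
constant, which is mildly conservative because the minimum-length-restricted
scan is dominated by `l0`-sized splits and its null quantile flattens to a
positive limit (the calibrated values fall only from ≈ 0.35 at N = 66 to
≈ 0.29 at N = 16384). Users holding an analytic critical curve can inject it
via `CriticalCurve.from_function`; non-default `(α, l0)` pairs trigger an
on-demand calibration that is cached on disk.

**Defaults.** `l0 = 33` beats ties the minimum patch to the 0.03 Hz upper
edge of the very-low-frequency band of heart-rate variability at a nominal
1 beat/s — cuts producing patches shorter than the slowest rhythm of interest
are not meaningful. `α = 0.01` keeps roughly one spurious cut per hundred
homogeneous records; both are exposed in the configuration.

**Implementation note.** The scan is evaluated with integer arithmetic
(`D(t) = |n·c_k − t·k| / (t(n−t))` over the counts `c_k` of left-side values
among the `k` smallest), processed in vectorized blocks; near-maximal
candidates are then re-evaluated with the plain empirical-CDF formula. The
returned position and distance are therefore *bit-identical* to an exhaustive
naive scan, which the test suite asserts against an independent oracle.

## 2. Per-subject quantifiers

From each subject's segmentation the pipeline extracts

* `<L>` — mean patch length in beats,
* `<σ²>` — mean of the patch variances (mmHg²),
* `<μ>` — mean of the patch means (mmHg, reported but not used for
  classification).

All three are unweighted per-segment averages; a beat-weighted variant is
available (`weighted="beats"`) since the natural-language definition does not
fix the weighting. Group-level analyses use complementary cumulative
distributions `P(L ≥ ℓ)` of patch lengths (per subject and pooled per group),
two-sample KS tests between each apneic group and the controls (both on
pooled lengths and on per-subject summaries), quartile summaries, and Pearson
correlations with the apnea-hypopnea index (AHI). The two-sample KS p-value
defaults to the exact small-sample distribution (equivalent to a permutation
test for continuous data, and verified against one); the asymptotic formula
with effective size `n_a·n_b/(n_a+n_b)` is available as `method="asymp"`.

## 3. Spectral oscillation quantifier

Subtracting each patch's mean yields the detrended ("filtered") signal; this
does not guarantee stationarity (variance may still drift) but removes the
level wander that dominates the raw spectrum. Apnea events drive a cyclic
blood-pressure swing visible as an oscillation near 0.02 cycles per beat
interval; its strength is quantified on the filtered signal by

    A_max = max_{f ∈ B} S(f) / ∫_B S(f) df ,

where `S` is the one-sided Welch PSD (Hamming window, 256-beat segments, 50 %
overlap — standard `pwelch`-style defaults, all configurable) and
`B = [1/512, 0.1]` cycles/beat. The band excludes DC, brackets the ≈ 0.02
peak with a wide margin, and sets the quantifier's white-noise floor at
`1/|B| ≈ 10.2`; "amplitude" is read as PSD value (power), with a `sqrt`
option for the amplitude-spectrum reading. Frequencies are in cycles per beat
interval throughout; conversion to Hz would need beat timestamps, which the
beat-index domain does not carry. Autocorrelation diagnostics (whole-record,
and paired 2000-beat apnea-rich vs apnea-free fragments when annotations are
available) use the biased estimator normalized to 1 at lag 0.

## 4. Classification

Each quantifier increases with apnea severity, so a subject is called apneic
when the feature exceeds a threshold. The ROC sweep evaluates all midpoints
between consecutive distinct feature values plus sentinels; the operating
point minimizes the Euclidean distance to the (FPR = 0, TPR = 1) corner, with
ties resolved toward lower FPR (screening favours specificity at equal
distance). AUC is the trapezoidal area, identical to the normalized
Mann-Whitney U statistic (asserted in tests). Reported accuracy is apparent
accuracy `(TP + TN)/n` — the natural metric at cohort sizes of a few dozen —
with an optional leave-one-out variant for an optimism check. The combined
rule declares a subject non-apneic only when *both* `<L>` and `A_max` lie at
or below their individual ROC-optimal thresholds (the "low-low" quadrant); an
OR-variant is configurable. No cross-validation, probabilistic models or
multiple-testing corrections are applied.

## 5. Synthetic cohorts

Because no clinical recordings ship with the package, a generator produces
cohorts with the structure the analysis assumes:

* **Baseline**: block-constant mean SBP with level shifts arriving as a
  Poisson process (`seg_rate` per 1000 beats) and mean-reverting AR(1) block
  levels (`φ = 0.5`, jump SD 6 mmHg), plus i.i.d. Gaussian beat noise
  (SD 4 mmHg). Baselines: 155 mmHg (hypertensive) / 120 mmHg (others).
* **Apnea load**: each event occupies 50 beats (≈ 50 s at 60 beats/min,
  consistent with the ≥ 10 s clinical event definition plus the recovery
  swing) and drives one cycle of a 50-beat-period sinusoid (amplitude
  6 mmHg). Events recur in contiguous cyclic trains, as in periodic
  breathing: the event budget is partitioned into epochs of geometrically
  many back-to-back events (mean 6), each epoch a continuous multi-cycle
  oscillation with its own phase, and epochs are placed uniformly at random
  subject to disjointness. The fraction of the night in apnea is
  `min(0.9, AHI · 50/3600)`, making AHI the single severity knob.
* **Study design**: 10 hypertensive apneic (AHI ~ U(16, 35)), 16 normotensive
  apneic (AHI ~ U(15, 22)), 7 controls (AHI ~ U(0, 4), no apnea intervals).
  Controls receive a four-fold higher spontaneous shift rate (4 vs 0.7 per
  1000 beats), encoding the more active blood-pressure regulation of healthy
  sleep; this *builds in* the shorter control patches and is a modelling
  choice, not a measured parameter. Apneic AHI ranges respect the AHI > 15
  inclusion rule; the implied mean apnea occupancy (≈ 35 % HT, ≈ 26 % NT)
  is therefore somewhat above clinical averages — the ordering, not the
  absolute occupancy, is the modelled feature.
* **Record length**: subjects default to 14 400 beats (≈ 4 h of artifact-free
  beats at 60 beats/min), a deliberate scale-down from a full night that
  keeps cohort-scale analyses fast while leaving every per-subject statistic
  comfortably resolved (≥ 10 baseline shifts for controls, ≥ 50 Welch
  averages).
* **Reproducibility**: one root seed; per-subject child seeds spawned via
  `numpy.random.SeedSequence`, so cohorts are byte-identical given the seed
  and any single subject can be regenerated.

**What passing on synthetic data shows — and what it does not.** The
generator contains, by construction, exactly the effects the quantifiers
target (piecewise-stationary baseline, epoch-confined oscillation, severity
proportional to AHI). Synthetic results therefore validate the *machinery* —
calibration of the cut test, recovery of change points and spectral peaks,
correctness of the ROC optimisation — and the *directions* of the group
effects, but not clinical effect sizes, thresholds or accuracies. Real
records add artifacts and ectopic beats (assumed removed upstream; a
preprocessing hook is the supported entry point), respiratory and baroreflex
rhythms, non-sinusoidal and variable-period apnea responses, and central vs
obstructive event heterogeneity — none of which are modelled.

## 6. Degenerate inputs and edge rules

Constant series produce one segment (`D_max = 0` never exceeds `D_crit`).
Series shorter than `2·l0` return a single segment. A single-beat series has
variance 0 by convention. Empty samples, zero-variance inputs to
autocorrelation or Pearson correlation, overlapping annotation intervals,
single-class cohorts, and bands containing the DC bin are rejected with
explicit errors; per-subject pipeline failures are isolated and logged while
cohort stages continue on the survivors.
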