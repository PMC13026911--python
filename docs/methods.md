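# Methods

## Model

A qPCR standard curve relates the quantification cycle to the starting
target amount through the log-linear response

    Cq(N) = k · log10(N) + m

where `k` is the slope in cycles per decade and `m` is the Cq of a single
double-stranded target molecule. The PCR efficiency — the fraction of
target molecules duplicated per cycle — follows from the slope as

    E = 10^(−1/k) − 1,

so perfect doubling (E = 1) corresponds to k = −1/log10(2) ≈ −3.32. The
curve is fitted by ordinary least squares of Cq on log10 copies; the
delta-method standard error of E is SE(k)·(1+E)·ln10/k², and all intervals
are Student-t with n − 2 degrees of freedom.

Two variance sources are modelled for replicate reactions:

1. **Aliquoting (sampling) uncertainty.** The actual target count `x` in an
   aliquot pipetted from a well-mixed sample with expected count `N` is
   Poisson(N). Aliquots with x = 0 are negative; positive aliquots report
   Cq(x) = m − log10(x)/log10(1+E). This term dominates at low N and
   vanishes as 1/√N.
2. **Technical Cq noise.** Additive Gaussian noise on the Cq scale with
   standard deviation `sigma_tech`, covering instrument read-out,
   pipetting, and chemistry repeatability. It dominates at high N.

Early-cycle amplification stochasticity (the branching-process variance of
single-molecule amplification) is deliberately not modelled; with an
optimized assay its contribution to Cq variance is small against the two
terms above, and the two-source model is what the analysis pipeline
estimates and inverts.

## Cq-scale vs linear-scale imprecision

An SD of Cq values maps to a relative standard deviation of concentration
on the linear scale. Treating the back-calculated concentration as
log-normal at base (1+E) with spread SD(Cq) cycles, the package uses

    RSD = sqrt((1+E)^(SD(Cq)²) − 1),        SD(Cq) = sqrt(ln(1+RSD²)/ln(1+E)).

This specific form was selected because, composed with the zero-truncated
Poisson Cq SD below, it reproduces the published theoretical precision
values for the reference assay (RSD 0.325/0.220/0.153 at N = 16/32/64,
E = 1, against published 0.327/0.221/0.153) and places the 25 % theoretical
quantification limit at 26 molecules; the two plausible alternatives (the
first-order conversion ln(1+E)·SD and the log-normal CV with exponent
(ln(1+E)·SD)²) miss those benchmarks by 20 % or more and put the crossing
near 18. A consequence worth knowing: at high N the linear RSD from
aliquoting alone tends to 1/√(N·ln(1+E)), i.e. about 1.2/√N at E = 1 —
slightly above the naive Poisson coefficient of variation, because the
conversion is applied to the log-scale spread.

## Poisson limits of detection and quantification

- P(positive) = 1 − e^(−N); the theoretical LOD at 95 % confidence is
  N = −ln(0.05) ≈ 3.0 molecules per aliquot, independent of the assay.
- The theoretical RSD(N) curve is computed from the SD of Cq over the
  zero-truncated Poisson distribution, evaluated by direct enumeration of
  x from 1 to the smallest cutoff with tail mass < 1e-12, renormalized by
  1 − e^(−N) (exact to tolerance, no sampling noise). Above N = 1e5 a
  delta-method series (Var(ln x) = 1/N + 3/(2N²)) replaces the enumeration;
  its relative error is below 1e-9 at the switch point.
- RSD(N) is a hump peaking at N ≈ 2.9 (height ≈ 0.76 at E = 1): it rises
  at the low end because negatives remove an increasing share of the
  distribution, and decays ~1/√N at the high end. The theoretical LOQ is
  the crossing of the decreasing branch with the RSD criterion (default
  25 %), found by bracketing + bisection to |ΔN| < 1e-6, reported both as
  the real root (25.36 at E = 1) and as the smallest integer satisfying the
  criterion (26).

## Empirical LOD and LLOQ/ULOQ

The empirical LOD fits the per-level positive fractions with a
two-parameter sigmoid in log10(N) by binomial maximum likelihood and
inverts it at the target confidence (default 95 %). The default family is
the complementary log-log curve p = 1 − exp(−exp(b0 + b1·ln N)), whose
(b0, b1) = (0, 1) member is exactly the Poisson occupancy law 1 − e^(−N);
when aliquoting dominates, the fit is unbiased for the theoretical limit.
A logistic family is available, but it cannot track the Poisson shape
across a saturating dilution series — on exact occupancy fractions it
returns anywhere between 1.1 and 3.4 depending on which saturated levels
enter the fit, which is why it is not the default. The LOD confidence
interval is a percentile interval over parametric-bootstrap resamples of
the per-level binomial counts (default 1000, seeded).

LLOQ and ULOQ are read from the per-level linear-scale RSD against the
threshold: ULOQ is the highest tested level meeting the criterion, LLOQ the
lowest level from which the criterion holds contiguously up to the ULOQ.
Transient sub-threshold dips below that run do not set the LLOQ, because
the dynamic range is by definition a contiguous interval. SD(Cq) per level
is computed over positive replicates only; when negatives are present this
conditioning biases the level mean and SD, and the profile flags it.

## varPCR

When aliquoting uncertainty dominates, the observed RSD of replicate Cq
values determines N by inverting the theoretical RSD(N) curve (bisection,
|ΔN| < 1e-6). The same RSD occurs once on each side of the hump; for a
single level the ambiguity is resolved by negatives (any negative replicate
⇒ rising branch, all positive ⇒ decreasing branch). Confidence intervals
are nonparametric percentile bootstrap over replicate reactions (default
2000 resamples, seeded). Technical noise inflates the observed RSD and
therefore biases the estimate downward on the decreasing branch; an
optional, experimental `sigma_tech` argument subtracts a known technical SD
in quadrature before conversion.

The combined estimator switches to the classical occupancy (dPCR-style)
readout N = −ln(f_negative), with a Wilson-interval-propagated CI, whenever
the negative fraction is in [0.05, 0.95], and uses the variance estimator
outside that window. Two refinements matter in the crossover region:

- On the variance path the branch follows the negative *fraction* rather
  than the any-negative rule: below 5 % negatives the level must sit on the
  decreasing branch (a 1/96 negative fraction already implies N ≈ 4.6 by
  occupancy, right of the hump). With 96 replicates near N = 5, one or two
  negatives are common, and the literal any-negative rule would invert on
  the wrong branch.
- If the observed RSD exceeds the Poisson-only maximum (possible by
  sampling noise near the hump) but negatives were observed, the combined
  estimator falls back to the occupancy readout instead of failing; with no
  negatives such an RSD is genuinely inconsistent with aliquoting-only
  variation and is reported as an error.

Under Poisson-only simulation (96 replicates, no technical noise) the
median variance-path estimate is within 5 % of truth for N between 8 and
128, and the combined estimator holds a median relative error below 25 %
from N = 0.5 to N = 500.

## Inverse prediction

log10(N) = (Cq − m)/k with standard error

    SE = (SEy.x/|k|) · sqrt(1/b + 1/n + (Cq − C̄q)²/(k²·Sxx)),

where b is the number of test-sample replicates averaged into the measured
Cq, n the number of calibration points, and Sxx the spread of the
calibration design in log10 units. The CI is t-based with the calibration
df, symmetric in log scale and back-transformed to an upward-skewed linear
interval; relative errors are 100·(CI width)/point on each scale. Test
replicates are averaged on the Cq scale before inversion with b inferred
from the input, keeping the b in the SE formula consistent with the
averaging actually applied; a warning fires when calibrator and test
replicate handling differ. Working–Hotelling bands are simultaneous by
default (multiplier sqrt(2·F(ci; 2, n−2))), with a pointwise-t option; the
prediction band adds 1/b to the leverage. Run QC applies the ±1-cycle
accuracy rule per quality-control sample, with a run-level verdict.

## Validation rules and their defaults

| Parameter | Default | Meaning |
|---|---|---|
| `ci_level` | 0.95 | all Student-t / bootstrap intervals |
| `rsd_threshold` | 0.25 | LOQ criterion, linear-scale fraction |
| `linearity_alpha` | 0.05 | F-tests of quadratic/cubic terms (unstated in common practice; exposed as config) |
| `grubbs_alpha` | 0.05 | single-pass two-sided Grubbs test |
| LOD confidence | 0.95 | positive-fraction target |
| `sigma_tech` (simulator) | 0.15 cycles | mid-range of reported qPCR repeatability; a stand-in, exposed in config |
| efficiency acceptance | reject if lower CI bound of E > 1 | warn when E < 0.90 or when the CI spans 1 |

The linearity check fits nested polynomials (linear/quadratic/cubic) and
F-tests the extra terms; the curve passes when both are non-significant.
Because the F-test is sensitive to harmless wiggle, the report also carries
the "allowable deviation from linearity": the largest relative difference,
in linear concentration scale, between back-calculation through the cubic
and through the linear fit (computed per level as 10^((ŷ₃−ŷ₁)/k) − 1);
below 20 % the curve would typically still be accepted. Grubbs is applied
once to the pooled standardized residuals (no iterative removal) and is
reported separately from the per-level ±3 screening rule. Weighted least
squares is not implemented; points below the LLOQ are excluded before
fitting instead, which is how the heteroscedasticity at low copy numbers
is handled.

## Synthetic data: what it does and does not emulate

The simulator reproduces the replicate structure of a high-replication
validation experiment (2-fold series from 2048 down to 1 expected copy;
128/64/32 replicates) and of routine triplicate/quadruplicate ten-fold
series. It draws Poisson counts per reaction, emits negatives as records
with empty Cq, applies the log-linear response and Gaussian Cq noise, and
is byte-reproducible under a fixed seed. It does not model partition-volume
variability, pipetting error, over-dispersion beyond Poisson,
matrix/inhibitor effects, or fluorescence-curve shape — so tests passing on
synthetic data demonstrate the statistical machinery, not robustness to
those real-data effects.

Study conditions frozen into the stochastic tests (chosen once as routine
validation designs): linearity calibration and power use 6 ten-fold levels
(1e3–1e8 copies) × 4 replicates with sigma_tech = 0.15 and E = 0.95;
prediction-CI coverage uses the same design at sigma_tech = 0.2, E = 1,
with a test sample of 3 replicates at 1e6 copies; varPCR recovery uses 96
replicates per level. At these sizes the full test suite runs in about a
minute.

## Numerical choices and degenerate inputs

- Truncated moments by exact enumeration (tail < 1e-12); series expansion
  above N = 1e5; all root-finding by Brent bisection.
- An exact-line fit leaves only float rounding noise in the residuals;
  standardized residuals snap to zero when SEy.x ≤ 1e-8 relative to the
  mean Cq, so no spurious outlier flags arise.
- Grubbs on zero-variance residuals reports no outlier (statistic
  undefined).
- A fully positive dilution series reports LOD as "below lowest level
  tested"; an RSD profile with no level under the threshold reports "not
  quantifiable in range"; observed RSD = 0 in varPCR reports "above the
  quantifiable-by-variance range".
- Negative reactions never enter curve fitting; levels with a single
  positive replicate carry no SD and are excluded from RSD statistics with
  a warning.

## Known limitations

- The Cq-SD→RSD conversion reproduces the published decreasing-branch
  precision values to ≈0.002 but not the printed values around the hump
  (printed 0.581/0.668/0.738 at N = 1/2/4 vs computed 0.571/0.729/0.728);
  the published low-N inversions (e.g. 53 predicted at 32 expected) are
  likewise not derivable from any of the candidate conversions and are not
  used as gates.
- varPCR assumes Poisson-only variation; under realistic technical noise
  the estimate is biased downward on the decreasing branch, and the
  optional quadrature correction requires an externally known sigma_tech.
- No weighted least squares, robust regression, multi-outlier ESD, or
  Bayesian calibration; no fluorescence-curve processing (inputs are Cq
  tables); no per-volume unit handling beyond a reporting-layer division.
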