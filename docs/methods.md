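# Methods

`abtp` models the probability that a dairy cow's body temperature is
abnormal (elevated above a herd reference) as a sigmoid function of a
quantitative heat-stress factor — in practice the temperature-humidity
index (THI). This note records the models, the synthetic-data design,
the numerical choices, and the limits of what the test suite shows.

## Heat-stress index and outcome definition

THI combines air temperature T (°C) and relative humidity RH (%):

    THI = (1.8·T + 32) − (0.55 − 0.0055·RH)·(1.8·T − 26)

It is strictly increasing in T for RH ∈ [0, 100] and increasing in RH
whenever T > 26/1.8 ≈ 14.4 °C. No alternative THI formulations are
offered.

The binary outcome "abnormal body temperature" is, by default, an
eye-socket temperature strictly above the dataset (annual) mean, with a
configurable offset, or alternatively a fixed threshold. The deviation
is one-sided upward because heat stress elevates body temperature; the
direction and offset are configuration, not facts about any particular
herd, and both are exposed.

Triage bands for day-to-day management: temperatures below a critical
value (default 38.32 °C) are *normal*; from there up to that value
inflated by the infrared imager's accuracy margin (2%, giving
round(38.32 × 1.02, 2) = 39.09 °C) are *observe*; at or above the
inflated bound, *abnormal*. Both band floors are inclusive. An
environmental alert triggers when THI strictly exceeds 75.

## ABTP curve families

Four two-parameter families map the factor n onto a probability, all
sharing the location parameter Tn50 (the factor value at exactly 50%
probability) plus one slope/shape parameter:

| family      | form                                   | shape |
|-------------|----------------------------------------|-------|
| LKB         | Φ((n − Tn50)/(m·Tn50))                 | m     |
| Logistic    | 1/(1 + e^−(β0+β1·n)), Tn50 = −β0/β1    | β1    |
| Schultheiss | 1/(1 + (Tn50/n)^k)  (log-logistic)     | k     |
| Poisson     | 2^(−exp(e·γ·(1 − n/Tn50)))             | γ     |

The Poisson tolerance model uses Euler's number at full double
precision, not a truncated 2.718 — only then is the value at n = Tn50
exactly 2^(−1) = 0.5, which the shared Tn50 semantics require. The LKB
probit is evaluated through the error function (`scipy.special.ndtr`),
not quadrature. The Poisson curve is bounded below by its n → 0⁺ limit
2^(−exp(e·γ)); quantiles below that floor are reported as unreachable.

### Maximum-likelihood fitting

The Bernoulli log-likelihood Σ yᵢ ln pᵢ + (1−yᵢ) ln(1−pᵢ) is maximised
over (Tn50, shape) by a 50×50 grid — Tn50 linear over the observed
factor range, shape log-spaced over family bounds m ∈ [0.005, 2],
β1 ∈ [0.01, 5], k ∈ [0.1, 200], γ ∈ [0.05, 20] — followed by
Nelder-Mead refinement from the best grid point in (Tn50, log shape)
space with tolerance 1e-8 on the log-likelihood. Probabilities are
clipped to [1e-12, 1 − 1e-12] before logs. If refinement ever returns a
worse value than the grid the grid optimum is kept and the fit flagged
non-converged; the fitted likelihood therefore never falls below any
searched grid point. Fitting is deterministic for a given dataset. On
noiseless separable data the slope runs to its lower search bound
(step-function limit), which is reported, not hidden.

Fitted curves invert to TTq thresholds (TT50, TT20) in closed form for
LKB, Logistic and Schultheiss, and by bracketed Brent root-finding for
Poisson. The logistic display slope γ50 = β1·TT50/4 is derived for
reporting only.

## Synthetic herd generator

No herd dataset ships with the package; the generator is the test bed.
Default marginal moments (mean ± SD): eye-socket temperature
38.3 ± 1.40 °C, ambient temperature 25.13 ± 4.55 °C, humidity
83.79 ± 7.90%, age 49 ± 27 months, days in milk 194 ± 132, parity
2 ± 1, body weight 599.76 ± 81.07 kg, milk yield 22.27 ± 6.87 l.
Marginals are Gaussian; ambient temperature and humidity share one
correlation (default −0.3, the usual diurnal anticorrelation); all
other variables are independent. Humidity is truncated to [0, 100];
age, days in milk and parity are truncated at zero and rounded to
integers. Truncation is by clipping; at the default moments the clipped
mass is small (≲7% for days in milk) and sample moments stay within
10% of the configured ones at n ≥ 10⁴.

Two outcome mechanisms:

* **temperature_generative** (default): eye temperature =
  38.1 + slope·max(0, THI − 70) + N(0, noise_sd). The 38.1 °C baseline
  is the average orbital temperature reported for healthy cattle, and
  the knee at THI 70 reflects the observed onset of the orbital-
  temperature rise. The slope default 0.032 °C per THI unit is fixed by
  requiring the implied mean eye temperature to match 38.3 °C given
  THI ~ N(75.37, 7.11) (E[max(0, THI−70)] ≈ 6.3), and noise_sd = 1.38
  by matching the 1.40 °C marginal SD. Those moments imply a weak
  THI signal relative to residual noise (in-sample AUC ≈ 0.59 for the
  fitted curves), so the generator reproduces the *structure* of the
  analysis, not any particular published performance level.
* **bernoulli_direct**: eye temperature is drawn from its marginal and
  labels are Bernoulli draws from a configured ABTP curve at each
  animal's THI. This makes dose-response parameter recovery exactly
  testable against known generating values.

The generator does not model time series or diurnal cycles, repeated
measures per animal (rows are independent), seasonal structure, or the
imager's optics beyond the noise term. Consequently, passing tests
demonstrate correctness of the estimators under the stated sampling
model — not predictive performance on real herds.

## LASSO factor ranking

Candidate factors (THI, temperature, humidity, age, days in milk,
parity, body weight, milk yield) are standardised to zero mean and unit
variance and entered into an L1-penalised binomial regression over 100
log-spaced penalties from λ_max (smallest penalty with an empty
support) down to λ_max/10⁴. Importance is *path entry order* — the
penalty at which a coefficient first becomes nonzero — with ties broken
by |coefficient| at the cross-validated penalty, then column order.
λ is selected by 10-fold outcome-stratified cross-validation minimising
binomial deviance. Solvers are scikit-learn's (liblinear per penalty;
coordinate-descent Lasso for the squared-error family used in analytic
oracle checks). Exactly duplicated columns are fitted once and the
coefficient split evenly among the duplicates — the symmetric
representative of the non-unique L1 solution — so entry order remains
well-defined. Note that in herds generated with the default mechanism
THI and ambient temperature are ≈0.99-correlated (THI is computed from
temperature and humidity), so entry order between them is genuinely
sample-dependent; with a THI-driven outcome THI enters first in the
large majority of replicates but not all.

## Effective-index (LKB_eff) model

The effective index couples body temperature into the LKB curve via a
power law Tn50(temp) = Tn50(1)·temp^(−c), c > 0, and an effective
temperature Temp_eff = Temp·(n/n_ref)^(−c) that renormalises an
observation to the reference factor level n_ref (identity when
n = n_ref, which holds exactly in the implementation). The combined
probability is Φ(u) with

    u = (dose − Tn50(1)·Temp_eff^(−c)) / (m·Tn50(1)·Temp_eff^(−c))

Two readings of `dose` are provided:

* `dose="reference"` (default): dose = n_ref, the published form. Here
  the observed factor enters only through Temp_eff^(−c) ∝ n^(c²) — a
  weak dependence that *decreases* the probability as the factor rises.
* `dose="observed"`: dose = n. The probability then rises steeply with
  the factor, iso-probability contours in the (temperature, factor)
  plane are ordered by probability level (the 20% contour lies at lower
  THI than the 50% contour at every temperature), and the model behaves
  like an LKB curve in n with a temperature-dependent threshold. This
  is the reading under which the two-region management chart (observe /
  alert bands with the THI-75 guide) is geometrically meaningful.

Both are kept because the choice is substantive, not cosmetic; the
default stays with the published numerator and the geometry tests use
the observed-dose reading.

All three parameters (Tn50(1), c, m) are estimated by joint MLE:
log-spaced grid (c ∈ [10⁻³, 1], m ∈ [0.005, 2], Tn50(1) bracketed from
n_ref and the mean body temperature) then Nelder-Mead in log-parameter
space. n_ref defaults to the mean observed factor value. Iso-probability
contours solve ABTP(thi, temp) = q per grid temperature by Brent
bisection to 10⁻¹⁰, with per-point unreachable flags.

**Identifiability.** Tn50(1) is the extrapolation of the power law to
temp = 1 °C, far outside any physiological range, so its log-error is
≈ ln(38.3) ≈ 3.6 times the error in c: the three parameters share a
likelihood ridge. The parameter-recovery experiment therefore uses a
steep, informative design — Tn50(1) = 75·38.3^0.25, c = 0.25,
m = 0.008, n_ref = 75, THI ~ U(55, 95), eye temperature ~ N(38.3, 1.4),
n = 5000 — chosen so that the curve spans the full probability range
over the data and all three parameters are recoverable to 10% relative
error in the large majority of replicates. Flatter configurations (small
c or large m) leave the probability nearly constant over realistic body
temperatures and are not identifiable at any reasonable sample size;
fits on such data return the flat-curve boundary and flag it.

## Evaluation battery

For each fitted model, in-sample (matching how univariate dose-response
fits are conventionally reported):

* **AUC** as Mann-Whitney concordance with half credit for ties, 95% CI
  from the DeLong structural-components variance (deterministic, unlike
  a bootstrap). The point estimate agrees with exhaustive pair
  enumeration to 1e-12 on every tested instance.
* **Accuracy** at the 50% cutoff with a strict `>` (probabilities at
  exactly 0.5 predict the negative class).
* **AIC** = 2k − 2·logL with k = 2 for every family, and **ΔAIC**
  against the LKB baseline (the baseline row renders as a dash; ΔAIC is
  invariant to shifting all log-likelihoods by a constant).
* **Brier score**, mean squared forecast error.
* **Hosmer-Lemeshow** over 10 equal-frequency probability bins (stable
  sort), statistic Σ(O−E)²/(E(1−E/n_g)), p-value from χ² with
  bins − 2 degrees of freedom — the convention for fitted models, which
  is the battery's use. For externally supplied forecasts the statistic
  is approximately χ² on `bins` degrees of freedom, so the default df
  makes the test mildly anti-conservative in that case; the test suite
  documents both behaviours. Zero-expectation bins merge with their
  neighbour (logged); fewer than three effective bins is an error.
* **Calibration**: per-bin mean predicted vs observed event rate, with
  count-weighted least-squares slope and intercept and the weighted
  correlation between bin rates. A single published scalar "calibration
  curve" value has no standard definition, so all three summaries are
  reported; a constant forecast makes the regression degenerate, which
  is flagged rather than silently NaN-propagated.

## Pipeline and reproducibility

One global seed determines every artifact byte: herd draws, label
draws, cross-validation folds. JSON artifacts are written with sorted
keys and full-precision floats and stamped with a hash of the
scientific configuration (output paths excluded) plus the seed;
rerunning an identical configuration reproduces identical files.
Default problem sizes — 320-animal herds, 100-replicate recovery
experiments, n = 5000 for the three-parameter effective-index recovery —
are chosen as the smallest sizes at which the corresponding estimators
are stable, and are configuration values, not constants.

## Known limitations

* The annual-mean labelling rule is a screening construction; its
  one-sidedness and zero offset are defaults, not estimates.
* The verbatim (reference-dose) effective-index surface is nearly
  insensitive to the factor value; quantitative factor-side conclusions
  from it should use the observed-dose reading.
* The evaluation is in-sample; no cross-validated performance
  estimation or threshold optimisation is provided.
* The generator's Gaussian, cross-sectionally independent design cannot
  exhibit herd-level clustering, repeated measures, or seasonal
  confounding; external validity of any fitted threshold rests on real
  data.
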