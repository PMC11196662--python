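# abtp — abnormal body temperature probability models for dairy cattle

Heat stress is the dominant welfare and productivity risk for lactating
dairy cows in hot-humid climates. `abtp` is a Python package for
modelling the **abnormal body temperature probability (ABTP)**: the
probability that an animal's eye-socket (orbital) temperature, measured
by non-contact infrared thermography, is elevated above a herd
reference, as a function of a quantitative heat-stress factor — in
practice the temperature-humidity index

```
THI = (1.8·T + 32) − (0.55 − 0.0055·RH)·(1.8·T − 26)
```

with T the air temperature (°C) and RH the relative humidity (%).

It is written for veterinary epidemiologists and precision-livestock
researchers who want a tested, reproducible version of this analysis:

* **Synthetic herd generation** with configurable marginal moments
  (defaults emulate a 320-cow Holstein-Friesian monitoring dataset:
  eye temperature 38.3 ± 1.40 °C, THI ≈ 75 ± 7, etc.) and a known
  ground-truth THI→abnormality mechanism, so every estimator is
  testable without access to farm data.
* **Risk-factor ranking** of the eight candidate factors (THI,
  temperature, humidity, age, days in milk, parity, body weight, milk
  yield) by L1 (LASSO) coefficient-path entry order with
  cross-validated penalty selection.
* **Four sigmoid dose-response families** fitted by maximum likelihood,
  each parameterised by the 50%-probability location Tn50 plus one
  slope parameter: the Lyman-Kutcher-Burman probit
  `Φ((n − Tn50)/(m·Tn50))`, the logistic `1/(1+e^−(β0+β1·n))`, the
  log-logistic (Schultheiss) `1/(1+(Tn50/n)^k)` and the Poisson
  tolerance model `2^(−exp(e·γ·(1−n/Tn50)))`; fitted curves invert to
  TT50/TT20 alert thresholds.
* An **effective-index (LKB_eff) extension** coupling body temperature
  into the curve through a power law `Tn50(temp) = Tn50(1)·temp^(−c)`,
  with iso-probability contours for two-region management charts.
* A **model-comparison battery**: AUC with DeLong 95% CI, accuracy at
  the 50% cutoff, AIC/ΔAIC against the LKB baseline, Brier score,
  Hosmer-Lemeshow test and calibration slope/intercept.
* **Triage utilities**: normal / observe / abnormal temperature bands
  (defaults 38.32 °C and 38.32 × 1.02 ≈ 39.09 °C) and the THI > 75
  environmental alert.

See `docs/methods.md` for the statistical details and design
decisions.

## Worked example

```python
import numpy as np
from abtp import (HerdConfig, ABTPParams, LabeledDataset, generate_herd,
                  generate_labels_direct, label_abnormal, fit_abtp, invert_ttq,
                  predict, evaluate_models, fit_lasso_path, rank_factors)

# a 320-animal herd whose abnormality risk is driven by THI through a
# logistic curve with a 50%-probability point at THI = 75
truth = ABTPParams.from_logistic_coefficients(beta0=-22.5, beta1=0.30)
config = HerdConfig(n_animals=320, label_mechanism="bernoulli_direct",
                    ground_truth=truth, seed=1)
dataset = label_abnormal(generate_herd(config))
y = generate_labels_direct(dataset.X["thi"].to_numpy(), truth, seed=2)
dataset = LabeledDataset(X=dataset.X, y=y)

ranking = rank_factors(fit_lasso_path(dataset))
print("factor ranking:", ranking[:3], "...")

thi_values = dataset.X["thi"].to_numpy()
fits = {fam: fit_abtp(fam, thi_values, dataset.y)
        for fam in ("LKB", "Logistic", "Schultheiss", "Poisson")}
for fam, fit in fits.items():
    print(f"{fam:12s} TT50={invert_ttq(fit, 0.5):6.2f}  TT20={invert_ttq(fit, 0.2):6.2f}"
          f"  logL={fit.log_likelihood:8.2f}")

preds = {fam: np.asarray(predict(f.params, thi_values)) for fam, f in fits.items()}
report = evaluate_models(dataset.y, preds, fits, baseline="LKB")
print(report.table[["auc", "accuracy", "brier", "hl_p", "delta_aic"]].round(3).to_string())
```

Output:

```
factor ranking: ['thi', 'ambient_temp', 'milk_yield'] ...
LKB          TT50= 74.86  TT20= 69.68  logL= -147.89
Logistic     TT50= 74.82  TT20= 70.02  logL= -146.86
Schultheiss  TT50= 74.70  TT20= 70.09  logL= -146.48
Poisson      TT50= 74.16  TT20= 69.71  logL= -147.50
               auc  accuracy  brier   hl_p  delta_aic
model
LKB          0.866     0.784  0.148  0.372        NaN
Logistic     0.866     0.781  0.147  0.571     -2.046
Schultheiss  0.866     0.778  0.147  0.710     -2.813
Poisson      0.866     0.784  0.148  0.649     -0.776
```

THI enters the LASSO path first, and all four fitted TT50 values sit
within one THI unit of the generating value 75: at THI ≈ 75 the model
predicts a coin-flip risk of abnormal temperature, and TT20 ≈ 70 marks
the 20% early-warning level. The ΔAIC column compares each family to
the LKB baseline (its own row is blank); negative values mean a better
in-sample fit on this draw. The Hosmer-Lemeshow p-values above 0.05
indicate no detectable miscalibration.

## Command line

The same workflow is available as subcommands —
`abtp simulate | label | select | fit | evaluate | effective-index | run` —
where `run` executes the full pipeline from one YAML/JSON configuration
and writes CSV/JSON reports plus the LASSO-path, fitted-sigmoid and
triage-chart figures:

```
abtp run --seed 1 --out-dir results/
```

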