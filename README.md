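# augbin

Efficient analysis of composite responder endpoints in small randomized
trials.

Responder endpoints common in rheumatology and rare-disease trials combine
a dichotomized continuous score (e.g. a percent-improvement measure cut at
20/50/70%) with binary failure rules (rescue medication, protocol-restricted
treatment, withdrawal). The usual analysis collapses everything to a binary
flag and runs a logistic regression, discarding how close each patient was
to responding. `augbin` implements the more efficient *augmented binary*
estimator — a factorized joint model of the continuous outcomes at the
scheduled visits and the per-interval failure indicators — together with the
standard binary comparator, and the two small-sample corrections that make
both usable at n = 30–80:

- **Firth penalized likelihood** for every logistic component (finite,
  bias-reduced estimates even under perfect separation), with a
  linear-program separation diagnostic;
- **MBN sandwich-variance inflation** for GEE fits of the continuous
  component (corrects the downward small-sample bias of robust SEs).

Treatment effects are reported on the log-odds, risk-difference and
log-risk-ratio scales with delta-method confidence intervals, standardizing
every patient to both arms. A simulation engine generates calibratable
synthetic trials, supports re-sampling and permutation-null harnesses, and
estimates power, type I error, coverage, CI width and the
separation-frequency diagnostic over a sample-size grid.

## Layout

| module               | contents                                                         |
| -------------------- | ---------------------------------------------------------------- |
| `augbin.datasets`    | `TrialDataset`, `AnalysisConfig`, responder derivation, CSV/YAML |
| `augbin.firth`       | ML / Firth logistic regression, separation detection             |
| `augbin.longitudinal`| GLS (normal ML, unstructured covariance), GEE, MBN correction    |
| `augbin.augmented`   | joint fit, response-probability quadrature, effect estimates     |
| `augbin.standard`    | standard binary comparator                                       |
| `augbin.effects`     | effect scales and delta-method machinery                         |
| `augbin.simulate`    | generator, calibration, resampling/permutation, OC engine        |
| `augbin.reporting`   | pairwise CI-width comparisons, JSON / text reports               |

## CLI

```sh
# generate a calibrated synthetic trial (response rates 0.470 vs 0.336)
augbin simulate --n 80 --seed 7 --out trial.csv

# fit the augmented binary method (GLS + Firth + MBN by default)
augbin fit --data trial.csv --scale log_odds

# standard binary comparator
augbin fit --data trial.csv --method binary --scale risk_difference

# operating characteristics over n = 30..80
augbin oc --methods binary,augbin-gls --mode power --n-grid 30:80:10 \
          --reps 1000 --seed 1 --out oc.json

# CI-width comparison table (width reduction -> implied sample-size saving)
augbin report --in oc.json --a binary-adjusted --b augbin-gls-adjusted
```

Input CSVs are patient-per-row: `patient_id, arm, baseline, y_1..y_T,
d_1..d_T` with empty cells for missing continuous outcomes; `d_t` are
absorbing failure indicators. Configuration YAML mirrors `AnalysisConfig`.

## Python API sketch

```python
import augbin

params = augbin.calibrate_generator(0.470, 0.336,
                                    augbin.default_generator_params())
data = augbin.generate_trial(params.replace(n_per_arm=40), seed=7)

cfg = augbin.AnalysisConfig(scale="log_odds")       # GLS + Firth + MBN
fit = augbin.fit_augmented_binary(data, cfg)
eff = augbin.estimate_effect(fit, data)
print(eff.estimate, (eff.ci_lower, eff.ci_upper), eff.p_bar_1, eff.p_bar_0)
```
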