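# lcra — latent class regression for multi-class reoffending risk

`lcra` implements a **latent class regression analysis** (LCRA, a
concomitant-covariate mixture of multinomial-logit experts) for
identifying subgroups of detained juveniles that differ in their risk of
reoffending, and for predicting the reoffending category of new cases.
It is aimed at forensic/biostatistical researchers who want to integrate
psychosocial and neurobiological measures in one risk model rather than
running separate moderation analyses.

## The model

Let `y` be the 3-category outcome (no / non-violent / violent reoffending
within 12 months), `z^c` a vector of psychosocial covariates (age,
neighbourhood SES, ethnicity, YPI-s psychopathic-trait scores, BPM-Y
problem scores, criminal friends, substance-use category, treatment
motivation, childhood trauma) and `z^p` a vector of continuous
neurobiological predictors (heart rate, pre-ejection period and
respiratory sinus arrhythmia, each at rest and as reactivity, plus
salivary cortisol and testosterone).  The density of the outcome is

```
f(y | z^c, z^p) = Σ_x  π(x | z^c) · f(y | x, z^p)
```

where the latent class `x ∈ {1..K}` follows a multinomial logit on the
covariates (concomitant model, class K as reference) and, within each
class, the outcome follows a multinomial logit on the predictors
(outcome "no reoffending" as reference).  Dummy coding yields 17
covariate and 8 predictor design columns, so the K-class model has
`Npar = K·2·9 + (K−1)·18` free parameters (18 / 54 / 90 for K = 1 / 2 / 3).

The package provides:

* **EM estimation** with random multi-starts, ridge-stabilised Newton
  M-steps, observed-information standard errors and Wald-Z effect
  screening (`|Z| ≥ 1.80`, a deliberately lenient two-sided level ≈ 0.07
  for exploratory subgroup description);
* **class enumeration**: L²-scale information criteria
  (BIC/AIC/AIC3/CAIC/SABIC penalised as `L² − penalty·df` with
  `df = N − Npar`), classification error, entropy pseudo-R², and a
  parametric bootstrap −2LLDiff test between nested class solutions;
* a **prediction tool** that assigns new cases (outcome unknown) a class
  membership from their covariates and a reoffending-category
  distribution from the full mixture;
* **external-validation metrics**: 3×3 confusion tables with per-category
  sensitivity / specificity / PPV / NPV under both margin conventions
  (standard, and the transposed-margin convention used in some published
  validation tables);
* a **synthetic cohort generator** that emulates the study sample's
  marginal distributions and a known-parameter version of the generative
  model, so the whole pipeline is testable without any restricted data.

The core estimator is scikit-learn style
(`LatentClassRegression(n_classes=3).fit(design)`, `predict_proba`,
`get_params`/`set_params`, fitted attributes with trailing underscores);
module-level functions (`fit_em`, `selection_table`, `bootstrap_lrt`,
`predict_batch`, `metric_report`, …) are thin wrappers around the same
machinery.

## Worked example

```python
import dataclasses, numpy as np
from lcra import (FitConfig, align_labels, class_outcome_profile, class_sizes,
                  default_study_spec, encode, fit_em, generate_cohort,
                  selection_table, predict_batch)

# a well-separated synthetic three-class cohort (classes sized 0.62/0.21/0.17)
spec = default_study_spec(n=1000, seed=7, separation=2.0)
records, _ = generate_cohort(spec)
design = encode(records)

table = selection_table(design, K_max=3, config=FitConfig(n_restarts=4, seed=11))
cols = ["K", "Npar", "L2", "BIC_L2", "AIC_L2", "SABIC_L2", "df", "CE", "R2", "neg2_ll_diff"]
print(table[cols].round(2).to_string(index=False))

fitted = align_labels(fit_em(design, FitConfig(n_classes=3, n_restarts=6, seed=11)))
print("class sizes:", np.round(class_sizes(fitted.posteriors), 2))
```

prints the class-enumeration table

```
 K  Npar      L2   BIC_L2  AIC_L2  SABIC_L2  df   CE   R2  neg2_ll_diff
 1    18 1805.52 -4977.90 -158.48  -1859.01 982 0.00 0.11           NaN
 2    54 1498.02 -5036.72 -393.98  -2032.17 946 0.00 0.26        307.50
 3    90 1361.99 -4924.07 -458.01  -2033.86 910 0.08 0.33        136.03
```

— AIC(L²) and SABIC(L²) are minimised at the generating K = 3 (lower is
better), while BIC(L²) prefers 2 classes, the familiar disagreement
between criteria in latent class analysis — and recovers the generating
class sizes:

```
class sizes: [0.61 0.19 0.2 ]
```

New cases are scored from a fitted model with outcome unknown:

```python
new = [dataclasses.replace(r, outcome=None) for r in records[:3]]
preds, summary = predict_batch(new, fitted.params)
for p in preds:
    print(p.case_id, np.round(p.class_posterior, 2), "->",
          p.outcome_label, np.round(p.outcome_probs, 2))
```

```
sim-00000 [0.72 0.04 0.24] -> non-violent [0.32 0.43 0.25]
sim-00001 [1. 0. 0.] -> no [0.69 0.17 0.13]
sim-00002 [0.89 0.03 0.08] -> violent [0.16 0.11 0.73]
```

Each line shows the covariate-based class membership (class 1 = lowest
risk) and the mixture distribution over reoffending categories with its
modal category.

The same pipeline is available from the shell:

```bash
lcra simulate -n 223 --seed 1 --out cases.csv --truth truth.json
lcra fit --cases cases.csv -K 3 --restarts 25 --seed 1 --out model.json
lcra select --cases cases.csv --kmax 3 --seed 1 --out table1.csv
lcra predict --model model.json --cases cases.csv --out pred.csv
lcra validate --pred pred.csv --obs cases.csv --out metrics.csv
```

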