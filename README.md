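# tallysurv

Neural discrete-time survival prediction for longitudinal claims-like
cohorts, with a visit-history **tally encoding** that lets standard
time-to-event networks use time-varying information.

## The problem

Survival models for localized breast cancer are usually fit on covariates
frozen at diagnosis: stage, grade, receptor status, age.  But much of
what determines survival happens afterwards — treatments given, adverse
events induced, comorbidities accrued, aging itself.  `tallysurv`
implements a simple, model-agnostic way to feed that history to standard
right-censored time-to-event networks: a patient's visits from diagnosis
onward are summarized as a 76-dimensional count vector —

* 46 treatment-category tallies `TR_j` (visits at which treatment *j* was
  administered),
* 18 adverse-event tallies `AE_k`,
* 6 age-bin tallies (bins ≤65, (65,70], …, >85),
* 6 comorbidity-bin tallies (bins ≤2, (2,4], …, >10),

appended to the one-hot-encoded time-fixed covariates.  Four model
families consume the resulting design matrix:

| family | head | loss |
|---|---|---|
| `deepsurv` | g(x) | Cox partial likelihood, Breslow ties |
| `coxtime` | g(t, x) | partial likelihood with time as an input covariate |
| `deephit` | PMF over K intervals + overflow | α·NLL + (1−α)·ranking(σ) |
| `nnet_survival` | K hazard logits | discrete-time (logistic-hazard) NLL |

Predicted curves S(t|x) come from the Breslow baseline for the
relative-risk families and from the discrete PMF/hazards for the others.
Performance is measured by the time-dependent concordance index c_td
(censoring-aware pair comparisons) and the IPCW integrated Brier score
(IBS).  Because the study data this design targets is access-restricted,
the package ships a synthetic cohort generator with a known discrete-time
logistic-hazard truth, used as the test bed throughout.  See
`docs/methods.md` for the full model and generator description.

## Worked example

```python
import numpy as np
from tallysurv import (SimulationConfig, simulate_cohort, build_design_matrix,
                       fit, predict_survival, concordance_td,
                       integrated_brier_score, HyperParams)

# a cohort whose survival signal lives in the visit history
cohort, _ = simulate_cohort(SimulationConfig.designed_separation(n=800), seed=0)
d = cohort.patients["duration"].to_numpy(float)
e = cohort.patients["event"].to_numpy(int)

for mode in ("fixed", "extended"):
    dm = build_design_matrix(cohort, mode)
    model = fit("deepsurv", dm, d, e, hp=HyperParams(epochs=50), seed=0)
    curves = predict_survival(model, dm.values, model.grid.times)
    print(mode, round(concordance_td(curves, d, e), 3),
          round(integrated_brier_score(curves, d, e,
                (0., float(model.grid.boundaries[-1]))), 3))
```

prints (in-sample, for illustration):

```
fixed 0.591 0.154
extended 0.843 0.066
```

— with only diagnosis-time covariates the model barely ranks subjects
(c_td 0.59) and its probability estimates are poor (IBS 0.15); adding the
history tallies lifts the concordance to 0.84 and cuts the Brier score by
more than half.  The honest held-out version of this contrast is what
`run_cv_comparison` (and the `compare` CLI subcommand) reports per model,
per encoding, with fold dispersion:

```
$ tallysurv simulate --n 2000 --seed 1 --designed-separation --out simdir
$ tallysurv compare --patients simdir/patients.csv --visits simdir/visits.csv \
      --scenario 1 --folds 5 --seed 1 --out cmp
```

The CLI also provides `encode`, `fit`, `evaluate`, `tune` (random search
over the documented hyperparameter space) and `curve` (per-patient
predicted survival with the median survival time).

## Layout

```
src/tallysurv/
  cohort.py       patients/visits tables, validation, scenario filters
  encoding.py     tally encoder and design matrices
  models.py       time grid, four losses, training, Breslow, prediction
  evaluation.py   Kaplan-Meier, time-dependent concordance, IPCW Brier
  simulate.py     synthetic cohort generator + sealed truth
  experiment.py   cross-validated comparison, random search, patient curves
  cli.py          command-line surface
  _autodiff.py    reverse-mode autodiff engine the networks run on
  networks.py     MLP + Adam
```
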