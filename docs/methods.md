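# Methods

## Problem setting

`tallysurv` predicts all-cause survival for subjects followed in a
longitudinal claims-like cohort — the motivating setting is elderly (65+)
women with stage I–III breast cancer observed from diagnosis through
irregular follow-up visits until death or right censoring.  Each subject
has time-fixed covariates recorded at diagnosis (age, race, marital
status, stage, grade, laterality, ER/PR/HER2 receptor status, baseline
comorbidity index) and a visit history: at each contact, the current age
and comorbidity index plus the sets of treatment categories (coded 1–46)
and treatment-induced adverse-event categories (coded 1–18) recorded that
day.  The outcome is `(duration, event)` with `event = 1` for observed
death and `0` for right censoring.

## The history-tally covariate extension

The package's central device turns an entire visit history into a fixed
76-dimensional count vector that can be appended to the time-fixed
covariates of any off-the-shelf survival network:

* `TR_j` (j = 1..46): number of visits at which treatment category *j* was
  administered;
* `AE_k` (k = 1..18): number of visits at which adverse-event category *k*
  occurred;
* `AGE_b` (b = 1..6): number of visits at which the subject's age fell in
  bin *b*, with right-closed bins (≤65, (65,70], (70,75], (75,80],
  (80,85], >85);
* `COMB_b` (b = 1..6): the same for the comorbidity index with bins
  (≤2, (2,4], (4,6], (6,8], (8,10], >10).

Counting is per visit: a treatment recorded several times within one
visit counts once (claims rows within a day are effectively deduplicated
by the set representation).  By default tallies run from diagnosis to the
end of the subject's follow-up.  This makes the features depend on
follow-up length — a subject followed longer accrues more visits — which
couples the covariates to the outcome.  We keep the whole-follow-up rule
as the default because it is the convention the extension was designed
with, and expose an `as_of` landmark (`encode_history(visits, as_of=t)`,
`build_design_matrix(..., as_of=t)`) that restricts tallies to visits with
`t_visit ≤ t` for users who need leakage-free prospective features.  The
fixed-vs-extended performance contrast reported by the experiment module
should therefore be read as "how much predictive signal the history
summary carries", not as the prospective accuracy of a deployable model.

Design-matrix assembly one-hot-encodes the categorical fixed covariates
(an explicit `unknown` level is a level like any other; levels unseen at
fit time map to a `<other>` catch-all and are logged).  Learned categorical
embeddings are deliberately not used: one-hot encoding is deterministic
and keeps the encoder unit-testable.  Continuous columns — the two numeric
fixed covariates and all 76 tallies — are z-scored with mean/sd computed
on the training rows only; zero-variance columns map to all-zeros rather
than NaN.  Missing numeric values are imputed with the training-fold
median; missing categoricals fall into `unknown`.

## The four model families

All four models share one network body: a multilayer perceptron with
`n_layers` hidden ReLU layers of `n_nodes` units, dropout after each
hidden layer, and a linear head.  `n_layers = 0` degenerates to a linear
model (used for recovery checks).  They differ in the head dimension and
the loss.

**DeepSurv** (proportional hazards).  The network outputs one score
g(x), trained by the negative Cox partial log-likelihood averaged over
event subjects, with Breslow handling of ties:

    L = mean over events i of [ log Σ_{j: T_j ≥ T_i} exp g(x_j) − g(x_i) ].

Survival comes from the Breslow baseline cumulative hazard
H₀(t) = Σ_{event times T_i ≤ t} d_i / Σ_{j∈R_i} e^{g(x_j)} via
S(t|x) = exp(−H₀(t) e^{g(x)}).

**Cox-Time** (time-dependent relative risk).  The score g(t, x) takes
(standardized) time as an input, dropping proportionality while keeping
the partial-likelihood form; for each event subject the whole risk set is
scored at that subject's event time.  The loss is averaged over event
subjects.  An optional uniform risk-set subsample (always containing the
event subject) bounds the quadratic cost; the default is the full risk
set.  Prediction uses the time-dependent Breslow estimator: the hazard
increment at training event time T_i for a new subject x is
d_i · e^{g(T_i, x)} / Σ_{j∈R_i} e^{g(T_i, x_j)}.

**DeepHit** (discrete-time PMF, single event).  The head has K + 1
outputs — one per grid interval plus one beyond-horizon cell, so the
softmax PMF stays proper when follow-up exceeds the grid — and the loss is
α · NLL + (1 − α) · rank, where the NLL credits an event in interval k
with log f(k) and a censoring with log(1 − F(k)), and the ranking term
averages exp(−(F_i(k_i) − F_j(k_i))/σ) over comparable pairs (i an event,
k_i < k_j).  Only the single-event case is implemented; the competing-risks
generality of the family is out of scope here.

**Logistic hazard / Nnet-survival** (discrete-time hazards).  The head
outputs K per-interval hazard logits; the loss is the mean negative
log-likelihood of the discrete survival process, identical to Bernoulli
log-loss on the person-period expansion (one row per subject-interval at
risk).  Survival is S(τ_k) = Π_{m≤k}(1 − h_m).

### Loss normalization

The partial-likelihood losses are averaged over *event* subjects rather
than all subjects.  Both constants give the same optimum; mean-over-events
keeps gradient magnitudes independent of the censoring fraction across
mini-batches, which stabilizes Adam's effective step size.

### Time grid

Discrete families use a quantile grid: K = 20 intervals by default, with
boundaries at empirical quantiles of the training *event* durations
(right-closed intervals, last boundary at the maximum observed training
duration).  Fewer distinct event times shrink the grid with a warning.
K = 20 balances resolution against per-interval event counts at the
cohort sizes this package targets; it is configurable (`n_intervals`).

### Training

Mini-batch Adam (β = 0.9/0.999) with the configured learning rate, at
most `epochs` epochs, early stopping with patience 10 epochs on the loss
of a held-out 20 % event-stratified split of the training rows, restoring
the best-validation parameters.  Batches without any event are skipped for
the partial-likelihood losses (the loss is undefined there).  A non-finite
loss aborts with the epoch number.  Everything is driven by one
`numpy.random.Generator` seeded from the `seed` argument, so identical
seeds give bit-identical parameters.  The networks and their gradients
run on a small reverse-mode automatic-differentiation engine over numpy
arrays (`tallysurv._autodiff`) — dense linear algebra plus the handful of
primitives the losses need — with finite-difference gradient checks in the
test suite.

### Hyperparameter space

The search space is: batch size {32, 64, 128, 256, 512}; epochs
{100, 200, 300, 500}; dropout {0.001, 0.01, 0.1, ..., 0.8}; layers 2–5;
nodes {32, 64, 128, 256, 512}; α {0.0, 0.001, 0.1, 0.2, 0.5, 0.8, 0.9,
0.99, 1.0}; σ {0.01, 0.1, 0.25, 0.5, 1.0, 10, 100}; learning rate
continuous in [0.0001, 0.1].  `random_search` samples every field
uniformly (the learning rate linearly on its range), scores each trial by
validation concordance on an inner split, and returns the arg-max trial
with the full trace.  Random search was chosen over Bayesian optimization
because it is dependency-free, trivially reproducible and auditable from
the trace; the space searched is identical.  Tuning is per (model,
scenario) when used inside scenario loops.

## Evaluation

**Time-dependent concordance** (Antolini-style): over comparable pairs —
(i, j) with T_i < T_j and i an observed event, plus tied times with i an
event and j censored — the fraction where S_i(T_i) < S_j(T_i), ties in
the prediction scoring ½.  It is invariant to monotone transforms of the
predicted curves and reduces to Harrell's C under proportional hazards.
No comparable pairs raises an error rather than returning 0.5.

**IPCW Brier score** (Graf):

    BS(t) = (1/n) Σ_i [ S_i(t)² · 1{T_i ≤ t, D_i = 1} / Ĝ(T_i−)
                      + (1 − S_i(t))² · 1{T_i > t} / Ĝ(t) ],

with Ĝ the Kaplan–Meier estimate of the censoring distribution (flipped
indicators), evaluated with a left limit for the event term so a subject
does not weight itself at its own event time.  Subjects censored by t
contribute nothing; zero-weight terms are dropped with a logged count.
The integrated score is a 100-point trapezoid over (0, max observed
duration) by default, divided by the range length; both the grid and the
range are configurable.  The Kaplan–Meier estimator itself is implemented
directly (product-limit with explicit left-limit evaluation) and
cross-checked against lifelines in the tests; the Brier implementation is
cross-checked against scikit-survival.

## Cross-validated comparison

`run_cv_comparison` runs event-stratified k-fold cross-validation
(default 5).  Fold labels come from an md5 hash of (seed, patient_id), so
the split is independent of row order; the cohort is additionally brought
to a canonical patient-id sort before fitting so the whole table is
row-order invariant.  Imputation, categorical levels, standardization and
the time grid are all fitted within training folds only.  The output
table holds per-fold concordance and IBS per (model, encoding) cell, with
mean ± SD summaries shaped like the usual model-comparison tables.

## The synthetic cohort generator

Real registry-claims data of this kind is access-restricted, so the test
bed is simulated.  The generative truth is a discrete-time logistic
hazard on 30-day intervals:

    h_ik = sigmoid( b0 + β_fixed · x_i + β_varying · z_ik ),

where x_i are unit-scale transforms of the fixed covariates (age centered
at 75 per decade, comorbidity index standardized, stage and receptor-group
indicators) and z_ik are the subject's true cumulative tallies as of the
end of interval k.  Per interval, while at risk: visit counts are
Poisson(`visit_rate`, default 0.6 per 30 days ≈ 7 contacts/year); each
visit draws every treatment category independently (per-category
probabilities defaulting to a decaying profile, a few common categories
near 0.25 and a long rare tail) and likewise adverse events; the
comorbidity index drifts upward by exponential increments; age advances
with calendar time.  Death in interval k is a Bernoulli draw at h_ik;
independent per-interval dropout (default 0.003) and administrative
censoring at `admin_censor_time` intervals (default 120 ≈ 10 years)
produce right censoring; death and dropout in the same interval resolve
to death.  Durations are emitted as interval ends, so observed times are
genuinely discrete — consistent with the discrete-time modeling stance.
Fixed-covariate marginals mimic an elderly registry cohort: age
truncated-normal(75, 7) at ≥65, a hormone-receptor-negative minority
(~17 %), later stages enriched in the receptor-negative group, ~2 %
unknown receptor status.

The covariate and visit processes are simulated over the full horizon for
every subject, so the sealed truth record carries complete counterfactual
hazard paths; `oracle_survival` converts them to true curves
S(k) = Π_{m≤k}(1 − h_m), which Monte-Carlo checks compare against
empirical survival.  Only visits up to the observed exit are emitted, and
emitted ages/comorbidities are rounded exactly as tallied so the truth
tallies agree with `encode_history` applied to the written tables.

Choosing the logistic hazard as the generative law makes the logistic-
hazard family well-specified: an unpenalized logistic regression on the
person-period expansion with the true as-of tallies
(`fit_person_period_glm`, a standard GLM fit) recovers the generative
coefficients, separating estimator correctness from model
misspecification.  The other three families are held to ranking-quality
standards only.

The `designed_separation` configuration concentrates the signal in the
history: near-null fixed effects and strong coefficients on two treatment
tallies (±0.25), one adverse-event tally (+0.4) and high-comorbidity
exposure (+0.2), sized so the time-varying contribution spans roughly ±2
logits over a typical follow-up without saturating the hazard.  Under
these conditions extended-encoding models must beat fixed-encoding models
on both metrics, which is the qualitative shape of the headline
fixed-vs-extended contrast; note that part of the extended advantage
comes from the follow-up-length information in whole-history tallies (see
the leakage discussion above), in the synthetic cohort just as in real
cohorts encoded this way.

### What the generator does not emulate

No claims/billing structure, no diagnosis-code vocabularies, no clinical
meaning for the 46/18 category codes, no seasonality or visit clustering,
no dependence of visit intensity on health status (visits are independent
of the hazard given the covariates), and no construction rule for the
comorbidity index beyond "nonnegative and drifting".  Passing tests
therefore demonstrate correctness of the estimators and the direction of
the encoding contrast under a known truth — not clinical performance on
real claims data.

## Numerical choices

* Probabilities inside logs in the discrete losses are guarded by
  ε = 1e-7; the logistic-hazard loss is computed in softplus form and
  needs no guard.
* Log-sum-exp style reductions subtract detached per-risk-set maxima.
* Ties in event times share risk sets (Breslow); tied predictions score ½
  in the concordance.
* Step-function convention everywhere: curves are right-continuous,
  S(t) = 1 before the first grid time, evaluation beyond the grid clamps
  to the last value with a warning.
* Default deliberate problem sizes in the test suite and acceptance
  script: oracle checks at n ≤ 10–20 against O(n²)/enumeration oracles;
  distributional checks at n = 10,000–50,000; the cross-validated
  contrast at n = 2,000 with 2-layer / 32-node networks, 5 folds.

## Known limitations

Single event type (no competing risks); no recurrent events; CPU-only
dense numerics sized for cohorts of order 10⁴, not 10⁶; the Cox-Time
baseline and prediction are O(events × subjects) network evaluations; the
whole-follow-up tally default leaks follow-up length by construction (use
`as_of` landmarking for prospective features); hormone-receptor grouping
treats ER+ or PR+ as the positive group and requires both negative for
the negative group — subjects with both receptors unknown belong to no
scenario.
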