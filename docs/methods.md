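# Methods

## Model

The package estimates a latent class regression: a finite mixture in
which class membership is predicted by *concomitant* covariates and the
outcome is regressed on *predictor* indicators within each class,

    f(y | z^c, z^p) = Σ_{x=1..K} π(x | z^c) · f(y | x, z^p).

Both factors are multinomial logits.  `π(x | z^c)` has coefficients
`gamma` of shape (K−1) × (1+17): one row per non-reference class (class K
is the reference), an intercept column plus the 17 dummy-coded covariate
columns (1 age + 2 SES + 2 ethnicity + 3 YPI-s + 3 BPM-Y + 1 criminal
friends + 3 substance use + 1 treatment motivation + 1 trauma).
`f(y | x, z^p)` has coefficients `beta` of shape K × 2 × (1+8): per class,
one row per non-reference outcome category ("no reoffending" is the
reference; the contrasts are non-violent vs no and violent vs no), an
intercept plus the 8 neurobiological predictor columns.  The free
parameter count is therefore

    Npar = K·(C−1)·(1+P) + (K−1)·(1+Q) = 18, 54, 90  for K = 1, 2, 3

with C = 3 outcome categories, P = 8 predictors, Q = 17 covariate
columns.  The reduced "psychosocial-only" model keeps the class structure
but drops the predictor block (within-class intercept-only regressions,
P = 0), which is the minimal reading of removing the neurobiological
markers while preserving the mixture's architecture.

Assumptions: covariates act on the outcome only through class membership;
predictors act only within class (no direct covariate→outcome or
predictor→class paths, i.e. local independence given the class); cases
are independent; complete cases only — records with any missing covariate
or predictor are rejected, never imputed, matching the behaviour of the
prediction prototype the model supports.

Fixed conventions (any fixed choice is statistically equivalent, but it
must be fixed for coefficients to be comparable): reference levels
ses=low, ethnicity=Dutch, criminal_friends=no, substance_use=non-user;
reference outcome "no"; reference class K.  Continuous variables enter on
their raw reported scales (RSA at rest is expected already
log-transformed; the reader validates plausibility only).  An optional
z-scoring flag exists on `encode` and defaults off — parameter counts and
likelihood bookkeeping are invariant to it.

## Estimation

Maximum likelihood by EM with random restarts.

* **E-step.**  Responsibilities τ_ik ∝ π(k | z^c_i) · f(y_i | k, z^p_i),
  log-sum-exp stabilised (all softmax paths stay finite for coefficient
  magnitudes to at least ±50).
* **M-step.**  Two independent families of weighted multinomial-logit
  maximisations: `gamma` regresses the *soft* class targets τ on the
  covariates; each class's `beta` regresses the observed outcome on the
  predictors with τ_·k as case weights.  The solver is a damped Newton
  iteration (analytic gradient and Hessian, step halving) on the
  ridge-penalised negative log-likelihood; the ridge λ = 1e-6 on all
  coefficients keeps Hessians invertible under quasi-separation in small
  classes while perturbing estimates below reporting precision.  After
  the first EM sweep each family takes a single warm-started damped
  Newton step per iteration; because step halving never accepts an
  increase of the family objective this is a generalized EM and the
  monitored objective is still monotone.
* **Monitored objective.**  The ridge-penalised observed-data
  log-likelihood `LL − (λ/2)(‖gamma‖² + ‖beta‖²)` — the exact quantity
  the penalised M-steps ascend.  Its trace is stored and asserted
  non-decreasing (tolerance 1e-8); the raw log-likelihood is reported at
  the final parameters.  (The raw LL itself could in principle dip by
  O(λ·Δ‖θ‖²) between iterations; monitoring the penalised objective makes
  the monotonicity guarantee exact.)
* **Stopping.**  Relative change of the objective < tol (default 1e-8),
  or an Aitken acceleration criterion: when successive gains shrink
  geometrically, stop once the projected remaining gain of the geometric
  tail falls below tol.  Cap at max_iter = 500.  Non-convergence in every
  restart is flagged (`converged=False`), never silent.
* **Starts.**  Initial responsibilities drawn per case from a symmetric
  Dirichlet(1,…,1), seeded; default 25 restarts, best final objective
  wins.  Identical seed + data give bitwise-identical trajectories.
  K = 1 needs no restarts (the model is a single multinomial logit and
  the first M-step solves it exactly).
* **Label switching.**  Classes are relabelled after fitting by
  descending class-conditional probability of no reoffending (class 1 =
  lowest risk); ties within 1e-9 break by class size descending.  `gamma`
  is re-referenced through the full K-row logit representation, so the
  likelihood is exactly unchanged; stored standard errors are invalidated
  by re-referencing and are recomputed on demand.

**Standard errors and effect screening.**  SEs come from the observed
information matrix — the negative numerical Hessian of the observed-data
log-likelihood at the optimum (statsmodels' finite-difference Hessian).
If the information matrix is singular (e.g. duplicated design columns),
entries loading on its null space are flagged unavailable (NaN), not
fabricated.  Effects are screened by Wald Z = estimate/SE with a default
threshold |Z| ≥ 1.80.  A two-sided type-I level of 0.07 — the lenient
level appropriate to an exploratory subgroup description — corresponds to
z ≈ 1.812; the default follows the 1.80 convention used when such effect
displays are plotted, and both the threshold and α are config values.

## Class enumeration

* **L² convention.**  With continuous covariates every case is unique, so
  the saturated reference is taken as perfect per-case prediction
  (LL_sat = 0), giving L² = −2·LL and df = N − Npar.  This reproduces the
  residual-df bookkeeping of standard LCA software output exactly, and
  all likelihood *differences* are invariant to the convention.  The
  convention is recorded in the `select` stage's JSON sidecar.
* **Information criteria** on the L² scale, lower better:
  BIC(L²) = L² − ln(N)·df, AIC(L²) = L² − 2df, AIC3(L²) = L² − 3df,
  CAIC(L²) = L² − (ln N + 1)·df, SABIC(L²) = L² − ln((N+2)/24)·df.
  Conventional LL-scale versions (−2LL + penalty·Npar) are emitted
  alongside for cross-package comparison.  (Under the perfect-prediction
  saturation the two scales differ per model by the constant penalty·N,
  so their rankings coincide; the disagreement flag in the output guards
  the general case.)
* **Classification error** CE = mean over cases of (1 − max posterior);
  **pseudo-R²** is entropy-based: 1 − Σ −log f(y_i|z_i) / Σ −log p̂(y_i)
  against the outcome-marginal null.  The R² definition used by
  commercial LCA software is not published, so printed R² values from
  study reports are not comparison targets.
* **Bootstrap LRT.**  −2LLDiff between nested class solutions is referred
  to a parametric bootstrap: simulate B outcome vectors from the fitted
  smaller model at the observed covariates/predictors, refit both models
  on each replicate with the *same* start protocol as the observed fits
  (asymmetric optimisation effort between observed and replicate fits
  would bias the null distribution — a warm-start shortcut for replicates
  was evaluated and rejected for exactly this reason), and report
  p = (1 + #{replicate ≥ observed}) / (B_used + 1).  Replicates where
  either refit fails to converge are dropped and counted; >20% dropped
  flags the result unreliable.  Default B = 500.

## Prediction and validation

For a new case the outcome is unknown, so class membership is the
concomitant prior π(· | z^c) and the outcome distribution is the full
mixture; the modal category is reported, exact ties break toward the less
severe category (no < non-violent < violent) and near-ties (gap < 1e-6)
are flagged.  A post-hoc mode conditioning class membership on an
observed outcome exists for internal validation.

Confusion tables are oriented rows = observed, columns = predicted.  Two
metric conventions are first-class and tagged in every output: *standard*
(sensitivity = TP/row, PPV = TP/column) and *as-published* (the same
formulas with the margins exchanged — equivalently standard metrics on
the transposed table), because published multi-class validation tables
sometimes follow the exchanged-margin orientation and only carrying both
keeps each reproducible.  Overall accuracy (trace/N) is identical under
both.  Zero-denominator metrics report 0.0 with a degenerate-denominator
flag.  Display rounding is half-up to 2 decimals; machine outputs keep
raw values.

## Synthetic data

The generator draws covariates independently from marginal distributions
emulating the study sample (categorical level frequencies; truncated
normals for continuous scores, e.g. age 18.49 ± 1.73 truncated to 12–24,
cortisol 9.71 ± 3.25 nmol/L, testosterone 284.6 ± 75.1 pmol/L), then the
latent class from π(x | z^c) at known `gamma`, then predictors from their
marginals (optionally with per-class mean offsets), then the outcome from
f(y | x, z^p) at known `beta`.  True class labels are returned as a
separate artifact and never written into a cases CSV.

`default_study_spec()` fixes the generating parameters once:

* within-class outcome profiles at mean predictors of
  (0.81, 0.14, 0.05), (0.45, 0.31, 0.24) and (0.27, 0.43, 0.30) for the
  low/medium/high-risk classes;
* standardized concomitant effects (per-SD log-odds, ±0.3–1.2) that
  caricature the three subgroups — an older, non-Dutch, low-trauma
  low-risk class; a younger medium-risk class with criminal friends,
  adverse environment and high trauma; a Dutch, high-SES, externalizing
  high-risk reference class — and sparse standardized predictor slopes
  (±0.6–0.8) with ANS and endocrine effects differing across classes;
* concomitant intercepts calibrated numerically (fixed internal
  calibration sample, iterative intercept adjustment) so the marginal
  class sizes are (0.62, 0.21, 0.17) within ±0.03 under the generated
  covariate distribution.  The builder is cached and pure: repeated calls
  return identical parameters.

`separation` scales every standardized effect (intercepts recalibrated).
The default 1.0 represents realistic overlap; at this setting the mixture
likelihood is genuinely flat — a maximum-likelihood fit at n ≈ 2000 can
miss the class sizes by ~0.08 while beating the generating parameters'
likelihood — which is a property of the estimand, not the optimizer.
Parameter-recovery experiments therefore use the well-separated variant
(separation = 2.0), where n = 2000 fits recover class sizes to ≲0.01 and
the signs of all large standardized effects.

What the generator does **not** emulate: cross-correlations among
covariates (only marginals are reproduced; a correlation hook exists but
is off by default), measurement error in physiology, follow-up censoring,
or per-class covariate descriptives (per-class effects are user-chosen,
not fitted to any table).  Passing tests on synthetic cohorts therefore
demonstrate correctness of the machinery and recoverability under the
stated generative model, not the field validity of any particular fitted
coefficient.

## Test-scale choices

Statistical property tests run at deliberately reduced problem sizes: the
bootstrap type-I calibration uses a 3-covariate/2-predictor design,
n = 120 per replication, B = 99 bootstrap replicates and 200 outer
replications with single-restart fits and a relaxed EM tolerance (3e-4,
Aitken-projected) — the calibration property of the p-value is invariant
to design size, and both observed and replicate fits share one protocol.
Recovery experiments use n = 2000 and two seeds; the Wald null-rate check
uses 40 replications of n = 400 with K = 1.  All experiment seeds are
fixed in the tests.

## Known limitations

* One latent variable, nominal outcome only; no ordinal link, no
  local-dependence (direct-effect) extensions, no missing-data handling.
* Numerical equality with any particular commercial-software fit of the
  original study data is out of reach (data unavailable, start/convergence
  settings unpublished); the package instead pins down everything that is
  desk-checkable (parameter accounting, index formulas, validation
  arithmetic) and validates estimation by simulation.
* The EM surface is multimodal at realistic overlap; with few restarts
  different seeds can settle in different local optima.  Restarts are
  cheap insurance and the per-start final objectives are always reported.
* The bootstrap LRT inherits the usual parametric-bootstrap caveat that
  replicates are drawn at the *fitted* null parameters, not the truth.
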