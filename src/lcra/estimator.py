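"""Maximum-likelihood estimation of the latent class regression model.

The estimator follows the scikit-learn conventions: construct with
hyper-parameters, call :meth:`LatentClassRegression.fit`, read fitted
attributes with trailing underscores, predict with
:meth:`~LatentClassRegression.predict` / :meth:`~LatentClassRegression.predict_proba`.

Fitting is EM with multiple random restarts:

* E-step — posterior responsibilities tau[i, k] proportional to
  pi(k | z^c_i) * f(y_i | k, z^p_i);
* M-step — two families of posterior-weighted multinomial-logit updates:
  the concomitant coefficients (gamma) regress the soft class targets on
  the covariates, and each class's outcome coefficients (beta) regress the
  observed outcome on the predictors with that class's responsibilities as
  case weights.  Both updates carry a small ridge penalty so the Newton
  steps survive quasi-separation in small classes.

The monitored objective is the ridge-penalized observed-data
log-likelihood, which EM increases monotonically; the raw log-likelihood is
reported at the final parameters.  Standard errors come from the observed
information matrix of the full observed-data log-likelihood (numerical
Hessian), and effects are screened with Wald Z scores against a threshold
of 1.80 (a deliberately lenient two-sided level of about 0.07 for this
exploratory subgroup analysis).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from sklearn.base import BaseEstimator

from .codebook import EncodedDesign
from .mnlogit import fit_weighted_mnlogit
from .model import (
    LCRAParameters,
    PosteriorMatrix,
    class_outcome_profile,
    class_sizes,
    log_likelihood,
    membership_log_probs,
    outcome_log_probs,
    posterior_class_probs,
)

__all__ = [
    "FitConfig",
    "FittedModel",
    "LatentClassRegression",
    "fit_em",
    "standard_errors",
    "wald_z_table",
    "align_labels",
]


@dataclass
class FitConfig:
    """Estimation settings (defaults are the package's study settings)."""

    n_classes: int = 3
    n_restarts: int = 25
    max_iter: int = 500
    tol: float = 1e-8
    ridge: float = 1e-6
    z_threshold: float = 1.80
    alpha: float = 0.07
    seed: int | None = None
    compute_se: bool = False

    def __post_init__(self) -> None:
        if self.n_classes < 1:
            raise ValueError("n_classes must be >= 1")
        if self.tol <= 0:
            raise ValueError("tol must be > 0")
        if self.ridge < 0:
            raise ValueError("ridge must be >= 0")


@dataclass
class FittedModel:
    """A fitted latent class regression: parameters plus diagnostics."""

    params: LCRAParameters
    log_likelihood: float
    objective_trace: np.ndarray  # ridge-penalized observed-data LL per iteration
    converged: bool
    posteriors: PosteriorMatrix
    n_cases: int
    n_iter: int
    restart_logliks: np.ndarray  # best penalized objective per restart
    config: FitConfig
    design: EncodedDesign | None = None
    se_gamma: np.ndarray | None = None
    se_beta: np.ndarray | None = None

    @property
    def n_classes(self) -> int:
        return self.params.n_classes

    def z_gamma(self) -> np.ndarray | None:
        if self.se_gamma is None:
            return None
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(self.se_gamma > 0, self.params.gamma / self.se_gamma, np.nan)

    def z_beta(self) -> np.ndarray | None:
        if self.se_beta is None:
            return None
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(self.se_beta > 0, self.params.beta / self.se_beta, np.nan)


def _penalty(gamma: np.ndarray, beta: np.ndarray, ridge: float) -> float:
    return 0.5 * ridge * (float(np.sum(gamma * gamma)) + float(np.sum(beta * beta)))


#: warm-started Newton steps per partial M-step after the first EM iteration;
#: one damped step per family per EM sweep is enough (generalized EM)
_INNER_NEWTON_STEPS = 1


def _log_softmax_rows(logits: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise log-softmax and log-normaliser (manual, allocation-lean)."""
    m = logits.max(axis=1, keepdims=True)
    e = np.exp(logits - m)
    lognorm = m + np.log(e.sum(axis=1, keepdims=True))
    return logits - lognorm, lognorm


def _em_single(
    design: EncodedDesign,
    K: int,
    tau0: np.ndarray,
    ridge: float,
    tol: float,
    max_iter: int,
) -> tuple[LCRAParameters, list[float], bool, int]:
    Zc = design.covariate_matrix
    Zp = design.predictor_matrix
    y = design.outcomes_or_raise()
    N = design.n
    C = 3
    Xc1 = np.hstack([np.ones((N, 1)), Zc])
    Xp1 = np.hstack([np.ones((N, 1)), Zp])
    Y = np.zeros((N, C))
    rows = np.arange(N)
    Y[rows, y] = 1.0

    gamma = np.zeros((K - 1, Xc1.shape[1]))
    beta = np.zeros((K, C - 1, Xp1.shape[1]))
    tau = tau0
    trace: list[float] = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # Partial M-steps (a few warm-started Newton steps with halving) never
        # decrease the family objectives, so the generalized EM stays monotone.
        inner = 25 if it == 1 else _INNER_NEWTON_STEPS
        # M-step: concomitant update (soft class targets, reference = last class)
        if K > 1:
            res_g = fit_weighted_mnlogit(
                Xc1, tau, ridge=ridge, ref=K - 1, coef0=gamma, max_iter=inner
            )
            gamma = res_g.coef
        # M-step: per-class outcome update with responsibilities as weights
        for k in range(K):
            Wk = Y * tau[:, k][:, None]
            res_b = fit_weighted_mnlogit(
                Xp1, Wk, ridge=ridge, ref=0, coef0=beta[k], max_iter=inner
            )
            beta[k] = res_b.coef
        # E-step, inlined on the raw coefficient arrays
        pi_logits = np.zeros((N, K))
        if K > 1:
            pi_logits[:, : K - 1] = Xc1 @ gamma.T
        logpi, _ = _log_softmax_rows(pi_logits)
        f_logits = np.zeros((N, K, C))
        f_logits[:, :, 1:] = (Xp1 @ beta.reshape(K * (C - 1), -1).T).reshape(N, K, C - 1)
        logf_y = (_log_softmax_rows(f_logits.reshape(N * K, C))[0]
                  .reshape(N, K, C)[rows, :, y])
        logjoint = logpi + logf_y
        logpost, lognorm = _log_softmax_rows(logjoint)
        tau = np.exp(logpost)
        ll = float(lognorm.sum())
        obj = ll - _penalty(gamma, beta, ridge)
        trace.append(obj)
        scale = max(1.0, abs(obj))
        if len(trace) > 1 and abs(trace[-1] - trace[-2]) < tol * scale:
            converged = True
            break
        # Aitken acceleration: stop once the projected remaining gain of the
        # geometric EM tail drops below tolerance
        if len(trace) >= 3:
            d1, d2 = trace[-2] - trace[-3], trace[-1] - trace[-2]
            if d1 > 0 and 0 < d2 < d1:
                projected = d2 * (d2 / d1) / (1.0 - d2 / d1)
                if projected < tol * scale:
                    converged = True
                    break
        if K == 1 and it >= 2:  # no latent structure: one M/E round suffices
            converged = True
            break
    return LCRAParameters(gamma=gamma, beta=beta), trace, converged, it


class LatentClassRegression(BaseEstimator):
    """Mixture-of-experts multinomial classifier with concomitant covariates.

    Parameters
    ----------
    n_classes : number of latent classes K (>= 1).
    n_restarts : random EM restarts; the best penalized log-likelihood wins.
    max_iter, tol : EM stopping rule (relative change in the penalized
        observed-data log-likelihood).
    ridge : L2 stabilizer on all coefficients inside the M-step Newton
        solves; the default 1e-6 perturbs estimates below reporting
        precision.
    z_threshold, alpha : Wald screening threshold for the effect tables.
    n_covariate_columns : where to split a plain feature matrix into the
        covariate block (class formation) and predictor block (within-class
        regression).  Ignored when ``fit`` receives an
        :class:`~lcra.codebook.EncodedDesign`.
    align : reorder classes after fitting so class 1 has the highest
        probability of no reoffending (lowest risk first).
    compute_se : also compute observed-information standard errors.
    random_state : seed for restart initialisation (Dirichlet posteriors).

    Attributes
    ----------
    params_ : fitted :class:`~lcra.model.LCRAParameters`.
    log_likelihood_ : observed-data log-likelihood at the optimum.
    posterior_probs_ : training-set posterior class membership.
    class_sizes_ : marginal class-size proportions.
    outcome_profile_ : K x 3 class-conditional outcome probabilities.
    converged_, n_iter_, objective_trace_, restart_logliks_ : diagnostics.
    """

    def __init__(
        self,
        n_classes: int = 3,
        n_restarts: int = 25,
        max_iter: int = 500,
        tol: float = 1e-8,
        ridge: float = 1e-6,
        z_threshold: float = 1.80,
        alpha: float = 0.07,
        n_covariate_columns: int = 17,
        align: bool = True,
        compute_se: bool = False,
        random_state: int | None = None,
    ) -> None:
        self.n_classes = n_classes
        self.n_restarts = n_restarts
        self.max_iter = max_iter
        self.tol = tol
        self.ridge = ridge
        self.z_threshold = z_threshold
        self.alpha = alpha
        self.n_covariate_columns = n_covariate_columns
        self.align = align
        self.compute_se = compute_se
        self.random_state = random_state

    # -- helpers -------------------------------------------------------
    def _as_design(self, X, y=None) -> EncodedDesign:
        if isinstance(X, EncodedDesign):
            return X if y is None else X.with_outcomes(np.asarray(y))
        X = np.asarray(X, dtype=float)
        q = self.n_covariate_columns
        if X.ndim != 2 or X.shape[1] < q:
            raise ValueError(
                f"X must be 2-D with at least n_covariate_columns={q} columns"
            )
        yv = np.full(X.shape[0], -1, dtype=int) if y is None else np.asarray(y, dtype=int)
        return EncodedDesign(
            covariate_matrix=X[:, :q],
            predictor_matrix=X[:, q:],
            outcome_vector=yv,
            covariate_names=[f"z_c{j}" for j in range(q)],
            predictor_names=[f"z_p{j}" for j in range(X.shape[1] - q)],
            reference_levels={},
        )

    # -- estimation ----------------------------------------------------
    def fit(self, X, y=None) -> "LatentClassRegression":
        design = self._as_design(X, y)
        config = FitConfig(
            n_classes=self.n_classes,
            n_restarts=self.n_restarts,
            max_iter=self.max_iter,
            tol=self.tol,
            ridge=self.ridge,
            z_threshold=self.z_threshold,
            alpha=self.alpha,
            seed=self.random_state,
            compute_se=self.compute_se,
        )
        fitted = fit_em(design, config)
        if self.align:
            fitted = align_labels(fitted)
        if self.compute_se:
            se_g, se_b = standard_errors(design, fitted.params, ridge_check=self.ridge)
            fitted = replace(fitted, se_gamma=se_g, se_beta=se_b)
        self.result_ = fitted
        self.params_ = fitted.params
        self.log_likelihood_ = fitted.log_likelihood
        self.objective_trace_ = fitted.objective_trace
        self.converged_ = fitted.converged
        self.posterior_probs_ = fitted.posteriors
        self.restart_logliks_ = fitted.restart_logliks
        self.n_iter_ = fitted.n_iter
        self.class_sizes_ = class_sizes(fitted.posteriors)
        self.outcome_profile_ = class_outcome_profile(design, fitted.params, fitted.posteriors)
        self.design_ = design
        self.n_features_in_ = design.covariate_matrix.shape[1] + design.predictor_matrix.shape[1]
        return self

    # -- prediction ----------------------------------------------------
    def predict_proba(self, X) -> np.ndarray:
        """Mixture outcome probabilities f(y | z^c, z^p), shape (N, 3)."""
        design = self._as_design(X)
        logpi = membership_log_probs(design.covariate_matrix, self.params_)
        logf = outcome_log_probs(design.predictor_matrix, self.params_)
        return np.exp(logsumexp(logpi[:, :, None] + logf, axis=1))

    def predict(self, X) -> np.ndarray:
        """Modal outcome category codes (0=no, 1=non-violent, 2=violent)."""
        return np.argmax(self.predict_proba(X), axis=1)

    def class_membership(self, X) -> np.ndarray:
        """Concomitant prior pi(x | z^c) per case, shape (N, K)."""
        design = self._as_design(X)
        return np.exp(membership_log_probs(design.covariate_matrix, self.params_))

    def posterior(self, X, y=None) -> PosteriorMatrix:
        """Posterior class membership; uses outcomes when provided."""
        return posterior_class_probs(self._as_design(X, y), self.params_)

    def score(self, X, y) -> float:
        """Mean per-case log-likelihood (sklearn convention: higher is better)."""
        design = self._as_design(X, y)
        return log_likelihood(design, self.params_) / max(design.n, 1)


def fit_em(
    design: EncodedDesign,
    config: FitConfig,
    init_params: LCRAParameters | None = None,
) -> FittedModel:
    """Best-of-restarts EM fit of the K-class model on an encoded design.

    Deterministic given ``config.seed``: restart initial responsibilities
    are drawn sequentially from one seeded generator.  When ``init_params``
    is given the first start is warm (responsibilities from an E-step at
    those parameters) and the remaining restarts stay random — used by the
    parametric bootstrap, whose replicates sit near the generating fit.
    """
    y = design.outcomes_or_raise()
    N = design.n
    K = config.n_classes
    from .selection import count_parameters  # local import avoids a cycle

    npar = count_parameters(
        K,
        n_predictor_columns=design.predictor_matrix.shape[1],
        n_covariate_columns=design.covariate_matrix.shape[1],
    )
    if N <= npar:
        warnings.warn(
            f"N={N} does not exceed the {npar} free parameters of the {K}-class model",
            UserWarning,
            stacklevel=2,
        )
    rng = np.random.default_rng(config.seed)
    n_restarts = 1 if K == 1 else max(1, config.n_restarts)
    best: tuple | None = None
    restart_objs = np.full(n_restarts, -np.inf)
    for r in range(n_restarts):
        if r == 0 and init_params is not None and init_params.n_classes == K:
            tau0 = posterior_class_probs(design, init_params).probs
        elif K == 1:
            tau0 = np.ones((N, 1))
        else:
            tau0 = rng.dirichlet(np.ones(K), size=N)
        params, trace, conv, n_iter = _em_single(
            design, K, tau0, config.ridge, config.tol, config.max_iter
        )
        restart_objs[r] = trace[-1]
        if best is None or trace[-1] > best[1][-1]:
            best = (params, trace, conv, n_iter)
    params, trace, conv, n_iter = best
    if not conv:
        warnings.warn(
            "EM did not converge in any restart within max_iter; "
            "result flagged converged=False",
            UserWarning,
            stacklevel=2,
        )
    posteriors = posterior_class_probs(design, params)
    col_mass = posteriors.probs.sum(axis=0)
    for k in np.nonzero(col_mass < 1.0)[0]:
        warnings.warn(
            f"degenerate class {int(k)}: posterior mass {col_mass[k]:.3g} "
            "(< 1 case equivalent)",
            UserWarning,
            stacklevel=2,
        )
    return FittedModel(
        params=params,
        log_likelihood=log_likelihood(design, params),
        objective_trace=np.asarray(trace),
        converged=conv,
        posteriors=posteriors,
        n_cases=N,
        n_iter=n_iter,
        restart_logliks=restart_objs,
        config=config,
        design=design,
    )


# -- standard errors and Wald tables ----------------------------------

def _pack(params: LCRAParameters) -> np.ndarray:
    return np.concatenate([params.gamma.ravel(), params.beta.ravel()])


def _unpack(theta: np.ndarray, like: LCRAParameters) -> LCRAParameters:
    ng = like.gamma.size
    gamma = theta[:ng].reshape(like.gamma.shape)
    beta = theta[ng:].reshape(like.beta.shape)
    return LCRAParameters(
        gamma=gamma if like.n_classes > 1 else like.gamma,
        beta=beta,
        class_labels=list(like.class_labels),
    )


def standard_errors(
    design: EncodedDesign,
    params: LCRAParameters,
    ridge_check: float = 0.0,
    null_space_tol: float = 1e-8,
) -> tuple[np.ndarray, np.ndarray]:
    """Observed-information standard errors at the fitted parameters.

    The information matrix is the negative numerical Hessian of the full
    observed-data log-likelihood.  Entries whose information is not
    positive-definite (e.g. a duplicated design column) are flagged
    unavailable as NaN rather than fabricated.
    """
    from statsmodels.tools.numdiff import approx_hess

    theta0 = _pack(params)

    def ll(theta: np.ndarray) -> float:
        return log_likelihood(design, _unpack(theta, params))

    H = approx_hess(theta0, ll)
    info = -(H + H.T) / 2.0
    eigval, eigvec = np.linalg.eigh(info)
    cutoff = max(eigval.max(), 0.0) * 1e-10
    bad = eigval <= cutoff
    se = np.full(theta0.shape, np.nan)
    if bad.any():
        # entries loading on the (near-)null space are unavailable
        load = (eigvec[:, bad] ** 2).sum(axis=1)
        ok = load <= null_space_tol
        inv_eig = np.where(bad, 0.0, 1.0 / np.where(bad, 1.0, eigval))
        cov = (eigvec * inv_eig) @ eigvec.T
        var = np.diag(cov)
        se[ok & (var > 0)] = np.sqrt(var[ok & (var > 0)])
    else:
        cov = np.linalg.inv(info)
        var = np.diag(cov)
        se[var > 0] = np.sqrt(var[var > 0])
    ng = params.gamma.size
    se_gamma = se[:ng].reshape(params.gamma.shape)
    se_beta = se[ng:].reshape(params.beta.shape)
    return se_gamma, se_beta


def wald_z_table(fitted: FittedModel, config: FitConfig | None = None) -> pd.DataFrame:
    """Flagged effect table: Z = estimate / SE, flag |Z| >= threshold.

    Partitioned into the covariate effects on class formation (the
    class-profile display) and the per-class predictor effects on the
    outcome (the neurobiological-profile display).
    """
    config = config or fitted.config
    if fitted.se_gamma is None or fitted.se_beta is None:
        assert fitted.design is not None, "need the training design to compute SEs"
        se_g, se_b = standard_errors(fitted.design, fitted.params)
        fitted = replace(fitted, se_gamma=se_g, se_beta=se_b)
    p = fitted.params
    design = fitted.design
    cov_names = ["intercept"] + (
        list(design.covariate_names) if design is not None else
        [f"z_c{j}" for j in range(p.gamma.shape[1] - 1)]
    )
    pred_names = ["intercept"] + (
        list(design.predictor_names) if design is not None else
        [f"z_p{j}" for j in range(p.beta.shape[2] - 1)]
    )
    rows = []
    ref_class = p.class_labels[-1]
    for k in range(p.n_classes - 1):
        for j, term in enumerate(cov_names):
            est = p.gamma[k, j]
            se = fitted.se_gamma[k, j]
            z = est / se if se and np.isfinite(se) and se > 0 else np.nan
            rows.append(
                {
                    "block": "covariate",
                    "class": f"{p.class_labels[k]} vs {ref_class}",
                    "contrast": "class membership",
                    "term": term,
                    "estimate": est,
                    "se": se,
                    "z": z,
                    "flagged": bool(np.isfinite(z) and abs(z) >= config.z_threshold),
                }
            )
    for k in range(p.n_classes):
        for c in range(p.n_outcomes - 1):
            contrast = f"{p.outcome_labels[c + 1]} vs {p.outcome_labels[0]}"
            for j, term in enumerate(pred_names):
                est = p.beta[k, c, j]
                se = fitted.se_beta[k, c, j]
                z = est / se if se and np.isfinite(se) and se > 0 else np.nan
                rows.append(
                    {
                        "block": "predictor",
                        "class": p.class_labels[k],
                        "contrast": contrast,
                        "term": term,
                        "estimate": est,
                        "se": se,
                        "z": z,
                        "flagged": bool(np.isfinite(z) and abs(z) >= config.z_threshold),
                    }
                )
    return pd.DataFrame(rows)


def _permute_params(params: LCRAParameters, order: Sequence[int]) -> LCRAParameters:
    """Relabel classes by ``order`` (new position -> old index)."""
    K = params.n_classes
    order = list(order)
    if sorted(order) != list(range(K)):
        raise ValueError("order must be a permutation of 0..K-1")
    Q1 = params.gamma.shape[1] if params.gamma.size else 1 + 0
    full = np.zeros((K, params.gamma.shape[1] if K > 1 else Q1))
    if K > 1:
        full[: K - 1] = params.gamma
        full = full[order]
        gamma = full[:-1] - full[-1]
    else:
        gamma = params.gamma
    beta = params.beta[order]
    labels = [params.class_labels[i] for i in order]
    return LCRAParameters(
        gamma=gamma,
        beta=beta,
        class_labels=labels,
        outcome_labels=list(params.outcome_labels),
        covariate_names=list(params.covariate_names),
        predictor_names=list(params.predictor_names),
    )


def align_labels(fitted: FittedModel, rule: str = "risk") -> FittedModel:
    """Resolve label switching by reordering classes.

    The default rule orders classes by descending class-conditional
    probability of no reoffending, so class 1 is the lowest-risk class;
    ties (within 1e-9) break by class size descending.  The likelihood is
    unchanged; stored standard errors are dropped because re-referencing
    the concomitant logit changes the parameterisation.
    """
    if rule != "risk":
        raise ValueError(f"unknown alignment rule: {rule!r}")
    K = fitted.params.n_classes
    if K == 1:
        return fitted
    assert fitted.design is not None, "alignment needs the training design"
    profile = class_outcome_profile(fitted.design, fitted.params, fitted.posteriors)
    sizes = class_sizes(fitted.posteriors)
    # descending P(no reoffending); ties by size descending
    keys = np.round(profile[:, 0] / 1e-9) * 1e-9
    order = sorted(range(K), key=lambda k: (-keys[k], -sizes[k]))
    if order == list(range(K)):
        return fitted
    params = _permute_params(fitted.params, order)
    posteriors = PosteriorMatrix(
        fitted.posteriors.probs[:, order],
        assignment_rule=fitted.posteriors.assignment_rule,
        used_outcome=fitted.posteriors.used_outcome,
    )
    return replace(
        fitted, params=params, posteriors=posteriors, se_gamma=None, se_beta=None
    )
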