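"""Class enumeration: fit indices, bootstrap LR tests, classification error.

The goodness-of-fit statistic L² is computed against a saturated reference
with perfect per-case prediction (log-likelihood 0), so L² = −2·LL.  With
entirely continuous covariates this is the only saturation convention that
keeps the residual-degrees-of-freedom bookkeeping df = N − Npar exact, and
every likelihood *difference* (−2LLDiff) is invariant to the convention in
any case.  The information criteria are penalized on the L² scale
(index = L² − penalty·df, lower is better):

    BIC(L²)   = L² − ln(N)·df
    AIC(L²)   = L² − 2·df
    AIC3(L²)  = L² − 3·df
    CAIC(L²)  = L² − (ln(N)+1)·df
    SABIC(L²) = L² − ln((N+2)/24)·df

Conventional log-likelihood-scale criteria (−2LL + penalty·Npar) are also
emitted for cross-package comparison; when the two scales rank the
candidate models differently the table flags it.

The number of latent classes is additionally tested by a parametric
bootstrap of −2LLDiff between nested class solutions: simulate outcome
vectors from the smaller fitted model at the observed covariates and
predictors, refit both models on each replicate, and compare the observed
statistic with the replicate distribution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .codebook import EncodedDesign
from .estimator import FitConfig, FittedModel, fit_em
from .model import PosteriorMatrix, mixture_outcome_probs

__all__ = [
    "FitIndices",
    "BootLRTResult",
    "count_parameters",
    "degrees_of_freedom",
    "information_criteria",
    "l2_statistic",
    "neg2_ll_diff",
    "bootstrap_lrt",
    "classification_error",
    "outcome_r2",
    "selection_table",
]


@dataclass
class FitIndices:
    """One row of the class-enumeration table."""

    K: int
    Npar: int
    L2: float
    BIC_L2: float
    AIC_L2: float
    AIC3_L2: float
    CAIC_L2: float
    SABIC_L2: float
    df: int
    p_value: float | None
    CE: float
    R2: float
    log_likelihood: float = np.nan
    # conventional LL-scale criteria (−2LL + penalty·Npar)
    BIC: float = np.nan
    AIC: float = np.nan
    AIC3: float = np.nan
    CAIC: float = np.nan
    SABIC: float = np.nan


@dataclass
class BootLRTResult:
    """Parametric bootstrap likelihood-ratio test between nested K."""

    K_small: int
    K_big: int
    statistic: float  # observed −2LLDiff
    replicates: np.ndarray
    p_value: float
    B_requested: int
    B_used: int
    n_dropped: int
    seed: int | None
    unreliable: bool = False


def count_parameters(
    K: int,
    n_outcome_categories: int = 3,
    n_predictor_columns: int = 8,
    n_covariate_columns: int = 17,
) -> int:
    """Free parameters: K·(C−1)·(1+P) within-class + (K−1)·(1+Q) concomitant.

    For the study design (C=3, P=8, Q=17) this gives 18, 54, 90 for
    K = 1, 2, 3.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    C = n_outcome_categories
    return K * (C - 1) * (1 + n_predictor_columns) + (K - 1) * (1 + n_covariate_columns)


def degrees_of_freedom(N: int, Npar: int) -> int:
    """Residual degrees of freedom df = N − Npar."""
    return N - Npar


def information_criteria(L2: float, df: int, N: int) -> dict[str, float]:
    """The five L²-scale penalized indices (lower is better)."""
    if N <= 0:
        raise ValueError("N must be positive")
    if df < 0:
        warnings.warn("negative df: more parameters than cases", UserWarning, stacklevel=2)
    logN = np.log(N)
    return {
        "BIC_L2": L2 - logN * df,
        "AIC_L2": L2 - 2.0 * df,
        "AIC3_L2": L2 - 3.0 * df,
        "CAIC_L2": L2 - (logN + 1.0) * df,
        "SABIC_L2": L2 - np.log((N + 2) / 24.0) * df,
    }


def l2_statistic(fitted: FittedModel, design: EncodedDesign) -> tuple[float, float | None]:
    """L² against the perfect-prediction saturated reference, and its
    upper-tail chi-square probability at df = N − Npar (None when df <= 0)."""
    L2 = -2.0 * fitted.log_likelihood
    npar = count_parameters(
        fitted.n_classes,
        n_predictor_columns=design.predictor_matrix.shape[1],
        n_covariate_columns=design.covariate_matrix.shape[1],
    )
    df = degrees_of_freedom(design.n, npar)
    if df <= 0:
        return L2, None
    return L2, float(chi2.sf(L2, df))


def neg2_ll_diff(fit_small: FittedModel, fit_big: FittedModel) -> float:
    """−2LLDiff = 2·(LL_big − LL_small) = L²_small − L²_big."""
    return 2.0 * (fit_big.log_likelihood - fit_small.log_likelihood)


def _simulate_outcomes(
    design: EncodedDesign, fitted: FittedModel, rng: np.random.Generator
) -> np.ndarray:
    probs = mixture_outcome_probs(
        design.covariate_matrix, design.predictor_matrix, fitted.params
    )
    probs = np.atleast_2d(probs)
    u = rng.random(design.n)
    return (probs.cumsum(axis=1) < u[:, None]).sum(axis=1).astype(int)


def bootstrap_lrt(
    design: EncodedDesign,
    K_small: int,
    K_big: int,
    B: int = 500,
    config: FitConfig | None = None,
) -> BootLRTResult:
    """Parametric bootstrap −2LLDiff test of K_small vs K_big classes.

    Outcomes are regenerated from the fitted smaller model at the observed
    covariates/predictors; both models are refitted on every replicate.
    p = (1 + #{replicate >= observed}) / (B_used + 1).  Replicates where
    either refit fails to converge are dropped and counted; more than 20%
    dropped flags the result unreliable.
    """
    if K_big <= K_small:
        raise ValueError("K_big must exceed K_small")
    if B < 1:
        raise ValueError("B must be >= 1")
    config = config or FitConfig()
    rng = np.random.default_rng(config.seed)

    def conf(K: int, seed) -> FitConfig:
        return FitConfig(
            n_classes=K,
            n_restarts=config.n_restarts,
            max_iter=config.max_iter,
            tol=config.tol,
            ridge=config.ridge,
            seed=int(seed),
        )

    seed0, seed1 = rng.integers(0, 2**31 - 1, size=2)
    fit_s = fit_em(design, conf(K_small, seed0))
    fit_b = fit_em(design, conf(K_big, seed1))
    stat_obs = neg2_ll_diff(fit_s, fit_b)

    stats = []
    dropped = 0
    for _ in range(B):
        y_star = _simulate_outcomes(design, fit_s, rng)
        d_star = design.with_outcomes(y_star)
        s_seed, b_seed = rng.integers(0, 2**31 - 1, size=2)
        # replicates get the same start protocol as the observed fits —
        # asymmetric optimisation effort would bias the statistic's null
        # distribution
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rs = fit_em(d_star, conf(K_small, s_seed))
            rb = fit_em(d_star, conf(K_big, b_seed))
        if not (rs.converged and rb.converged):
            dropped += 1
            continue
        stats.append(neg2_ll_diff(rs, rb))
    stats = np.asarray(stats)
    B_used = len(stats)
    if B_used == 0:
        raise RuntimeError("all bootstrap replicates failed to converge")
    p = (1 + int(np.sum(stats >= stat_obs))) / (B_used + 1)
    return BootLRTResult(
        K_small=K_small,
        K_big=K_big,
        statistic=stat_obs,
        replicates=stats,
        p_value=p,
        B_requested=B,
        B_used=B_used,
        n_dropped=dropped,
        seed=config.seed,
        unreliable=dropped > 0.2 * B,
    )


def classification_error(posteriors: PosteriorMatrix) -> float:
    """CE: mean posterior probability mass off the modal class."""
    return float(np.mean(1.0 - posteriors.probs.max(axis=1)))


def outcome_r2(fitted: FittedModel, design: EncodedDesign) -> float:
    """Entropy-based pseudo-R² of outcome prediction.

    1 − (Σ_i −log f(y_i|z_i)) / (Σ_i −log p̂(y_i)) with the outcome-marginal
    model as the null; 0 when the model matches the null, 1 for perfect
    prediction.
    """
    y = design.outcomes_or_raise()
    model_entropy = -fitted.log_likelihood
    counts = np.bincount(y, minlength=3).astype(float)
    marg = counts / counts.sum()
    with np.errstate(divide="ignore"):
        null_entropy = -float(np.sum(counts * np.where(counts > 0, np.log(marg), 0.0)))
    if null_entropy <= 0:
        return 1.0 if model_entropy <= 0 else 0.0
    return 1.0 - model_entropy / null_entropy


def _indices_for(fitted: FittedModel, design: EncodedDesign) -> FitIndices:
    K = fitted.n_classes
    npar = count_parameters(
        K,
        n_predictor_columns=design.predictor_matrix.shape[1],
        n_covariate_columns=design.covariate_matrix.shape[1],
    )
    df = degrees_of_freedom(design.n, npar)
    L2, p = l2_statistic(fitted, design)
    ics = information_criteria(L2, df, design.n)
    ll = fitted.log_likelihood
    logN = np.log(design.n)
    return FitIndices(
        K=K,
        Npar=npar,
        L2=L2,
        df=df,
        p_value=p,
        CE=classification_error(fitted.posteriors),
        R2=outcome_r2(fitted, design),
        log_likelihood=ll,
        BIC=-2 * ll + logN * npar,
        AIC=-2 * ll + 2 * npar,
        AIC3=-2 * ll + 3 * npar,
        CAIC=-2 * ll + (logN + 1) * npar,
        SABIC=-2 * ll + np.log((design.n + 2) / 24.0) * npar,
        **ics,
    )


def selection_table(
    design: EncodedDesign,
    K_max: int,
    config: FitConfig | None = None,
) -> pd.DataFrame:
    """Class-enumeration table for K = 1..K_max with −2LLDiff between
    consecutive solutions.

    Columns mirror the published layout (Npar, L², the five L²-scale
    indices, df, p, CE, R²) plus the LL-scale criteria and a flag when the
    two scales disagree on the best K.
    """
    if K_max < 1:
        raise ValueError("K_max must be >= 1")
    config = config or FitConfig()
    rng = np.random.default_rng(config.seed)
    fits: list[FittedModel] = []
    rows: list[FitIndices] = []
    for K in range(1, K_max + 1):
        cfg = FitConfig(
            n_classes=K,
            n_restarts=config.n_restarts,
            max_iter=config.max_iter,
            tol=config.tol,
            ridge=config.ridge,
            z_threshold=config.z_threshold,
            alpha=config.alpha,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        fitted = fit_em(design, cfg)
        fits.append(fitted)
        rows.append(_indices_for(fitted, design))
    df = pd.DataFrame([vars(r) for r in rows])
    diffs = [np.nan] + [neg2_ll_diff(fits[i - 1], fits[i]) for i in range(1, len(fits))]
    df["neg2_ll_diff"] = diffs
    # scale-disagreement flag: do L2-scale and LL-scale indices pick the same K?
    for name in ("BIC", "AIC", "AIC3", "CAIC", "SABIC"):
        l2_best = int(df[f"{name}_L2"].idxmin())
        ll_best = int(df[name].idxmin())
        df[f"{name}_scale_disagrees"] = l2_best != ll_best
    return df
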