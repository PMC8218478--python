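"""The latent class regression model.

The density of the 3-category reoffending outcome given covariates z^c and
predictors z^p is a concomitant-covariate mixture

    f(y | z^c, z^p) = sum_x  pi(x | z^c) * f(y | x, z^p)

where ``pi(x | z^c)`` is a multinomial logit of latent class membership on
the psychosocial covariates (class K is the reference), and
``f(y | x, z^p)`` is a class-specific multinomial logit of the outcome on
the neurobiological predictors (outcome "no reoffending" is the reference).

Parameters:

* ``gamma`` — (K-1) x (1+Q) concomitant coefficients, column 0 the
  intercept, Q covariate columns (17 in the study design);
* ``beta`` — K x (C-1) x (1+P) within-class outcome coefficients, C=3
  outcome categories, P predictor columns (8 in the study design; 0 in the
  reduced psychosocial-only model).

All softmax computations are log-sum-exp stabilised and stay finite for
coefficient magnitudes up to at least +-50.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.special import logsumexp

from .codebook import EncodedDesign, OUTCOME_LEVELS

__all__ = [
    "LCRAParameters",
    "PosteriorMatrix",
    "class_membership_probs",
    "outcome_probs_given_class",
    "mixture_outcome_probs",
    "log_likelihood",
    "posterior_class_probs",
    "class_sizes",
    "class_outcome_profile",
]


@dataclass
class LCRAParameters:
    """Concomitant (gamma) and within-class outcome (beta) coefficients."""

    gamma: np.ndarray  # (K-1, 1+Q); empty (0, 1+Q) when K == 1
    beta: np.ndarray   # (K, C-1, 1+P)
    class_labels: list[str] = field(default_factory=list)
    outcome_labels: list[str] = field(default_factory=lambda: list(OUTCOME_LEVELS))
    covariate_names: list[str] = field(default_factory=list)
    predictor_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.gamma = np.atleast_2d(np.asarray(self.gamma, dtype=float))
        self.beta = np.asarray(self.beta, dtype=float)
        if self.beta.ndim != 3:
            raise ValueError("beta must have shape (K, C-1, 1+P)")
        K = self.beta.shape[0]
        if K < 1:
            raise ValueError("K must be >= 1")
        if K == 1:
            self.gamma = self.gamma.reshape(0, self.gamma.shape[-1] if self.gamma.size else 1)
        elif self.gamma.shape[0] != K - 1:
            raise ValueError(
                f"gamma has {self.gamma.shape[0]} rows, expected K-1 = {K - 1}"
            )
        if not (np.all(np.isfinite(self.gamma)) and np.all(np.isfinite(self.beta))):
            raise ValueError("parameters must be finite")
        if not self.class_labels:
            self.class_labels = [f"class {k + 1}" for k in range(K)]

    @property
    def n_classes(self) -> int:
        return self.beta.shape[0]

    @property
    def n_outcomes(self) -> int:
        return self.beta.shape[1] + 1

    @property
    def n_covariates(self) -> int:
        return max(self.gamma.shape[1] - 1, 0)

    @property
    def n_predictors(self) -> int:
        return self.beta.shape[2] - 1

    # -- serialization -------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "n_classes": self.n_classes,
            "gamma": self.gamma.tolist(),
            "beta": self.beta.tolist(),
            "class_labels": self.class_labels,
            "outcome_labels": self.outcome_labels,
            "covariate_names": self.covariate_names,
            "predictor_names": self.predictor_names,
            "reference_class": "last",
            "reference_outcome": self.outcome_labels[0],
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def from_dict(cls, doc: dict) -> "LCRAParameters":
        K = int(doc["n_classes"])
        gamma = np.asarray(doc["gamma"], dtype=float)
        beta = np.asarray(doc["beta"], dtype=float)
        if K == 1:
            gamma = gamma.reshape(0, 18 if gamma.size == 0 else gamma.shape[-1])
        return cls(
            gamma=gamma,
            beta=beta,
            class_labels=list(doc.get("class_labels", [])),
            outcome_labels=list(doc.get("outcome_labels", OUTCOME_LEVELS)),
            covariate_names=list(doc.get("covariate_names", [])),
            predictor_names=list(doc.get("predictor_names", [])),
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "LCRAParameters":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass
class PosteriorMatrix:
    """N x K posterior class-membership probabilities (modal assignment)."""

    probs: np.ndarray
    assignment_rule: str = "modal"
    used_outcome: bool = True

    def __post_init__(self) -> None:
        self.probs = np.atleast_2d(np.asarray(self.probs, dtype=float))
        rs = self.probs.sum(axis=1)
        if self.probs.size and not np.allclose(rs, 1.0, atol=1e-10):
            raise ValueError("posterior rows must sum to 1")

    @property
    def n_classes(self) -> int:
        return self.probs.shape[1]

    def modal(self) -> np.ndarray:
        return np.argmax(self.probs, axis=1)


def _with_intercept(M: np.ndarray) -> np.ndarray:
    M = np.atleast_2d(np.asarray(M, dtype=float))
    return np.hstack([np.ones((M.shape[0], 1)), M])


def membership_log_probs(Zc: np.ndarray, params: LCRAParameters) -> np.ndarray:
    """log pi(x | z^c) for every row; shape (N, K)."""
    Zc = np.atleast_2d(np.asarray(Zc, dtype=float))
    K = params.n_classes
    if K == 1:
        return np.zeros((Zc.shape[0], 1))
    if Zc.shape[1] != params.gamma.shape[1] - 1:
        raise ValueError(
            f"covariate row has {Zc.shape[1]} columns, gamma expects {params.gamma.shape[1] - 1}"
        )
    logits = np.zeros((Zc.shape[0], K))
    logits[:, : K - 1] = _with_intercept(Zc) @ params.gamma.T
    return logits - logsumexp(logits, axis=1, keepdims=True)


def outcome_log_probs(Zp: np.ndarray, params: LCRAParameters) -> np.ndarray:
    """log f(y | x, z^p) for every row and class; shape (N, K, C)."""
    Zp = np.atleast_2d(np.asarray(Zp, dtype=float))
    if Zp.shape[1] != params.n_predictors:
        raise ValueError(
            f"predictor row has {Zp.shape[1]} columns, beta expects {params.n_predictors}"
        )
    X = _with_intercept(Zp)  # (N, 1+P)
    K, Cm1, _ = params.beta.shape
    logits = np.zeros((Zp.shape[0], K, Cm1 + 1))
    # category 0 ("no") is the reference with logit 0
    logits[:, :, 1:] = np.einsum("np,kcp->nkc", X, params.beta)
    return logits - logsumexp(logits, axis=2, keepdims=True)


def class_membership_probs(covariate_row: np.ndarray, params: LCRAParameters) -> np.ndarray:
    """pi(x | z^c): the K-simplex of class-membership probabilities."""
    row = np.asarray(covariate_row, dtype=float)
    single = row.ndim == 1
    out = np.exp(membership_log_probs(row, params))
    return out[0] if single else out


def outcome_probs_given_class(
    predictor_row: np.ndarray, k: int, params: LCRAParameters
) -> np.ndarray:
    """f(y | x=k, z^p): the C-simplex of outcome probabilities in class k."""
    if not 0 <= k < params.n_classes:
        raise ValueError(f"class index {k} out of range for K={params.n_classes}")
    row = np.asarray(predictor_row, dtype=float)
    single = row.ndim == 1
    out = np.exp(outcome_log_probs(row, params)[:, k, :])
    return out[0] if single else out


def mixture_outcome_probs(
    covariate_row: np.ndarray, predictor_row: np.ndarray, params: LCRAParameters
) -> np.ndarray:
    """f(y | z^c, z^p) = sum_x pi(x|z^c) f(y|x,z^p)."""
    cov = np.asarray(covariate_row, dtype=float)
    single = cov.ndim == 1
    logpi = membership_log_probs(cov, params)  # (N, K)
    logf = outcome_log_probs(predictor_row, params)  # (N, K, C)
    logmix = logsumexp(logpi[:, :, None] + logf, axis=1)
    out = np.exp(logmix)
    return out[0] if single else out


def log_likelihood(design: EncodedDesign, params: LCRAParameters) -> float:
    """Observed-data log-likelihood sum_i log f(y_i | z^c_i, z^p_i)."""
    y = design.outcomes_or_raise()
    probs = mixture_outcome_probs(design.covariate_matrix, design.predictor_matrix, params)
    probs = np.atleast_2d(probs)
    return float(np.sum(np.log(probs[np.arange(design.n), y])))


def posterior_class_probs(
    design: EncodedDesign, params: LCRAParameters
) -> PosteriorMatrix:
    """Posterior class membership by Bayes' rule on the mixture factors.

    For cases with an observed outcome the posterior is proportional to
    pi(k|z^c) * f(y|k, z^p); without an outcome it reduces to the
    concomitant prior pi(k|z^c) — the mode used by the new-case tool.
    """
    logpi = membership_log_probs(design.covariate_matrix, params)  # (N, K)
    y = design.outcome_vector
    observed = y >= 0
    logpost = logpi.copy()
    if observed.any():
        logf = outcome_log_probs(design.predictor_matrix[observed], params)
        logpost[observed] += logf[np.arange(int(observed.sum())), :, y[observed]]
    logpost -= logsumexp(logpost, axis=1, keepdims=True)
    return PosteriorMatrix(np.exp(logpost), used_outcome=bool(observed.all()))


def class_sizes(posteriors: PosteriorMatrix) -> np.ndarray:
    """Marginal class-size proportions: the mean of the posterior columns."""
    return posteriors.probs.mean(axis=0)


def class_outcome_profile(
    design: EncodedDesign, params: LCRAParameters, posteriors: PosteriorMatrix
) -> np.ndarray:
    """K x C class-conditional outcome probabilities.

    Row k is the posterior-weighted average over cases of f(y | k, z^p_i),
    i.e. the within-class outcome profile reported when describing classes
    as low/medium/high risk.
    """
    f = np.exp(outcome_log_probs(design.predictor_matrix, params))  # (N, K, C)
    tau = posteriors.probs  # (N, K)
    w = tau.sum(axis=0)  # (K,)
    prof = np.einsum("nk,nkc->kc", tau, f) / np.maximum(w, 1e-300)[:, None]
    empty = w <= 1e-300
    if empty.any():  # degenerate class: fall back to unweighted average
        prof[empty] = f.mean(axis=0)[empty]
    return prof
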