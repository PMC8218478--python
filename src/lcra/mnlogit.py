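"""Weighted multinomial logit with soft targets — the EM M-step solver.

Minimises

    -sum_i sum_c W[i, c] * log p_c(x_i)  +  (ridge / 2) * ||B||^2

over the free coefficient block B ((C-1) x p; the reference category's
coefficients are pinned at zero), where p(x) = softmax(x B_full^T).  The
target weights W may be fractional (posterior responsibilities) and rows
need not sum to one.  This is exactly the concomitant (gamma) update — soft
class targets — and, with one-hot outcome targets scaled by a class's
responsibilities, the within-class outcome (beta) update.

Newton iterations with analytic gradient/Hessian and step halving; the
ridge term keeps the Hessian invertible under quasi-separation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
__all__ = ["MNLogitResult", "fit_weighted_mnlogit"]


@dataclass
class MNLogitResult:
    coef: np.ndarray          # (C-1, p), non-reference categories in order
    objective: float          # penalized negative log-likelihood
    log_likelihood: float     # unpenalized weighted log-likelihood
    n_iter: int
    converged: bool


def _objective(X: np.ndarray, W: np.ndarray, w_row: np.ndarray, B: np.ndarray, ridge: float):
    """Penalized NLL, its log-likelihood part, and free-category softmax
    probabilities.

    The reference category's logit is the implicit zero column; softmax is
    computed with a manual max shift (cheaper than scipy's logsumexp on the
    small matrices the EM loop hits thousands of times).
    """
    L = X @ B.T  # (N, C-1) free-category logits
    m = np.maximum(L.max(axis=1), 0.0)
    E = np.exp(L - m[:, None])
    denom = np.exp(-m) + E.sum(axis=1)
    lognorm = m + np.log(denom)
    ll = float(np.sum(W[:, 1:] * L) - np.dot(w_row, lognorm))
    Pf = E / denom[:, None]  # probabilities of the free categories
    return -ll + 0.5 * ridge * float(np.sum(B * B)), ll, Pf


def fit_weighted_mnlogit(
    X: np.ndarray,
    W: np.ndarray,
    ridge: float = 1e-6,
    ref: int = 0,
    coef0: np.ndarray | None = None,
    tol: float = 1e-10,
    max_iter: int = 100,
) -> MNLogitResult:
    """Fit the weighted soft-target multinomial logit.

    Parameters
    ----------
    X : (N, p) design including any intercept column.
    W : (N, C) non-negative target weights.
    ridge : L2 penalty on the free coefficients.
    ref : reference category index (coefficients pinned to zero).
    coef0 : optional (C-1, p) warm start for the non-reference categories
        (in their original order with ``ref`` removed).
    tol : convergence threshold on the Newton decrement / objective change.
    """
    X = np.asarray(X, dtype=float)
    W = np.asarray(W, dtype=float)
    N, p = X.shape
    C = W.shape[1]
    if C < 2:
        raise ValueError("need at least 2 categories")
    order = [ref] + [c for c in range(C) if c != ref]
    Wp = W[:, order]  # reference first

    B = np.zeros((C - 1, p)) if coef0 is None else np.array(coef0, dtype=float)
    w_row = Wp.sum(axis=1)
    nfree = (C - 1) * p

    obj, ll, Pf = _objective(X, Wp, w_row, B, ridge)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # gradient of penalized NLL wrt free block
        R = w_row[:, None] * Pf - Wp[:, 1:]  # (N, C-1)
        grad = R.T @ X + ridge * B  # (C-1, p)
        gnorm = float(np.max(np.abs(grad)))
        if gnorm < tol * max(1.0, abs(obj)):
            converged = True
            break
        # Hessian: blocks H[cd] = X^T diag(w * (P_c (delta_cd - P_d))) X
        if C == 2:
            s = w_row * Pf[:, 0] * (1.0 - Pf[:, 0])
            Hm = X.T @ (s[:, None] * X)
        else:
            H = np.empty((C - 1, p, C - 1, p))
            for c in range(C - 1):
                for d in range(c, C - 1):
                    s = w_row * Pf[:, c] * ((1.0 if c == d else 0.0) - Pf[:, d])
                    block = X.T @ (s[:, None] * X)
                    H[c, :, d, :] = block
                    if d != c:
                        H[d, :, c, :] = block
            Hm = H.reshape(nfree, nfree)
        Hm.flat[:: nfree + 1] += ridge
        try:
            step = np.linalg.solve(Hm, grad.ravel()).reshape(C - 1, p)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(Hm, grad.ravel(), rcond=None)[0].reshape(C - 1, p)
        # step halving on the penalized objective
        t = 1.0
        for _ in range(30):
            Bn = B - t * step
            obj_n, ll_n, Pf_n = _objective(X, Wp, w_row, Bn, ridge)
            if obj_n <= obj + 1e-12 * max(1.0, abs(obj)):
                break
            t *= 0.5
        else:
            converged = True  # no descent direction left: at numerical optimum
            break
        if abs(obj - obj_n) < tol * max(1.0, abs(obj)):
            B, obj, ll, Pf = Bn, obj_n, ll_n, Pf_n
            converged = True
            break
        B, obj, ll, Pf = Bn, obj_n, ll_n, Pf_n

    # restore original category order: rows of B correspond to order[1:]
    coef = np.empty((C - 1, p))
    pos = 0
    for c in range(C):
        if c == ref:
            continue
        coef[pos] = B[order.index(c) - 1]
        pos += 1
    return MNLogitResult(coef=coef, objective=obj, log_likelihood=ll, n_iter=it, converged=converged)
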