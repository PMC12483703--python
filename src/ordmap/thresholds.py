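"""Per-response maximum-likelihood threshold estimation.

The structural values enter as a fixed offset (a predictor with coefficient
one and no further covariates), so for each response only the ``C_r - 1``
cut-points are free.  A damped Newton iteration with the exact tridiagonal
Hessian is used; steps are halved until the negative log-likelihood does not
increase and the strict threshold order is preserved, which keeps the outer
EMM deviance monotone when warm-starting from the current thresholds.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.special import expit

#: |tau| cap on the latent scale for empty / near-empty categories
TAU_CAP = 30.0


class ThresholdConvergenceError(RuntimeError):
    """Raised when Newton fails to reach the gradient tolerance."""

    def __init__(self, message, last_iterate):
        super().__init__(message)
        self.last_iterate = last_iterate


def _logistic_pdf(x):
    p = expit(x)
    return p * (1.0 - p)


def nll_and_grad(tau: np.ndarray, y: np.ndarray, offset: np.ndarray):
    """Negative log-likelihood and gradient in the cut-points.

    ``y`` holds categories 1..C, ``offset`` the structural column; cells use
    bounds ``(a, b) = (tau_{c-1}, tau_c) - offset`` with infinite sentinels.
    """
    k = tau.size
    full = np.concatenate(([-np.inf], tau, [np.inf]))
    b = full[y] - offset
    a = full[y - 1] - offset
    p = np.maximum(expit(b) - expit(a), 1e-300)
    nll = -np.log(p).sum()
    fb = _logistic_pdf(b) / p
    fa = _logistic_pdf(a) / p
    # d nll / d tau_c = -sum_{y=c} f(b)/p + sum_{y=c+1} f(a)/p
    # contributions at b = +inf (y = k+1) / a = -inf (y = 1) are zero, so
    # bincount over shifted categories picks them up harmlessly
    grad = (
        np.bincount(y - 1, weights=fa, minlength=k + 1)[1 : k + 1]
        - np.bincount(y - 1, weights=fb, minlength=k + 1)[:k]
    )
    return nll, grad


def _hessian(tau: np.ndarray, y: np.ndarray, offset: np.ndarray) -> np.ndarray:
    """Exact (tridiagonal) Hessian of the negative log-likelihood."""
    k = tau.size
    full = np.concatenate(([-np.inf], tau, [np.inf]))
    b = full[y] - offset
    a = full[y - 1] - offset
    p = np.maximum(expit(b) - expit(a), 1e-300)
    fb, fa = _logistic_pdf(b), _logistic_pdf(a)
    # f'(x) = f(x) (1 - 2 expit(x))
    dfb = fb * (1.0 - 2.0 * expit(b))
    dfa = fa * (1.0 - 2.0 * expit(a))
    h = np.zeros((k, k))
    # upper-bound role (y = c <= k): -f'(b)/p + (f(b)/p)^2 on the diagonal;
    # lower-bound role (y = c + 1): f'(a)/p + (f(a)/p)^2.  Infinite bounds
    # contribute exactly zero, so bincount over all cells is safe.
    diag_up = np.bincount(y - 1, weights=-dfb / p + (fb / p) ** 2, minlength=k + 1)[:k]
    diag_lo = np.bincount(y - 1, weights=dfa / p + (fa / p) ** 2, minlength=k + 1)[
        1 : k + 1
    ]
    np.fill_diagonal(h, diag_up + diag_lo)
    # cross terms between tau_{c-1} (lower) and tau_c (upper), cells 2<=y<=k
    cross = np.bincount(y - 1, weights=-fa * fb / p**2, minlength=k + 1)[1:k]
    idx = np.arange(k - 1)
    h[idx + 1, idx] += cross
    h[idx, idx + 1] += cross
    return h


def start_values(y: np.ndarray, n_cats: int, offset: np.ndarray) -> np.ndarray:
    """Cumulative-proportion start: logit of capped cumulative frequencies,
    shifted by the mean offset."""
    n = y.size
    counts = np.bincount(y, minlength=n_cats + 1)[1:]
    cum = np.cumsum(counts)[:-1] / n
    cum = np.clip(cum, 1.0 / (2 * n), 1.0 - 1.0 / (2 * n))
    tau = np.log(cum / (1.0 - cum)) + offset.mean()
    # enforce strict order under heavy ties
    for c in range(1, tau.size):
        tau[c] = max(tau[c], tau[c - 1] + 1e-8)
    return tau


def fit_thresholds(
    y_r,
    theta_r,
    tau0=None,
    n_cats: int | None = None,
    tol: float = 1e-8,
    max_iter: int = 50,
    strict: bool = False,
) -> np.ndarray:
    """ML cut-points for one response with ``theta_r`` as fixed offset.

    Damped Newton; every accepted step weakly decreases the negative
    log-likelihood, so warm-started calls never decrease the likelihood.
    Thresholds drifting beyond ``TAU_CAP`` (empty categories) are capped with
    a warning.  With ``strict=True`` non-convergence raises
    :class:`ThresholdConvergenceError` carrying the last iterate.
    """
    y = np.asarray(y_r, dtype=np.int64)
    offset = np.asarray(theta_r, dtype=float)
    if n_cats is None:
        n_cats = int(y.max())
    counts = np.bincount(y, minlength=n_cats + 1)[1:]
    if (counts == 0).any():
        warnings.warn(
            "empty response category; thresholds capped at +-30",
            RuntimeWarning,
        )
    if tau0 is None:
        tau = start_values(y, n_cats, offset)
    else:
        tau = np.array(tau0, dtype=float)
    nll, grad = nll_and_grad(tau, y, offset)
    for _ in range(max_iter):
        if np.abs(grad).max() < tol:
            break
        h = _hessian(tau, y, offset)
        try:
            step = np.linalg.solve(h, -grad)
        except np.linalg.LinAlgError:
            step = -grad
        if grad @ step >= 0:  # not a descent direction, fall back
            step = -grad
        t = 1.0
        accepted = False
        for _ in range(40):
            cand = tau + t * step
            if np.all(np.diff(cand) > 0) or cand.size == 1:
                cand_nll, cand_grad = nll_and_grad(cand, y, offset)
                if cand_nll <= nll:
                    tau, nll, grad = cand, cand_nll, cand_grad
                    accepted = True
                    break
            t *= 0.5
        if not accepted:
            break
    else:
        if strict and np.abs(grad).max() >= tol and not (counts == 0).any():
            raise ThresholdConvergenceError(
                "threshold Newton did not converge", tau
            )
    if np.abs(tau).max() > TAU_CAP:
        tau = np.clip(tau, -TAU_CAP, TAU_CAP)
        for c in range(1, tau.size):
            tau[c] = max(tau[c], tau[c - 1] + 1e-8)
    return tau


def fit_all_thresholds(y_matrix, n_categories, theta, tau0=None, **kwargs):
    """Re-estimate thresholds for every response column."""
    out = []
    for r in range(y_matrix.shape[1]):
        t0 = None if tau0 is None else tau0[r]
        out.append(
            fit_thresholds(
                y_matrix[:, r],
                theta[:, r],
                tau0=t0,
                n_cats=int(n_categories[r]),
                **kwargs,
            )
        )
    return out
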