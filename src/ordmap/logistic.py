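"""Cumulative-logistic probability machinery and the E-step closed forms.

The model for observation ``i`` and ordinal response ``r`` with ``C_r``
categories assumes a latent variable ``z_ir = theta_ir + e_ir`` with ``e_ir``
standard logistic, and ``y_ir = c`` iff ``tau_{r,c-1} < z_ir <= tau_{r,c}``
(``tau_{r,0} = -inf``, ``tau_{r,C_r} = +inf``).  Hence

    P(y_ir <= c) = Lambda(tau_rc - theta_ir),

with ``Lambda`` the logistic CDF, so the category probabilities are
differences of adjacent cumulative probabilities.

E-step closed forms
-------------------
The complete-data negative log-likelihood term is ``-log f(z - theta)`` with
``f`` the logistic density.  Its gradient in ``theta`` is
``1 - 2 Lambda(z - theta)`` and its curvature ``2 f(z - theta) <= 1/2``.
Conditioning on the observed category truncates ``x = z - theta`` to the
interval ``(a, b) = (tau_{c-1} - theta, tau_c - theta)``; because
``int Lambda * lambda = Lambda^2 / 2`` the truncated mean of ``Lambda(x)`` is
``(Lambda(a) + Lambda(b)) / 2``, giving the closed-form expected gradient

    g_ir = 1 - Lambda(a) - Lambda(b).

The quadratic majorizer with curvature bound 1/2 then yields the working
responses ``ztilde = theta - 2 g`` (minimising the majorizer in ``theta`` is
a least-squares problem with these targets).
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit

from .data import OrdinalDataset

#: probabilities are floored at this value inside logarithms
PROB_FLOOR = 1e-12

#: supremum of the curvature of -log f(z - theta) in theta (2 * max pdf)
CURVATURE_BOUND = 0.5


class ThresholdError(ValueError):
    """Raised for thresholds violating the strict-order invariant."""


def validate_thresholds(tau) -> list[np.ndarray]:
    """Validate a ragged threshold set and return it as a list of arrays.

    Each element must be a strictly increasing 1-d array (length ``C_r - 1``
    for response ``r``).
    """
    out = []
    for r, t in enumerate(tau):
        t = np.atleast_1d(np.asarray(t, dtype=float))
        if t.ndim != 1 or t.size < 1:
            raise ThresholdError(f"thresholds for response {r} must be 1-d")
        if not np.all(np.isfinite(t)):
            raise ThresholdError(f"non-finite threshold in response {r}")
        if t.size > 1 and not np.all(np.diff(t) > 0):
            raise ThresholdError(
                f"thresholds for response {r} are not strictly increasing"
            )
        out.append(t)
    return out


def _tau_full(tau: list[np.ndarray]) -> np.ndarray:
    """Pad thresholds into an (R, Cmax+1) array with -inf / +inf sentinels.

    Column ``c`` holds ``tau_{r,c}`` for ``c = 0..Cmax`` with
    ``tau_{r,0} = -inf`` and ``tau_{r,c} = +inf`` for ``c >= C_r``.
    """
    r_tot = len(tau)
    cmax = max(t.size + 1 for t in tau)
    full = np.full((r_tot, cmax + 1), np.inf)
    full[:, 0] = -np.inf
    for r, t in enumerate(tau):
        full[r, 1 : t.size + 1] = t
    return full


def _interval_bounds(y: np.ndarray, theta: np.ndarray, tau: list[np.ndarray]):
    """Per-cell truncation bounds (a, b) = (tau_{c-1}, tau_c) minus theta."""
    full = _tau_full(tau)
    cols = np.arange(theta.shape[1])
    upper = full[cols, y]  # tau_{r, y_ir}
    lower = full[cols, y - 1]  # tau_{r, y_ir - 1}
    return lower - theta, upper - theta


def cumulative_probabilities(theta, tau) -> np.ndarray:
    """Cumulative probabilities P(y_ir <= c), padded to (N, R, Cmax).

    Entries for ``c > C_r`` are 1 by the sentinel convention.  The last slice
    (``c = Cmax``) is identically 1.
    """
    tau = validate_thresholds(tau)
    theta = np.asarray(theta, dtype=float)
    full = _tau_full(tau)  # (R, Cmax+1)
    lam = expit(full[None, :, 1:] - theta[:, :, None])
    return lam


def category_probabilities(theta, tau) -> np.ndarray:
    """Category probabilities p_irc, padded to (N, R, Cmax) with zeros.

    ``p[i, r, c-1] = P(y_ir = c)``; slices beyond ``C_r`` are zero and each
    cell sums to one.
    """
    lam = cumulative_probabilities(theta, tau)
    p = np.diff(lam, axis=2, prepend=0.0)
    return p


def cell_probabilities(y: OrdinalDataset, theta, tau) -> np.ndarray:
    """P(y_ir = observed category) as an (N, R) array."""
    tau = validate_thresholds(tau)
    theta = np.asarray(theta, dtype=float)
    _check_categories(y, tau)
    a, b = _interval_bounds(y.y, theta, tau)
    return expit(b) - expit(a)


def _check_categories(y: OrdinalDataset, tau: list[np.ndarray]):
    if y.n_responses != len(tau):
        raise ValueError("threshold set does not match number of responses")
    for r, t in enumerate(tau):
        if y.n_categories[r] != t.size + 1:
            raise ValueError(
                f"response {r} has {y.n_categories[r]} categories but "
                f"{t.size} thresholds"
            )


def deviance(y: OrdinalDataset, theta, tau) -> float:
    """Observed-data deviance, -2 sum log P(y_ir = observed).

    Probabilities are floored at ``PROB_FLOOR`` so the result is finite even
    for degenerate cells.
    """
    p = cell_probabilities(y, theta, tau)
    return float(-2.0 * np.log(np.maximum(p, PROB_FLOOR)).sum())


def expected_gradient(y: OrdinalDataset, theta, tau) -> np.ndarray:
    """E-step: conditional expectation of the complete-data score in theta.

    Closed form ``g_ir = 1 - Lambda(a_ir) - Lambda(b_ir)`` with ``(a, b)``
    the truncation interval of the observed category (see module docstring).
    Always lies in (-1, 1).
    """
    tau = validate_thresholds(tau)
    theta = np.asarray(theta, dtype=float)
    _check_categories(y, tau)
    a, b = _interval_bounds(y.y, theta, tau)
    return 1.0 - expit(a) - expit(b)


def working_responses(theta, g) -> np.ndarray:
    """Majorization targets ``ztilde = theta - g / CURVATURE_BOUND``.

    Equal to ``theta`` exactly where the expected gradient vanishes; the
    M-step least-squares problem fits the structural part to these targets.
    """
    theta = np.asarray(theta, dtype=float)
    g = np.asarray(g, dtype=float)
    return theta - g / CURVATURE_BOUND
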