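"""Inner-loop least-squares updates of the structural part.

Four parameterisations of ``Theta``:

* dominance, unrestricted (PCA): ``Theta = U V'`` — truncated SVD;
* dominance, restricted (RRR): ``Theta = X B V'`` — generalized SVD in the
  ``X'X`` metric;
* proximity, unrestricted (MDU): ``Theta = -D(U, V)`` — one SMACOF
  (Guttman-type) sweep on negative dissimilarities;
* proximity, restricted (RMDU): ``U = X B`` — the SMACOF row update replaced
  by a weighted regression onto the predictors.

The SMACOF variant handles negative working dissimilarities with Heiser's
device: a cell with ``delta < 0`` gets adjusted dissimilarity 0 and inflated
weight ``1 + |delta| / max(d, eps)``, which majorizes the offending
``-2 delta d`` term (``2|delta| d <= |delta| (d^2 + d0^2) / d0``).  Both the
adjusted dissimilarities and the weights depend on the current configuration
and are rebuilt every iteration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

#: default small constant in the negative-dissimilarity weight redefinition
SMACOF_EPS = 1e-8

_TINY = 1e-300


@dataclass
class Configuration:
    """Row scores / ideal points ``U``, item structure ``V``, optional ``B``.

    For restricted models ``U = X B`` holds exactly after every update.
    """

    U: np.ndarray
    V: np.ndarray
    B: np.ndarray | None = None

    @property
    def n_dims(self) -> int:
        return self.U.shape[1]


def _sign_fix(P: np.ndarray, Q: np.ndarray):
    """Deterministic sign convention: largest-|.| element of each right
    singular vector is positive."""
    for s in range(Q.shape[1]):
        j = np.argmax(np.abs(Q[:, s]))
        if Q[j, s] < 0:
            Q[:, s] = -Q[:, s]
            P[:, s] = -P[:, s]
    return P, Q


def pca_update(ztilde: np.ndarray, n_dims: int) -> Configuration:
    """Best rank-S approximation of the working responses (Eckart-Young).

    Returns ``U = P_S Phi_S^{1/2}`` and ``V = Q_S Phi_S^{1/2}`` from the
    truncated SVD ``ztilde ~ P Phi Q'`` (symmetric singular-value split, so
    ``V'V`` is diagonal).
    """
    ztilde = np.asarray(ztilde, dtype=float)
    n, r = ztilde.shape
    if n_dims > min(n, r):
        raise ValueError("n_dims exceeds min(N, R)")
    P, phi, Qt = np.linalg.svd(ztilde, full_matrices=False)
    rank = int(np.sum(phi > phi[0] * max(n, r) * np.finfo(float).eps))
    if n_dims > rank:
        warnings.warn(
            f"requested {n_dims} dimensions but working-response matrix has "
            f"rank {rank}; trailing dimensions are numerically null",
            RuntimeWarning,
        )
    P, Q = _sign_fix(P[:, :n_dims].copy(), Qt[:n_dims].T.copy())
    root = np.sqrt(phi[:n_dims])
    return Configuration(U=P * root, V=Q * root)


def rrr_update(
    ztilde: np.ndarray, x: np.ndarray, n_dims: int, xqr=None
) -> Configuration:
    """Minimise ``||ztilde - X B V'||_F^2`` at rank S.

    Generalized SVD in the ``X'X`` metric via the thin QR of ``X``: with
    ``X = Q R``, the rank-S SVD of ``Q' ztilde = P Phi T'`` gives
    ``B = R^{-1} P_S Phi_S^{1/2}`` and ``V = T_S Phi_S^{1/2}``.
    """
    ztilde = np.asarray(ztilde, dtype=float)
    x = np.asarray(x, dtype=float)
    if xqr is None:
        xqr = qr_factor(x)
    q, rmat = xqr
    if n_dims > min(x.shape[1], ztilde.shape[1]):
        raise ValueError("n_dims exceeds min(P, R)")
    m = q.T @ ztilde  # P x R
    P, phi, Tt = np.linalg.svd(m, full_matrices=False)
    P, T = _sign_fix(P[:, :n_dims].copy(), Tt[:n_dims].T.copy())
    root = np.sqrt(phi[:n_dims])
    b = np.linalg.solve(rmat, P * root)
    v = T * root
    return Configuration(U=x @ b, V=v, B=b)


def qr_factor(x: np.ndarray):
    """Thin QR of the predictor matrix; errors on rank deficiency."""
    x = np.asarray(x, dtype=float)
    q, rmat = np.linalg.qr(x)
    diag = np.abs(np.diag(rmat))
    if diag.min() < 1e-10 * max(diag.max(), 1.0):
        raise ValueError(
            "predictor matrix is rank deficient; drop collinear predictors"
        )
    return q, rmat


def distances(U: np.ndarray, V: np.ndarray) -> np.ndarray:
    """Euclidean distances d(u_i, v_r) as an (N, R) matrix."""
    return cdist(U, V)


@dataclass
class SmacofSystem:
    """Adjusted dissimilarities ``A``, weights ``W`` and current distances.

    Built from working dissimilarities ``delta = -ztilde`` (the proximity
    structural part is ``theta = -d``).  Entries follow the sign rule in the
    module docstring; all weights are >= 1 and finite.
    """

    A: np.ndarray
    W: np.ndarray
    D: np.ndarray


def build_smacof_system(
    ztilde: np.ndarray, current: Configuration, eps: float = SMACOF_EPS
) -> SmacofSystem:
    """Assemble the (iteration-dependent) SMACOF system for the M-step."""
    delta = -np.asarray(ztilde, dtype=float)
    d = distances(current.U, current.V)
    neg = delta < 0
    a = np.where(neg, 0.0, delta)
    w = np.ones_like(delta)
    if neg.any():
        w = w + np.where(neg, -delta / np.maximum(d, eps), 0.0)
    return SmacofSystem(A=a, W=w, D=d)


def stress(system: SmacofSystem, U: np.ndarray, V: np.ndarray) -> float:
    """Weighted raw STRESS sum w (a - d)^2 at a candidate configuration."""
    d = distances(U, V)
    return float((system.W * (system.A - d) ** 2).sum())


def raw_stress(delta: np.ndarray, U: np.ndarray, V: np.ndarray) -> float:
    """Unweighted raw STRESS sum (delta - d)^2 (delta may be negative)."""
    d = distances(U, V)
    return float(((delta - d) ** 2).sum())


def _guttman_terms(system: SmacofSystem):
    # C matrix of the Cauchy-Schwarz minorisation, zero where d = 0
    with np.errstate(divide="ignore", invalid="ignore"):
        c = np.where(system.D > 0, system.W * system.A / system.D, 0.0)
    return c


def mdu_update(system: SmacofSystem, current: Configuration) -> Configuration:
    """One Guttman-type alternating update of U then V.

    Minimises the joint quadratic majorizer anchored at ``current`` first in
    the row points, then in the item points; weighted raw STRESS with the
    system's (A, W) is non-increasing.
    """
    u0, v0 = current.U, current.V
    w, c = system.W, _guttman_terms(system)
    rw = w.sum(axis=1, keepdims=True)
    cw = w.sum(axis=0)[:, None]
    if rw.min() <= 0 or cw.min() <= 0:
        warnings.warn("singular weight totals; ridge guard applied", RuntimeWarning)
        rw = np.maximum(rw, 1e-12)
        cw = np.maximum(cw, 1e-12)
    u_new = (w @ v0 + c.sum(axis=1, keepdims=True) * u0 - c @ v0) / rw
    v_new = (w.T @ u_new + c.sum(axis=0)[:, None] * v0 - c.T @ u0) / cw
    return Configuration(U=u_new, V=v_new)


def rmdu_update(
    system: SmacofSystem,
    x: np.ndarray,
    current: Configuration,
    xqr=None,
) -> Configuration:
    """Restricted SMACOF sweep: regression update of B, then U = XB, then V.

    The unrestricted Guttman row target is projected onto the predictor
    space in the row-weight metric:
    ``B = (X' D_w X)^{-1} X' (W V0 + diag(C 1) U0 - C V0)``.
    """
    x = np.asarray(x, dtype=float)
    if xqr is None:
        qr_factor(x)  # rank check
    u0, v0 = current.U, current.V
    w, c = system.W, _guttman_terms(system)
    rw = w.sum(axis=1)
    m = w @ v0 + c.sum(axis=1, keepdims=True) * u0 - c @ v0
    xtwx = (x * rw[:, None]).T @ x
    try:
        b = np.linalg.solve(xtwx, x.T @ m)
    except np.linalg.LinAlgError:
        warnings.warn("singular weighted normal equations; ridge guard", RuntimeWarning)
        ridge = 1e-10 * np.trace(xtwx) / xtwx.shape[0]
        b = np.linalg.solve(xtwx + ridge * np.eye(xtwx.shape[0]), x.T @ m)
    u_new = x @ b
    cw = w.sum(axis=0)[:, None]
    v_new = (w.T @ u_new + c.sum(axis=0)[:, None] * v0 - c.T @ u0) / np.maximum(
        cw, _TINY
    )
    return Configuration(U=u_new, V=v_new, B=b)
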