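"""Synthetic data generation and the recovery / dimension-selection studies.

The generator emulates the study conditions of the restricted models: P = 5
correlated predictors, a two-dimensional population coefficient matrix B,
an item matrix with R = 4 locations (R = 8 by rotating the item matrix 45
degrees and appending), per-family population thresholds for 3- or 5-category
responses, and multinomial ordinal draws through the cumulative-logistic
link.  Predictors come from a multivariate normal, a moment-matched uniform
(Gaussian copula), or a 5-point Likert discretization, each standardized to
mean zero and unit variance.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import expit, ndtr

from .data import OrdinalDataset
from .model import CLRMDU, CLRRR
from .updates import Configuration, distances

# ---------------------------------------------------------------------------
# population fixture (synthetic; magnitudes comparable to survey-scale fits)
# ---------------------------------------------------------------------------

#: correlation matrix of the five predictors (attitude-survey-like: two
#: correlated attitude scores, gender, age, education)
PREDICTOR_CORR = np.array(
    [
        [1.00, 0.40, 0.10, 0.15, 0.20],
        [0.40, 1.00, 0.10, 0.10, 0.25],
        [0.10, 0.10, 1.00, 0.05, 0.10],
        [0.15, 0.10, 0.05, 1.00, 0.30],
        [0.20, 0.25, 0.10, 0.30, 1.00],
    ]
)

#: population coefficient matrix B (P = 5 predictors x S = 2 dimensions)
POPULATION_B = np.array(
    [
        [0.80, -0.20],
        [0.50, 0.60],
        [-0.40, 0.70],
        [0.30, -0.50],
        [-0.60, -0.30],
    ]
)

#: population item matrix V for R = 4 responses (S = 2)
POPULATION_V = np.array(
    [
        [1.00, 0.30],
        [0.60, -0.80],
        [-0.50, 0.90],
        [-0.90, -0.40],
    ]
)

#: population thresholds per family and category count.  Dominance
#: structural values are roughly symmetric around zero; proximity ones are
#: negative (minus a distance), so their thresholds sit below zero.
POPULATION_TAU = {
    ("dominance", 3): np.array([-0.8, 0.8]),
    ("dominance", 5): np.array([-1.5, -0.5, 0.5, 1.5]),
    ("proximity", 3): np.array([-2.0, -1.0]),
    ("proximity", 5): np.array([-2.4, -1.8, -1.2, -0.6]),
}


def rotation(angle_deg: float) -> np.ndarray:
    a = np.deg2rad(angle_deg)
    return np.array([[np.cos(a), -np.sin(a)], [np.sin(a), np.cos(a)]])


def item_matrix(n_items: int, base: np.ndarray | None = None) -> np.ndarray:
    """Population item matrix; R = 8 appends the 45-degree rotation of R = 4."""
    base = POPULATION_V if base is None else np.asarray(base, dtype=float)
    if n_items == base.shape[0]:
        return base.copy()
    if n_items == 2 * base.shape[0] and base.shape[1] == 2:
        return np.vstack([base, base @ rotation(45.0).T])
    raise ValueError(f"unsupported number of items {n_items}")


@dataclass
class SimulationDesign:
    """One cell of the factorial simulation design."""

    family: str = "dominance"  # 'dominance' (CLRRR) or 'proximity' (CLRMDU)
    n_obs: int = 500
    n_items: int = 4  # 4 or 8 (8 = rotated copy appended)
    n_cats: int = 3  # 3 or 5
    predictor_dist: str = "normal"  # 'normal' | 'uniform' | 'likert'
    coefficients: np.ndarray = field(default_factory=lambda: POPULATION_B.copy())
    items: np.ndarray | None = None
    tau: np.ndarray | None = None
    corr: np.ndarray = field(default_factory=lambda: PREDICTOR_CORR.copy())
    n_reps: int = 20
    seed: int = 0

    def __post_init__(self):
        if self.family not in ("dominance", "proximity"):
            raise ValueError("family must be 'dominance' or 'proximity'")
        if self.items is None:
            self.items = item_matrix(self.n_items)
        if self.tau is None:
            self.tau = POPULATION_TAU[(self.family, self.n_cats)].copy()
        vals = np.linalg.eigvalsh(self.corr)
        if vals.min() <= 0:
            raise ValueError("predictor correlation matrix is not positive definite")
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")
        if np.any(np.diff(np.atleast_1d(self.tau)) <= 0):
            raise ValueError("population thresholds must be strictly increasing")


def _rep_rng(design: SimulationDesign, rep: int) -> np.random.Generator:
    # independent substream per (master seed, replicate); condition order
    # does not affect draws
    return np.random.default_rng(np.random.SeedSequence([design.seed, rep]))


# standard deviation of the symmetric 5-point Likert cut of a standard
# normal at (-1.5, -0.5, 0.5, 1.5), used for exact standardization
_LIKERT_CUTS = np.array([-1.5, -0.5, 0.5, 1.5])
_LIKERT_P = np.diff(np.concatenate(([0.0], ndtr(_LIKERT_CUTS), [1.0])))
_LIKERT_SD = float(np.sqrt((_LIKERT_P * (np.arange(1, 6) - 3.0) ** 2).sum()))


def draw_predictors(design: SimulationDesign, rng) -> np.ndarray:
    """Predictors with the declared marginal distribution and correlation.

    All three variants start from correlated standard normals; 'uniform'
    maps them through the Gaussian copula to mean-zero unit-variance
    uniforms, 'likert' discretizes them into 5 points and standardizes.
    """
    p = design.corr.shape[0]
    chol = np.linalg.cholesky(design.corr)
    z = rng.standard_normal((design.n_obs, p)) @ chol.T
    if design.predictor_dist == "normal":
        return z
    if design.predictor_dist == "uniform":
        return np.sqrt(12.0) * (ndtr(z) - 0.5)
    if design.predictor_dist == "likert":
        codes = 1 + np.searchsorted(_LIKERT_CUTS, z).astype(float)
        return (codes - 3.0) / _LIKERT_SD
    raise ValueError(f"unknown predictor distribution {design.predictor_dist!r}")


def structural_matrix(design: SimulationDesign, x: np.ndarray) -> np.ndarray:
    u = x @ design.coefficients
    if design.family == "dominance":
        return u @ design.items.T
    return -distances(u, design.items)


def generate_dataset(design: SimulationDesign, rep: int = 0):
    """Draw one replicate: returns (OrdinalDataset, X, true Theta).

    Reproducible from (design.seed, rep); ordinal draws are multinomial
    through the cumulative-logistic probabilities.
    """
    rng = _rep_rng(design, rep)
    x = draw_predictors(design, rng)
    theta = structural_matrix(design, x)
    lam = expit(design.tau[None, None, :] - theta[:, :, None])
    u01 = rng.random(theta.shape)
    y = 1 + (u01[:, :, None] > lam).sum(axis=2)
    n_cats = np.full(theta.shape[1], design.n_cats)
    return OrdinalDataset(y, n_categories=n_cats), x, theta


def recovery_Q(theta_hat, theta_true) -> float:
    """Stress-1-type normalized discrepancy between structural matrices.

    ``Q = sqrt( sum (theta_hat - theta_true)^2 / sum theta_true^2 )``;
    invariant to rotation/reflection indeterminacies because it compares the
    structural matrices directly.
    """
    theta_hat = np.asarray(theta_hat, dtype=float)
    theta_true = np.asarray(theta_true, dtype=float)
    if theta_hat.shape != theta_true.shape:
        raise ValueError("structural matrices must have equal shapes")
    denom = (theta_true**2).sum()
    if denom == 0:
        raise ValueError("Q undefined for an all-zero true structural matrix")
    return float(np.sqrt(((theta_hat - theta_true) ** 2).sum() / denom))


def _model_for(design: SimulationDesign):
    return CLRRR if design.family == "dominance" else CLRMDU


def _truth_start(design: SimulationDesign, x) -> Configuration:
    b = design.coefficients
    return Configuration(U=x @ b, V=design.items.copy(), B=b.copy())


def fit_replicate(
    design: SimulationDesign,
    rep: int,
    n_dims: int = 2,
    extra_random_starts: int = 0,
    tol: float = 1e-6,
    max_iter: int = 500,
):
    """Generate one replicate and fit the matching restricted model.

    Proximity fits start from the population values (optionally plus random
    starts); dominance fits use the deterministic start.
    """
    y, x, theta = generate_dataset(design, rep)
    cls = _model_for(design)
    mod = cls(y, exog=x, n_dims=n_dims)
    kwargs = dict(tol=tol, max_iter=max_iter, seed=design.seed + 7919 * rep)
    if design.family == "proximity" and n_dims == design.coefficients.shape[1]:
        kwargs["start"] = _truth_start(design, x)
        kwargs["n_starts"] = 1 + extra_random_starts
    elif design.family == "proximity":
        kwargs["n_starts"] = 1 + extra_random_starts
    res = mod.fit(**kwargs)
    return res, theta


def run_recovery_study(
    designs,
    n_reps: int | None = None,
    n_dims: int = 2,
    tol: float = 1e-6,
    max_iter: int = 500,
    extra_random_starts: int = 0,
    verbose: bool = False,
) -> pd.DataFrame:
    """Per-replicate recovery Q for each design cell (tidy table)."""
    rows = []
    for design in designs:
        reps = design.n_reps if n_reps is None else n_reps
        for rep in range(reps):
            res, theta = fit_replicate(
                design,
                rep,
                n_dims=n_dims,
                extra_random_starts=extra_random_starts,
                tol=tol,
                max_iter=max_iter,
            )
            rows.append(
                {
                    "family": design.family,
                    "n_obs": design.n_obs,
                    "n_items": design.n_items,
                    "n_cats": design.n_cats,
                    "predictor_dist": design.predictor_dist,
                    "rep": rep,
                    "Q": recovery_Q(res.theta, theta),
                    "deviance": res.deviance,
                    "converged": res.converged,
                }
            )
            if verbose:
                print(rows[-1])
    return pd.DataFrame(rows)


def run_dimension_selection_study(
    designs,
    n_reps: int | None = None,
    fit_dims=(1, 2, 3),
    tol: float = 1e-7,
    max_iter: int = 1500,
    extra_random_starts: int = 0,
    verbose: bool = False,
) -> pd.DataFrame:
    """AIC/BIC-chosen dimensionality per replicate (data generated at S = 2).

    Returns a tidy table with one row per replicate carrying the selected
    dimensionality under each criterion; aggregate with value_counts to
    reproduce selection-count tables.
    """
    rows = []
    for design in designs:
        reps = design.n_reps if n_reps is None else n_reps
        for rep in range(reps):
            aics, bics = {}, {}
            for s in fit_dims:
                res, _ = fit_replicate(
                    design,
                    rep,
                    n_dims=int(s),
                    extra_random_starts=extra_random_starts,
                    tol=tol,
                    max_iter=max_iter,
                )
                aics[int(s)] = res.aic
                bics[int(s)] = res.bic
            rows.append(
                {
                    "family": design.family,
                    "n_obs": design.n_obs,
                    "n_items": design.n_items,
                    "n_cats": design.n_cats,
                    "predictor_dist": design.predictor_dist,
                    "rep": rep,
                    "aic_choice": min(aics, key=aics.get),
                    "bic_choice": min(bics, key=bics.get),
                    **{f"aic_{s}": v for s, v in aics.items()},
                    **{f"bic_{s}": v for s, v in bics.items()},
                }
            )
            if verbose:
                print(rows[-1])
    return pd.DataFrame(rows)


def design_grid(
    family: str,
    n_obs=(250, 500, 1000),
    n_items=(4, 8),
    n_cats=(3, 5),
    predictor_dist=("normal",),
    n_reps: int = 20,
    seed: int = 0,
) -> list[SimulationDesign]:
    """Full factorial grid of designs for one family."""
    out = []
    for n in n_obs:
        for r in n_items:
            for c in n_cats:
                for dist in predictor_dist:
                    out.append(
                        SimulationDesign(
                            family=family,
                            n_obs=int(n),
                            n_items=int(r),
                            n_cats=int(c),
                            predictor_dist=dist,
                            n_reps=n_reps,
                            seed=seed,
                        )
                    )
    return out


def with_seed(design: SimulationDesign, seed: int) -> SimulationDesign:
    """Copy of a design with a different master seed."""
    return replace(design, seed=seed)
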