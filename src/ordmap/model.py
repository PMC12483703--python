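"""Model classes and the outer EMM loop.

Four models share one estimation scheme: an EM outer loop whose M-step is a
majorization-minimization step.  Each outer iteration (i) computes the
closed-form conditional expectation of the complete-data score (E-step) and
the working responses, (ii) refits the structural part by least squares
(SVD / generalized SVD for the dominance models, a SMACOF sweep for the
proximity models), and (iii) re-estimates the per-response cut-points by
maximum likelihood with the structural values as offset.  Every step weakly
decreases the observed-data deviance.

Dominance fits reach the global minimum from any start; proximity fits can
hit local minima, so they run a deterministic correspondence-analysis start
plus random starts and keep the best.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from . import logistic, thresholds, updates
from .data import OrdinalDataset
from .selection import count_parameters, information_criteria
from .updates import Configuration

__all__ = [
    "CLPCA",
    "CLRRR",
    "CLMDU",
    "CLRMDU",
    "CLResults",
    "CumulativeLogisticModel",
    "fit_model",
]

_MODEL_NAMES = {"clpca", "clrrr", "clmdu", "clrmdu"}


def _ca_start(y: OrdinalDataset, n_dims: int, rng=None) -> Configuration:
    """Correspondence-analysis-flavoured start for the unfolding models.

    Treats the integer codes as a two-way table, decomposes the standardized
    residuals and scales row/column coordinates to unit root-mean-square, so
    that small distances correspond to strong positive association.
    """
    f = y.y.astype(float)
    n = f.sum()
    r = f.sum(axis=1) / n
    c = f.sum(axis=0) / n
    resid = (f / n - np.outer(r, c)) / np.sqrt(np.outer(r, c))
    pmat, phi, qt = np.linalg.svd(resid, full_matrices=False)
    s_avail = min(n_dims, phi.size)
    u = pmat[:, :s_avail] * phi[:s_avail] / np.sqrt(r)[:, None]
    v = qt[:s_avail].T * phi[:s_avail] / np.sqrt(c)[:, None]
    if s_avail < n_dims:
        rng = rng or np.random.default_rng(0)
        u = np.hstack([u, 0.01 * rng.standard_normal((u.shape[0], n_dims - s_avail))])
        v = np.hstack([v, 0.01 * rng.standard_normal((v.shape[0], n_dims - s_avail))])
    scale = np.sqrt(np.mean(np.vstack([u, v]) ** 2)) or 1.0
    return Configuration(U=u / scale, V=v / scale)


@dataclass
class CLResults:
    """Fit results: estimates, fit measures and the deviance trace.

    ``row_scores`` (U) holds principal scores / ideal points, ``item_scores``
    (V) loadings / item locations, ``coefficients`` (B) the predictor
    weights of restricted models (with U = X B).  The deviance trace is
    non-increasing across outer iterations by construction of the EMM steps.
    """

    model: "CumulativeLogisticModel"
    row_scores: np.ndarray
    item_scores: np.ndarray
    coefficients: np.ndarray | None
    thresholds: list[np.ndarray]
    deviance: float
    deviance_trace: np.ndarray
    null_deviance: float
    converged: bool
    n_iter: int
    best_start: int = 0
    start_deviances: list = field(default_factory=list)

    # -- aliases used throughout ------------------------------------
    @property
    def U(self):
        return self.row_scores

    @property
    def V(self):
        return self.item_scores

    @property
    def B(self):
        return self.coefficients

    @property
    def theta(self) -> np.ndarray:
        return self.model.structure(
            Configuration(self.row_scores, self.item_scores, self.coefficients)
        )

    @property
    def n_parameters(self) -> int:
        m = self.model
        return count_parameters(
            m.name,
            m.n_dims,
            m.endog.n_categories,
            n_obs=m.endog.n_obs,
            n_predictors=None if m.exog is None else m.exog.shape[1],
        )

    @property
    def aic(self) -> float:
        return information_criteria(
            self.deviance, self.n_parameters, self.model.endog.n_obs
        )[0]

    @property
    def bic(self) -> float:
        return information_criteria(
            self.deviance, self.n_parameters, self.model.endog.n_obs
        )[1]

    # -- prediction --------------------------------------------------
    def predict_proba(self) -> np.ndarray:
        """Fitted category probabilities, padded to (N, R, Cmax)."""
        return logistic.category_probabilities(self.theta, self.thresholds)

    def predict_category(self) -> np.ndarray:
        """Latent-rule prediction: category c with tau_{c-1} < theta <= tau_c."""
        theta = self.theta
        out = np.empty_like(self.model.endog.y)
        # boundary theta == tau belongs to the lower category
        for r, t in enumerate(self.thresholds):
            out[:, r] = 1 + (theta[:, r][:, None] > t[None, :]).sum(axis=1)
        return out

    def biplot(self, dims=(0, 1), **kwargs):
        """Render the biplot/triplot for a pair of dimensions."""
        from .biplot import build_geometry, render

        return render(build_geometry(self, dims=dims), **kwargs)

    # -- reporting ---------------------------------------------------
    def summary(self) -> str:
        m = self.model
        lines = []
        head = {
            "clpca": "Cumulative Logistic PCA",
            "clrrr": "Cumulative Logistic Reduced-Rank Regression",
            "clmdu": "Cumulative Logistic Multidimensional Unfolding",
            "clrmdu": "Cumulative Logistic Restricted MDU",
        }[m.name]
        lines.append(head)
        lines.append("=" * len(head))
        lines.append(
            f"N = {m.endog.n_obs}   responses = {m.endog.n_responses}   "
            f"dimensions = {m.n_dims}"
            + ("" if m.exog is None else f"   predictors = {m.exog.shape[1]}")
        )
        lines.append(
            f"deviance = {self.deviance:.4f}   null deviance = "
            f"{self.null_deviance:.4f}"
        )
        lines.append(
            f"parameters = {self.n_parameters}   AIC = {self.aic:.4f}   "
            f"BIC = {self.bic:.4f}"
        )
        lines.append(
            f"converged = {self.converged}   outer iterations = {self.n_iter}"
            + (
                f"   best start = {self.best_start + 1}/{len(self.start_deviances)}"
                if len(self.start_deviances) > 1
                else ""
            )
        )
        lines.append("")
        if self.coefficients is not None:
            lines.append("Coefficients B (predictors x dimensions)")
            for name, row in zip(m.predictor_names, self.coefficients):
                lines.append(
                    f"  {name:<12s} " + " ".join(f"{v: .4f}" for v in row)
                )
            lines.append("")
        lines.append("Item structure V and thresholds")
        for name, row, t in zip(
            m.endog.response_names, self.item_scores, self.thresholds
        ):
            vtxt = " ".join(f"{v: .4f}" for v in row)
            ttxt = ", ".join(f"{v:.3f}" for v in t)
            lines.append(f"  {name:<12s} {vtxt}   tau: [{ttxt}]")
        return "\n".join(lines)

    # -- serialization ----------------------------------------------
    def to_dict(self) -> dict:
        m = self.model
        return {
            "model": m.name,
            "representation": m.representation,
            "restricted": m.restricted,
            "n_dims": m.n_dims,
            "n_obs": m.endog.n_obs,
            "response_names": m.endog.response_names,
            "n_categories": m.endog.n_categories.tolist(),
            "predictor_names": None if m.exog is None else list(m.predictor_names),
            "row_scores": self.row_scores.tolist(),
            "item_scores": self.item_scores.tolist(),
            "coefficients": None
            if self.coefficients is None
            else self.coefficients.tolist(),
            "thresholds": [t.tolist() for t in self.thresholds],
            "deviance": self.deviance,
            "null_deviance": self.null_deviance,
            "deviance_trace": np.asarray(self.deviance_trace).tolist(),
            "n_parameters": self.n_parameters,
            "aic": self.aic,
            "bic": self.bic,
            "converged": self.converged,
            "n_iter": self.n_iter,
            "predictor_meta": m.predictor_meta,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)


class CumulativeLogisticModel:
    """Base class; use CLPCA, CLRRR, CLMDU or CLRMDU.

    Parameters
    ----------
    endog : OrdinalDataset or array-like of int (N, R)
        Ordinal responses coded 1..C_r.
    exog : array-like (N, P), optional
        Predictors (restricted models only); should be standardized /
        dummy-coded, see :mod:`ordmap.io`.
    n_dims : int
        Dimensionality S of the latent space.
    """

    name: str = ""
    representation: str = ""
    restricted: bool = False

    def __init__(
        self,
        endog,
        exog=None,
        n_dims: int = 2,
        response_names=None,
        predictor_names=None,
        predictor_meta=None,
    ):
        if not isinstance(endog, OrdinalDataset):
            endog = OrdinalDataset(endog, response_names=response_names)
        self.endog = endog
        if self.restricted:
            if exog is None:
                raise ValueError(f"{self.name} requires predictor variables")
            exog = np.asarray(exog, dtype=float)
            if exog.ndim != 2 or exog.shape[0] != endog.n_obs:
                raise ValueError("exog must be (N, P)")
            self._xqr = updates.qr_factor(exog)
        elif exog is not None:
            raise ValueError(f"{self.name} does not take predictor variables")
        self.exog = exog
        self.n_dims = int(n_dims)
        if self.n_dims < 1:
            raise ValueError("n_dims must be >= 1")
        if predictor_names is None and exog is not None:
            predictor_names = [f"x{j + 1}" for j in range(exog.shape[1])]
        self.predictor_names = predictor_names
        self.predictor_meta = predictor_meta

    @classmethod
    def from_dataframe(
        cls,
        df,
        responses,
        predictors=None,
        orderings=None,
        n_dims: int = 2,
        references=None,
    ):
        """Build a model from a DataFrame of raw columns.

        ``responses`` are remapped through ``orderings`` (label lists, low to
        high); numeric predictors are standardized and categorical ones
        dummy-coded against ``references``.
        """
        from .io import encode_predictors

        endog = OrdinalDataset.from_dataframe(df, responses, orderings)
        exog = names = meta = None
        if predictors:
            exog, names, meta = encode_predictors(df, predictors, references)
        return cls(
            endog,
            exog=exog,
            n_dims=n_dims,
            predictor_names=names,
            predictor_meta=meta,
        )

    # -- structural geometry ----------------------------------------
    def structure(self, conf: Configuration) -> np.ndarray:
        """Theta from a configuration: inner products or negated distances."""
        if self.representation == "dominance":
            return conf.U @ conf.V.T
        return -updates.distances(conf.U, conf.V)

    # -- starts ------------------------------------------------------
    def _default_n_starts(self) -> int:
        return 1 if self.representation == "dominance" else 10

    def _start_configs(self, n_starts, rng, tau0, start):
        y = self.endog
        configs = []
        if start is not None:
            configs.append(start)
        if self.representation == "dominance":
            # deterministic: SVD of the working responses at theta = 0
            theta0 = np.zeros((y.n_obs, y.n_responses))
            g = logistic.expected_gradient(y, theta0, tau0)
            z = logistic.working_responses(theta0, g)
            if self.restricted:
                configs.append(
                    updates.rrr_update(z, self.exog, self.n_dims, self._xqr)
                )
            else:
                configs.append(updates.pca_update(z, self.n_dims))
        else:
            ca = _ca_start(y, self.n_dims, rng)
            configs.append(self._restrict(ca))
            while len(configs) < n_starts:
                u = rng.standard_normal((y.n_obs, self.n_dims))
                v = rng.standard_normal((y.n_responses, self.n_dims))
                configs.append(self._restrict(Configuration(U=u, V=v)))
        return configs[:n_starts] if n_starts else configs[:1]

    def _restrict(self, conf: Configuration) -> Configuration:
        """Project a free configuration onto U = X B (no-op when unrestricted)."""
        if not self.restricted:
            return conf
        b, *_ = np.linalg.lstsq(self.exog, conf.U, rcond=None)
        return Configuration(U=self.exog @ b, V=conf.V, B=b)

    # -- M-step ------------------------------------------------------
    def _structural_update(self, z, conf, inner_sweeps, eps):
        if self.representation == "dominance":
            if self.restricted:
                return updates.rrr_update(z, self.exog, self.n_dims, self._xqr)
            return updates.pca_update(z, self.n_dims)
        for _ in range(inner_sweeps):
            system = updates.build_smacof_system(z, conf, eps=eps)
            if self.restricted:
                conf = updates.rmdu_update(system, self.exog, conf, self._xqr)
            else:
                conf = updates.mdu_update(system, conf)
        return conf

    # -- fitting -----------------------------------------------------
    def fit(
        self,
        tol: float = 1e-6,
        max_iter: int = 5000,
        n_starts: int | None = None,
        seed=None,
        start: Configuration | None = None,
        inner_sweeps: int = 1,
        eps: float = updates.SMACOF_EPS,
    ) -> CLResults:
        """Run the EMM algorithm; for proximity models, best of ``n_starts``.

        Convergence: relative deviance change below ``tol``.  ``start``
        supplies an explicit extra starting configuration (counted first).
        """
        y = self.endog
        rng = np.random.default_rng(seed)
        if n_starts is None:
            n_starts = 1 if (start is not None) else self._default_n_starts()
        tau0 = thresholds.fit_all_thresholds(
            y.y, y.n_categories, np.zeros((y.n_obs, y.n_responses))
        )
        null_dev = logistic.deviance(
            y, np.zeros((y.n_obs, y.n_responses)), tau0
        )
        best = None
        start_devs = []
        for idx, conf in enumerate(
            self._start_configs(n_starts, rng, tau0, start)
        ):
            out = self._fit_single(conf, tau0, tol, max_iter, inner_sweeps, eps)
            start_devs.append(out[2][-1])
            if best is None or out[2][-1] < best[2][-1]:
                best = out
                best_idx = idx
        conf, tau, trace, converged = best
        return CLResults(
            model=self,
            row_scores=conf.U,
            item_scores=conf.V,
            coefficients=conf.B,
            thresholds=tau,
            deviance=float(trace[-1]),
            deviance_trace=np.asarray(trace),
            null_deviance=null_dev,
            converged=converged,
            n_iter=len(trace) - 1,
            best_start=best_idx,
            start_deviances=start_devs,
        )

    def _fit_single(self, conf, tau0, tol, max_iter, inner_sweeps, eps):
        y = self.endog
        tau = [t.copy() for t in tau0]
        theta = self.structure(conf)
        tau = thresholds.fit_all_thresholds(
            y.y, y.n_categories, theta, tau0=tau
        )
        dev = logistic.deviance(y, theta, tau)
        trace = [dev]
        converged = False
        for _ in range(max_iter):
            g = logistic.expected_gradient(y, theta, tau)
            z = logistic.working_responses(theta, g)
            conf = self._structural_update(z, conf, inner_sweeps, eps)
            theta = self.structure(conf)
            # warm-started: a couple of damped Newton steps per outer
            # iteration suffice and keep the deviance monotone
            tau = thresholds.fit_all_thresholds(
                y.y, y.n_categories, theta, tau0=tau, max_iter=2
            )
            dev_new = logistic.deviance(y, theta, tau)
            if not np.isfinite(dev_new):
                raise RuntimeError(
                    "non-finite deviance during EMM; last finite deviance "
                    f"{dev:.6f}"
                )
            trace.append(dev_new)
            if dev - dev_new < tol * (abs(dev_new) + 1.0):
                converged = True
                dev = dev_new
                break
            dev = dev_new
        return conf, tau, trace, converged


class CLPCA(CumulativeLogisticModel):
    """Cumulative logistic PCA: Theta = U V' (dominance, unrestricted)."""

    name = "clpca"
    representation = "dominance"
    restricted = False


class CLRRR(CumulativeLogisticModel):
    """Cumulative logistic reduced-rank regression: Theta = X B V'."""

    name = "clrrr"
    representation = "dominance"
    restricted = True


class CLMDU(CumulativeLogisticModel):
    """Cumulative logistic unfolding: Theta = -d(U, V) (proximity)."""

    name = "clmdu"
    representation = "proximity"
    restricted = False


class CLRMDU(CumulativeLogisticModel):
    """Cumulative logistic restricted unfolding: U = X B, Theta = -d."""

    name = "clrmdu"
    representation = "proximity"
    restricted = True


_CLASSES = {c.name: c for c in (CLPCA, CLRRR, CLMDU, CLRMDU)}


def fit_model(y, x=None, model: str = "clpca", n_dims: int = 2, **fit_kwargs):
    """Functional one-shot interface: build the model class and fit it."""
    model = model.lower()
    if model not in _CLASSES:
        raise ValueError(f"unknown model {model!r}")
    cls = _CLASSES[model]
    mod = cls(y, exog=x if cls.restricted else None, n_dims=n_dims)
    return mod.fit(**fit_kwargs)


def results_from_dict(doc: dict) -> dict:
    """Parse a serialized fit document back into arrays (for plotting)."""
    out = dict(doc)
    out["row_scores"] = np.asarray(doc["row_scores"], dtype=float)
    out["item_scores"] = np.asarray(doc["item_scores"], dtype=float)
    if doc.get("coefficients") is not None:
        out["coefficients"] = np.asarray(doc["coefficients"], dtype=float)
    out["thresholds"] = [np.asarray(t, dtype=float) for t in doc["thresholds"]]
    return out
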