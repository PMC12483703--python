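"""Biplot and triplot geometry for the cumulative-logistic models.

Dominance models: each response is a calibrated axis through the origin with
direction ``v_r``; the marker for cut-point ``tau_rc`` sits at
``(tau_rc / v_r'v_r) v_r`` and is labelled ``c|c+1`` — every point whose
inner product with ``v_r`` equals ``tau_rc`` projects exactly onto it.
Decision lines run orthogonal to the axis through the markers.

Proximity models: each response is a point ``v_r`` with concentric decision
circles of radius ``-tau_rc``; inside circle ``c`` the probability of
responding above ``c`` exceeds one half.  Circles with non-positive radius
(``tau_rc >= 0``) are suppressed.

Restricted models add predictor geometry: numeric predictors get axes with a
solid segment over the observed range and back-transformed value markers;
each non-reference category of a categorical predictor gets a point at its
coefficient row (reference at the origin).  Interpolation of a predictor
profile is vector addition, i.e. ``x' B``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "BiplotGeometry",
    "pca_axis_markers",
    "mdu_threshold_circles",
    "triplot_elements",
    "interpolate",
    "build_geometry",
    "assign_regions",
    "render",
]


@dataclass
class ResponseAxis:
    name: str
    direction: np.ndarray  # (2,)
    markers: np.ndarray  # (K, 2) marker coordinates
    labels: list[str]
    thresholds: np.ndarray


@dataclass
class ResponseItem:
    name: str
    point: np.ndarray  # (2,)
    radii: np.ndarray  # (K,) = -tau, may be <= 0
    labels: list[str]
    drawn: np.ndarray  # bool mask: radius > 0
    thresholds: np.ndarray


@dataclass
class PredictorAxis:
    name: str
    direction: np.ndarray  # (2,) row of B
    solid: np.ndarray  # (2, 2) endpoints of the observed-range segment
    marker_values: np.ndarray  # original-scale values at the markers
    marker_coords: np.ndarray  # (M, 2)


@dataclass
class CategoryPoint:
    name: str
    category: str
    point: np.ndarray  # (2,)


@dataclass
class BiplotGeometry:
    representation: str
    row_points: np.ndarray
    responses: list
    predictors: list = field(default_factory=list)
    dims: tuple = (0, 1)


def pca_axis_markers(v_r, tau_r):
    """Threshold markers on a dominance variable axis.

    Marker ``c`` lies at ``(tau_rc / v'v) v`` with label ``c|c+1``; any point
    ``u`` with ``u'v = tau_rc`` projects onto it.
    """
    v = np.asarray(v_r, dtype=float)
    tau = np.atleast_1d(np.asarray(tau_r, dtype=float))
    norm2 = float(v @ v)
    if norm2 == 0:
        warnings.warn("zero loading vector; axis suppressed", RuntimeWarning)
        return np.zeros((0, v.size)), []
    markers = (tau / norm2)[:, None] * v[None, :]
    labels = [f"{c}|{c + 1}" for c in range(1, tau.size + 1)]
    return markers, labels


def mdu_threshold_circles(v_r, tau_r):
    """Decision circles around a proximity item point.

    Circle ``c`` has center ``v_r`` and radius ``-tau_rc``; it is drawn only
    when the radius is strictly positive.
    """
    v = np.asarray(v_r, dtype=float)
    tau = np.atleast_1d(np.asarray(tau_r, dtype=float))
    radii = -tau
    labels = [f"{c}|{c + 1}" for c in range(1, tau.size + 1)]
    return v, radii, labels, radii > 0


def interpolate(profile, coefficients) -> np.ndarray:
    """Position of a predictor profile by vector addition: ``x' B``."""
    return np.asarray(profile, dtype=float) @ np.asarray(coefficients, dtype=float)


def _nice_values(lo, hi, max_n=5):
    span = hi - lo
    if span <= 0:
        return np.array([lo])
    raw = span / max_n
    mag = 10.0 ** np.floor(np.log10(raw))
    step = min(
        (m for m in (1.0, 2.0, 2.5, 5.0, 10.0) if m * mag >= raw),
        default=10.0,
    ) * mag
    first = np.ceil(lo / step) * step
    return np.arange(first, hi + 0.5 * step, step)


def triplot_elements(coefficients, predictor_meta=None, x=None, names=None):
    """Predictor geometry for restricted-model triplots.

    Numeric predictor ``p``: axis with direction ``B[p]``, a solid segment
    spanning the observed (standardized) range, and markers at round
    original-scale values (back-transformed through the stored mean/sd).
    Categorical predictors: one point per non-reference category.
    """
    b = np.asarray(coefficients, dtype=float)
    p = b.shape[0]
    if names is None:
        names = [f"x{j + 1}" for j in range(p)]
    meta = predictor_meta or {}
    axes, points = [], []
    for j, name in enumerate(names):
        info = meta.get(name, {"type": "numeric", "mean": 0.0, "sd": 1.0})
        if info.get("type") == "categorical":
            points.append(
                CategoryPoint(
                    name=info.get("predictor", name),
                    category=info.get("category", name),
                    point=b[j],
                )
            )
            continue
        mean = float(info.get("mean", 0.0))
        sd = float(info.get("sd", 1.0))
        if x is not None:
            lo_std, hi_std = float(x[:, j].min()), float(x[:, j].max())
        else:
            lo_std, hi_std = info.get("min", -2.0), info.get("max", 2.0)
        solid = np.vstack([lo_std * b[j], hi_std * b[j]])
        vals = _nice_values(mean + lo_std * sd, mean + hi_std * sd)
        coords = ((vals - mean) / sd)[:, None] * b[j][None, :]
        axes.append(
            PredictorAxis(
                name=name,
                direction=b[j],
                solid=solid,
                marker_values=vals,
                marker_coords=coords,
            )
        )
    return axes, points


def build_geometry(results, dims=(0, 1)) -> BiplotGeometry:
    """Biplot/triplot geometry from a fitted-results object (or fit dict)."""
    if isinstance(results, dict):
        rep = results["representation"]
        u = results["row_scores"]
        v = results["item_scores"]
        b = results.get("coefficients")
        tau = results["thresholds"]
        rnames = results["response_names"]
        pnames = results.get("predictor_names")
        meta = results.get("predictor_meta") or {}
    else:
        m = results.model
        rep = m.representation
        u, v, b = results.row_scores, results.item_scores, results.coefficients
        tau = results.thresholds
        rnames = m.endog.response_names
        pnames = m.predictor_names
        meta = m.predictor_meta or {}
    dims = tuple(dims)
    if len(dims) != 2:
        raise ValueError("a biplot needs exactly two dimensions")
    if max(dims) >= u.shape[1] and u.shape[1] == 1:
        # one-dimensional fit: second coordinate identically zero
        u = np.hstack([u, np.zeros_like(u)])
        v = np.hstack([v, np.zeros_like(v)])
        if b is not None:
            b = np.hstack([b, np.zeros_like(b)])
        dims = (0, 1)
    u2 = np.asarray(u)[:, list(dims)]
    v2 = np.asarray(v)[:, list(dims)]
    responses = []
    for r, name in enumerate(rnames):
        t = np.atleast_1d(tau[r])
        if rep == "dominance":
            markers, labels = pca_axis_markers(v2[r], t)
            responses.append(
                ResponseAxis(
                    name=name,
                    direction=v2[r],
                    markers=markers,
                    labels=labels,
                    thresholds=t,
                )
            )
        else:
            center, radii, labels, drawn = mdu_threshold_circles(v2[r], t)
            responses.append(
                ResponseItem(
                    name=name,
                    point=center,
                    radii=radii,
                    labels=labels,
                    drawn=drawn,
                    thresholds=t,
                )
            )
    predictors = []
    if b is not None:
        b2 = np.asarray(b)[:, list(dims)]
        axes, points = triplot_elements(b2, meta, names=pnames)
        predictors = axes + points
    return BiplotGeometry(
        representation=rep,
        row_points=u2,
        responses=responses,
        predictors=predictors,
        dims=dims,
    )


def assign_regions(points, geometry: BiplotGeometry) -> np.ndarray:
    """Category assignment of plane points from the drawn decision geometry.

    Dominance: the scalar position of the projection along the axis is
    compared against the marker positions.  Proximity: the category is one
    plus the number of decision circles strictly containing the point.
    Returns an (n_points, R) integer array.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    out = np.empty((pts.shape[0], len(geometry.responses)), dtype=int)
    for r, resp in enumerate(geometry.responses):
        if geometry.representation == "dominance":
            v = resp.direction
            norm2 = float(v @ v)
            # scalar coefficient of the projection along v, for the points
            # and for the markers; a point past marker c responds above c
            t_pts = pts @ v / norm2
            t_markers = resp.markers @ v / norm2
            out[:, r] = 1 + (t_pts[:, None] > t_markers[None, :]).sum(axis=1)
        else:
            d = np.linalg.norm(pts - resp.point[None, :], axis=1)
            out[:, r] = 1 + (d[:, None] < resp.radii[None, :]).sum(axis=1)
    return out


def geometry_to_dict(geometry: BiplotGeometry) -> dict:
    """Structured-text export of the geometry for external plotting."""
    doc = {
        "representation": geometry.representation,
        "dims": list(geometry.dims),
        "row_points": geometry.row_points.tolist(),
        "responses": [],
        "predictors": [],
    }
    for resp in geometry.responses:
        if isinstance(resp, ResponseAxis):
            doc["responses"].append(
                {
                    "kind": "axis",
                    "name": resp.name,
                    "direction": resp.direction.tolist(),
                    "markers": resp.markers.tolist(),
                    "labels": resp.labels,
                    "thresholds": resp.thresholds.tolist(),
                }
            )
        else:
            doc["responses"].append(
                {
                    "kind": "item",
                    "name": resp.name,
                    "point": resp.point.tolist(),
                    "radii": resp.radii.tolist(),
                    "labels": resp.labels,
                    "drawn": resp.drawn.tolist(),
                    "thresholds": resp.thresholds.tolist(),
                }
            )
    for pred in geometry.predictors:
        if isinstance(pred, PredictorAxis):
            doc["predictors"].append(
                {
                    "kind": "axis",
                    "name": pred.name,
                    "direction": pred.direction.tolist(),
                    "solid": pred.solid.tolist(),
                    "marker_values": pred.marker_values.tolist(),
                    "marker_coords": pred.marker_coords.tolist(),
                }
            )
        else:
            doc["predictors"].append(
                {
                    "kind": "point",
                    "name": pred.name,
                    "category": pred.category,
                    "point": pred.point.tolist(),
                }
            )
    return doc


def _extend_to_edge(direction, lim):
    """Scalar t such that t * direction hits the plotting box boundary."""
    d = np.asarray(direction, dtype=float)
    if np.allclose(d, 0):
        return 0.0
    ts = []
    for k in (0, 1):
        if d[k] != 0:
            ts.append(abs(lim / d[k]))
    return min(ts)


def render(
    geometry: BiplotGeometry,
    path=None,
    ax=None,
    figsize=(7.0, 7.0),
    point_kwargs=None,
    show_decision_lines=True,
):
    """Deterministic matplotlib rendering of a biplot/triplot.

    Response labels sit at the positive end of each axis; predictor axes are
    solid over the observed range and dotted out to the plot edge.  Returns
    the figure.  With a one-dimensional geometry the second coordinate is
    zero, giving a stripe plot.
    """
    import matplotlib

    if path is not None and matplotlib.get_backend().lower() != "agg":
        matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        fig, ax = plt.subplots(figsize=figsize)
    else:
        fig = ax.figure
    pts = geometry.row_points
    extent = 1.0
    if pts.size:
        ax.scatter(
            pts[:, 0],
            pts[:, 1],
            s=12,
            c="0.6",
            zorder=1,
            **(point_kwargs or {}),
        )
        extent = max(extent, np.abs(pts).max())
    for resp in geometry.responses:
        if isinstance(resp, ResponseAxis):
            if resp.markers.size:
                extent = max(extent, np.abs(resp.markers).max())
        else:
            rad = resp.radii[resp.drawn]
            reach = np.abs(resp.point).max() + (rad.max() if rad.size else 0.0)
            extent = max(extent, reach)
    lim = 1.1 * extent
    for resp in geometry.responses:
        if isinstance(resp, ResponseAxis):
            t = _extend_to_edge(resp.direction, lim)
            line = np.vstack([-t * resp.direction, t * resp.direction])
            ax.plot(line[:, 0], line[:, 1], color="darkgreen", lw=1.2, zorder=2)
            for (mx, my), lab in zip(resp.markers, resp.labels):
                ax.plot(mx, my, marker="o", ms=4, color="darkgreen")
                ax.annotate(
                    lab, (mx, my), fontsize=7, color="darkgreen",
                    textcoords="offset points", xytext=(3, 3),
                )
                if show_decision_lines:
                    perp = np.array(
                        [-resp.direction[1], resp.direction[0]], dtype=float
                    )
                    nrm = np.linalg.norm(perp) or 1.0
                    perp = perp / nrm * lim * 2
                    ax.plot(
                        [mx - perp[0], mx + perp[0]],
                        [my - perp[1], my + perp[1]],
                        ls=":",
                        lw=0.6,
                        color="darkgreen",
                        zorder=0,
                    )
            end = t * resp.direction
            ax.annotate(
                resp.name, end, fontsize=9, color="darkgreen", fontweight="bold"
            )
        else:
            ax.plot(*resp.point, marker="o", ms=6, color="darkgreen")
            ax.annotate(
                resp.name,
                resp.point,
                fontsize=9,
                color="darkgreen",
                fontweight="bold",
                textcoords="offset points",
                xytext=(4, 4),
            )
            for radius, lab, drawn in zip(resp.radii, resp.labels, resp.drawn):
                if not drawn:
                    continue
                circ = plt.Circle(
                    resp.point, radius, fill=False, color="darkgreen",
                    lw=0.8, ls="--",
                )
                ax.add_patch(circ)
                ax.annotate(
                    lab,
                    (resp.point[0], resp.point[1] + radius),
                    fontsize=7,
                    color="darkgreen",
                    ha="center",
                )
    for pred in geometry.predictors:
        if isinstance(pred, PredictorAxis):
            t = _extend_to_edge(pred.direction, lim)
            dotted = np.vstack([-t * pred.direction, t * pred.direction])
            ax.plot(
                dotted[:, 0], dotted[:, 1], ls=":", lw=0.8,
                color="steelblue", zorder=2,
            )
            ax.plot(
                pred.solid[:, 0], pred.solid[:, 1], lw=1.6,
                color="steelblue", zorder=3,
            )
            for (mx, my), val in zip(pred.marker_coords, pred.marker_values):
                ax.plot(mx, my, marker="|", ms=6, color="steelblue")
                ax.annotate(
                    f"{val:g}", (mx, my), fontsize=6, color="steelblue",
                    textcoords="offset points", xytext=(2, -8),
                )
            ax.annotate(
                pred.name,
                t * pred.direction,
                fontsize=9,
                color="steelblue",
                fontweight="bold",
            )
        else:
            ax.plot(*pred.point, marker="s", ms=5, color="indigo")
            ax.annotate(
                f"{pred.category}",
                pred.point,
                fontsize=8,
                color="indigo",
                textcoords="offset points",
                xytext=(4, 4),
            )
    ax.set_xlim(-lim, lim)
    ax.set_ylim(-lim, lim)
    ax.set_aspect("equal")
    ax.axhline(0, color="0.85", lw=0.5, zorder=0)
    ax.axvline(0, color="0.85", lw=0.5, zorder=0)
    ax.set_xlabel(f"dimension {geometry.dims[0] + 1}")
    ax.set_ylabel(f"dimension {geometry.dims[1] + 1}")
    if path is not None:
        fig.savefig(path, bbox_inches="tight", dpi=150)
    return fig
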