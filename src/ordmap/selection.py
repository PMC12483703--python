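"""Parameter counting, information criteria and stepwise model selection."""

from __future__ import annotations

import numpy as np
import pandas as pd

_FAMILIES = ("clpca", "clrrr", "clmdu", "clrmdu")


def threshold_parameters(n_categories) -> int:
    """Sum over responses of C_r - 1 free cut-points."""
    return int(np.sum(np.asarray(n_categories) - 1))


def structural_parameters(
    model: str, n_dims: int, n_responses: int, n_obs=None, n_predictors=None
) -> int:
    """Free parameters in the structural part, net of indeterminacies.

    * CLPCA: ``S(N + R) - S^2`` (U V' invariant under any invertible S x S
      transformation);
    * CLRRR: ``S(P + R) - S^2``;
    * CLMDU: ``S(N + R) - S(S + 1)/2`` (distances invariant under joint
      translation and rotation);
    * CLRMDU: ``S(P + R) - S(S - 1)/2`` (rotation only; with no intercept in
      X a translation is not reachable through B).
    """
    model = model.lower()
    s, r = int(n_dims), int(n_responses)
    if model == "clpca":
        return s * (n_obs + r) - s * s
    if model == "clrrr":
        return s * (n_predictors + r) - s * s
    if model == "clmdu":
        return s * (n_obs + r) - s * (s + 1) // 2
    if model == "clrmdu":
        return s * (n_predictors + r) - s * (s - 1) // 2
    raise ValueError(f"unknown model {model!r}; expected one of {_FAMILIES}")


def count_parameters(
    model: str,
    n_dims: int,
    n_categories,
    n_obs=None,
    n_predictors=None,
) -> int:
    """Total free parameters: thresholds plus the structural part.

    ``n_dims = 0`` is the thresholds-only null model.  A rank-1 CLRRR with a
    single response is exactly the proportional-odds regression model
    (``S(P + 1) - S^2 = P`` slopes plus its cut-points).
    """
    n_categories = np.atleast_1d(np.asarray(n_categories))
    k = threshold_parameters(n_categories)
    if n_dims == 0:
        return k
    return k + structural_parameters(
        model, n_dims, n_categories.size, n_obs=n_obs, n_predictors=n_predictors
    )


def information_criteria(deviance: float, n_parameters: int, n_obs: int):
    """AIC = D + 2k, BIC = D + log(N) k on the deviance scale."""
    aic = deviance + 2.0 * n_parameters
    bic = deviance + np.log(n_obs) * n_parameters
    return float(aic), float(bic)


def select_dimension(
    y,
    x=None,
    model: str = "clpca",
    dims=(1, 2, 3),
    criterion: str = "aic",
    **fit_kwargs,
):
    """Fit a model at each candidate dimensionality and rank by criterion.

    Returns ``(best_results, report)`` where ``report`` is a tidy DataFrame
    with deviance, parameter count, AIC and BIC per dimensionality.
    """
    from .model import fit_model

    criterion = criterion.lower()
    rows, fits = [], {}
    for s in dims:
        res = fit_model(y, x, model=model, n_dims=int(s), **fit_kwargs)
        fits[int(s)] = res
        rows.append(
            {
                "model": model,
                "n_dims": int(s),
                "deviance": res.deviance,
                "n_parameters": res.n_parameters,
                "aic": res.aic,
                "bic": res.bic,
            }
        )
    report = pd.DataFrame(rows)
    best_s = int(report.loc[report[criterion].idxmin(), "n_dims"])
    return fits[best_s], report


def stepwise_selection(
    y,
    x,
    model: str = "clrrr",
    dims=(1, 2, 3),
    groups=None,
    criterion: str = "aic",
    predictor_names=None,
    **fit_kwargs,
):
    """Two-stage selection: dimensionality first, then backward elimination.

    Stage 1 fits all predictors at each candidate dimensionality and picks S
    by the chosen criterion.  Stage 2, at fixed S, repeatedly evaluates
    dropping each remaining predictor group (a group is a list of column
    indices of ``x``, e.g. the dummies of one categorical predictor) and
    removes the group whose removal improves the criterion most, until no
    removal improves it.  Every evaluated candidate is a row of the report.
    """
    from .model import fit_model

    x = np.asarray(x, dtype=float)
    criterion = criterion.lower()
    if predictor_names is None:
        predictor_names = [f"x{j + 1}" for j in range(x.shape[1])]
    if groups is None:
        groups = {name: [j] for j, name in enumerate(predictor_names)}

    _, dim_report = select_dimension(
        y, x, model=model, dims=dims, criterion=criterion, **fit_kwargs
    )
    best_s = int(dim_report.loc[dim_report[criterion].idxmin(), "n_dims"])

    kept = dict(groups)
    rows = []

    def _fit(cols, label, stage):
        res = fit_model(y, x[:, cols], model=model, n_dims=best_s, **fit_kwargs)
        rows.append(
            {
                "stage": stage,
                "candidate": label,
                "n_dims": best_s,
                "deviance": res.deviance,
                "n_parameters": res.n_parameters,
                "aic": res.aic,
                "bic": res.bic,
            }
        )
        return res

    all_cols = sorted(c for cols in kept.values() for c in cols)
    current = _fit(all_cols, "<full>", stage=0)
    current_score = getattr(current, criterion)
    stage = 1
    improved = True
    while improved and len(kept) > 1:
        improved = False
        candidates = {}
        for name in list(kept):
            cols = sorted(
                c for g, cc in kept.items() if g != name for c in cc
            )
            res = _fit(cols, f"-{name}", stage)
            candidates[name] = getattr(res, criterion)
        best_drop = min(candidates, key=candidates.get)
        if candidates[best_drop] <= current_score:
            kept.pop(best_drop)
            current_score = candidates[best_drop]
            improved = True
            stage += 1

    report = pd.DataFrame(rows)
    return {
        "n_dims": best_s,
        "dimension_report": dim_report,
        "report": report,
        "retained": sorted(kept),
        "criterion": criterion,
    }
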