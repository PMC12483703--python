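"""Data ingestion and analysis configuration.

Input is a single UTF-8, comma-delimited CSV with a header row.  Every
response column must be declared with an explicit category order (lowest to
highest); predictors are declared as numeric (standardized) or categorical
(dummy-coded against a declared reference).  All transformations are
recorded in a provenance log and in the predictor metadata, so biplots can
back-transform to the original scales.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .data import OrdinalDataset


@dataclass
class AnalysisConfig:
    """Declarative description of one analysis run."""

    data: str = ""
    #: response column -> ordered category labels (low to high)
    responses: dict = field(default_factory=dict)
    #: predictor column -> {"type": "numeric"} or
    #: {"type": "categorical", "reference": <label>}
    predictors: dict = field(default_factory=dict)
    model: str = "clpca"
    n_dims: int = 2
    dims_grid: list = field(default_factory=list)
    tol: float = 1e-6
    max_iter: int = 5000
    n_starts: int | None = None
    seed: int = 0
    out: str = "."

    def __post_init__(self):
        if self.responses and not all(
            isinstance(v, (list, tuple)) for v in self.responses.values()
        ):
            raise ValueError(
                "every response column must declare an explicit category order"
            )


def load_config(path) -> AnalysisConfig:
    """Read a YAML or JSON configuration file."""
    text = Path(path).read_text()
    doc = yaml.safe_load(text)
    return AnalysisConfig(**doc)


def encode_predictors(df: pd.DataFrame, predictors, references=None, log=None):
    """Standardize numeric and dummy-code categorical predictors.

    ``predictors`` is a list of column names or a dict
    ``name -> {"type": ..., "reference": ...}``.  Returns
    ``(X, column_names, meta)`` where ``meta`` maps each X column to its
    provenance (mean/sd for numerics; predictor/category/reference for
    dummies) so plots can invert the coding.
    """
    if isinstance(predictors, (list, tuple)):
        predictors = {
            name: {"type": "categorical" if df[name].dtype == object else "numeric"}
            for name in predictors
        }
    references = references or {}
    cols, names, meta = [], [], {}
    log = log if log is not None else []
    for name, spec in predictors.items():
        if name not in df.columns:
            raise ValueError(f"declared predictor column {name!r} not in data")
        kind = spec.get("type", "numeric")
        if kind == "numeric":
            vals = pd.to_numeric(df[name], errors="coerce")
            if vals.isna().any():
                row = int(vals.isna().idxmax())
                raise ValueError(
                    f"non-numeric value in numeric predictor {name!r} "
                    f"(row {row})"
                )
            mean, sd = float(vals.mean()), float(vals.std(ddof=0))
            if sd == 0:
                raise ValueError(f"predictor {name!r} is constant")
            cols.append(((vals - mean) / sd).to_numpy())
            names.append(name)
            meta[name] = {
                "type": "numeric",
                "mean": mean,
                "sd": sd,
                "min": float(((vals - mean) / sd).min()),
                "max": float(((vals - mean) / sd).max()),
            }
            log.append(f"standardized numeric predictor {name} "
                       f"(mean={mean:.4g}, sd={sd:.4g})")
        elif kind == "categorical":
            ref = spec.get("reference", references.get(name))
            levels = sorted(map(str, df[name].astype(str).unique()))
            if ref is None:
                ref = levels[0]
            ref = str(ref)
            if ref not in levels:
                raise ValueError(
                    f"reference {ref!r} not observed in predictor {name!r}"
                )
            for lev in levels:
                if lev == ref:
                    continue
                col = f"{name}[{lev}]"
                cols.append(
                    (df[name].astype(str) == lev).to_numpy(dtype=float)
                )
                names.append(col)
                meta[col] = {
                    "type": "categorical",
                    "predictor": name,
                    "category": lev,
                    "reference": ref,
                }
            log.append(
                f"dummy-coded categorical predictor {name} "
                f"(reference={ref})"
            )
        else:
            raise ValueError(f"unknown predictor type {kind!r} for {name!r}")
    x = np.column_stack(cols) if cols else None
    return x, names, meta


def read_tables(config: AnalysisConfig):
    """Load the CSV and produce the coded responses and predictor matrix.

    Returns ``(OrdinalDataset, X or None, predictor_names, meta, log)``.
    """
    path = Path(config.data)
    if not path.exists():
        raise FileNotFoundError(f"input table {path} does not exist")
    df = pd.read_csv(path)
    log = [f"read {len(df)} rows from {path}"]
    missing = [c for c in config.responses if c not in df.columns]
    if missing:
        raise ValueError(f"declared response columns missing from data: {missing}")
    orderings = {k: list(v) for k, v in config.responses.items()}
    y = OrdinalDataset.from_dataframe(df, list(config.responses), orderings)
    for col, order in orderings.items():
        log.append(f"coded response {col}: " +
                   ", ".join(f"{lab}->{k + 1}" for k, lab in enumerate(order)))
    x = names = meta = None
    if config.predictors:
        x, names, meta = encode_predictors(df, config.predictors, log=log)
    return y, x, names, meta, log


def write_results_json(results, path):
    results.to_json(path)


def read_results_json(path) -> dict:
    from .model import results_from_dict

    with open(path) as fh:
        return results_from_dict(json.load(fh))
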