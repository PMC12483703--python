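"""Ordinal response container.

Responses are stored as consecutive integer categories ``1..C_r``; the number
of categories may differ per response.  Arbitrary ordered labels are remapped
at the API boundary (see :mod:`ordmap.io`).
"""

from __future__ import annotations

import numpy as np
import pandas as pd


class OrdinalDataset:
    """An N x R matrix of ordinal responses coded 1..C_r.

    Parameters
    ----------
    y : array-like of int, shape (N, R)
        Observed categories.  Every entry of column ``r`` must lie in
        ``1..n_categories[r]``; missing values are not supported.
    n_categories : sequence of int, optional
        Categories per response.  Defaults to the per-column maximum.
    response_names : sequence of str, optional
    """

    def __init__(self, y, n_categories=None, response_names=None):
        y = np.asarray(y)
        if y.ndim == 1:
            y = y[:, None]
        if y.ndim != 2:
            raise ValueError("y must be a 2-d array of categories")
        if not np.issubdtype(y.dtype, np.integer):
            yf = np.asarray(y, dtype=float)
            if np.isnan(yf).any():
                raise ValueError("missing response cells are not supported")
            if not np.allclose(yf, np.round(yf)):
                raise ValueError("responses must be integer categories")
            y = yf.astype(int)
        self.y = np.ascontiguousarray(y, dtype=np.int64)
        n, r = self.y.shape
        if n_categories is None:
            n_categories = self.y.max(axis=0)
        self.n_categories = np.asarray(n_categories, dtype=np.int64)
        if self.n_categories.shape != (r,):
            raise ValueError("n_categories must have one entry per response")
        if (self.n_categories < 2).any():
            raise ValueError("each response needs at least 2 categories")
        low = self.y.min(axis=0)
        high = self.y.max(axis=0)
        if (low < 1).any() or (high > self.n_categories).any():
            bad = np.where((low < 1) | (high > self.n_categories))[0][0]
            raise ValueError(
                f"response column {bad} has categories outside "
                f"1..{self.n_categories[bad]}"
            )
        if response_names is None:
            response_names = [f"y{j + 1}" for j in range(r)]
        self.response_names = list(response_names)
        if len(self.response_names) != r:
            raise ValueError("response_names must match number of responses")

    @property
    def n_obs(self) -> int:
        return self.y.shape[0]

    @property
    def n_responses(self) -> int:
        return self.y.shape[1]

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, columns=None, orderings=None):
        """Build from a DataFrame, remapping ordered labels to 1..C.

        ``orderings`` maps column name -> list of category labels from lowest
        to highest.  Columns without an ordering must already be integers.
        """
        if columns is None:
            columns = list(df.columns)
        orderings = orderings or {}
        coded = np.empty((len(df), len(columns)), dtype=np.int64)
        n_cats = []
        for j, col in enumerate(columns):
            vals = df[col]
            if col in orderings:
                order = list(orderings[col])
                lut = {lab: k + 1 for k, lab in enumerate(order)}
                try:
                    coded[:, j] = [lut[v] for v in vals]
                except KeyError as exc:
                    raise ValueError(
                        f"undeclared category {exc.args[0]!r} in column {col!r}"
                    ) from None
                n_cats.append(len(order))
            else:
                coded[:, j] = np.asarray(vals, dtype=np.int64)
                n_cats.append(int(coded[:, j].max()))
        return cls(coded, n_categories=n_cats, response_names=columns)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.y, columns=self.response_names)

    def __repr__(self):
        return (
            f"OrdinalDataset(n_obs={self.n_obs}, "
            f"n_responses={self.n_responses}, "
            f"n_categories={self.n_categories.tolist()})"
        )
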