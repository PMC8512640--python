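"""Containers and delimited-text IO for positive series with regressors."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["SeriesData", "read_series_csv"]


@dataclass
class SeriesData:
    """A strictly positive response series with an aligned regressor matrix.

    ``X`` has shape (n, r); r may be 0.  ``names`` labels the regressor
    columns (defaults to x1..xr).
    """

    y: np.ndarray
    X: np.ndarray
    names: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim == 1:
            self.X = self.X[:, None]
        if self.X.size == 0:
            self.X = np.empty((self.y.shape[0], 0))
        if self.y.ndim != 1:
            raise ValueError("y must be one-dimensional")
        if self.X.shape[0] != self.y.shape[0]:
            raise ValueError(
                f"X has {self.X.shape[0]} rows but y has {self.y.shape[0]}"
            )
        if np.any(~np.isfinite(self.y)) or np.any(~np.isfinite(self.X)):
            raise ValueError("missing or non-finite values are not supported")
        bad = np.nonzero(self.y <= 0)[0]
        if bad.size:
            raise ValueError(f"response must be strictly positive; first bad row: {bad[0] + 1}")
        if not self.names:
            self.names = [f"x{i + 1}" for i in range(self.X.shape[1])]

    @property
    def n(self) -> int:
        return self.y.shape[0]

    @property
    def r(self) -> int:
        return self.X.shape[1]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"t": np.arange(1, self.n + 1), "y": self.y})
        for j, name in enumerate(self.names):
            df[name] = self.X[:, j]
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def read_series_csv(path, response: str = "y", regressors=None) -> SeriesData:
    """Read a SeriesData from a delimited text file with a header row.

    ``regressors`` lists the regressor columns in their model order; by
    default every numeric column other than the response and any ``t``
    index column is used, in file order.
    """
    df = pd.read_csv(path)
    if response not in df.columns:
        raise ValueError(f"column {response!r} not found in {path}")
    if regressors is None:
        regressors = [c for c in df.columns if c not in (response, "t")]
    missing = [c for c in regressors if c not in df.columns]
    if missing:
        raise ValueError(f"regressor column(s) {missing} not found in {path}")
    for col in [response, *regressors]:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = np.nonzero(vals.isna().to_numpy())[0]
        if bad.size:
            raise ValueError(f"non-numeric value in column {col!r} at row {bad[0] + 1}")
        df[col] = vals
    return SeriesData(
        y=df[response].to_numpy(float),
        X=df[list(regressors)].to_numpy(float).reshape(len(df), -1),
        names=list(regressors),
    )
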