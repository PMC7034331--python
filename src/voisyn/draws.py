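"""Containers for Monte Carlo posterior draws.

A :class:`DrawsTable` holds K joint posterior draws of named scalar
quantities — founder parameters, derived model outputs, and simulated
summary statistics of future data — as a rectangular table.  It is a thin,
validated wrapper around a :class:`pandas.DataFrame` so that every
downstream estimator can rely on a common contract: no missing values,
unique column names, and a configurable minimum number of draws for
estimation entry points.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: Default minimum number of draws required by estimation entry points.
DEFAULT_MIN_DRAWS = 1000


@dataclass
class DrawsTable:
    """K posterior draws of M named quantities.

    Parameters
    ----------
    data : pandas.DataFrame
        Rows are draws, columns are named quantities.  Values must be
        finite reals.
    """

    data: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        if not isinstance(self.data, pd.DataFrame):
            self.data = pd.DataFrame(self.data)
        if self.data.shape[0] < 1:
            raise ValueError("DrawsTable requires at least one draw")
        if self.data.columns.duplicated().any():
            dupes = self.data.columns[self.data.columns.duplicated()].tolist()
            raise ValueError(f"duplicate column labels: {dupes}")
        values = self.data.to_numpy(dtype=float)
        if not np.isfinite(values).all():
            bad = self.data.columns[~np.isfinite(values).all(axis=0)].tolist()
            raise ValueError(f"non-finite values in columns: {bad}")

    # -- basic accessors -------------------------------------------------

    @property
    def K(self) -> int:
        """Number of draws."""
        return self.data.shape[0]

    @property
    def names(self) -> list[str]:
        return [str(c) for c in self.data.columns]

    def column(self, name: str) -> np.ndarray:
        self._check_columns([name])
        return self.data[name].to_numpy(dtype=float)

    def matrix(self, names: Sequence[str]) -> np.ndarray:
        """K x len(names) array of the requested columns."""
        self._check_columns(names)
        return self.data.loc[:, list(names)].to_numpy(dtype=float)

    def _check_columns(self, names: Iterable[str]) -> None:
        missing = [n for n in names if n not in self.data.columns]
        if missing:
            raise KeyError(f"unknown draw columns: {missing}")

    def require_min_draws(self, floor: int = DEFAULT_MIN_DRAWS) -> None:
        if self.K < floor:
            raise ValueError(
                f"estimation requires at least {floor} draws, got {self.K}; "
                "lower the floor explicitly if this is intentional"
            )

    def with_columns(self, **columns: np.ndarray) -> "DrawsTable":
        """Return a new table with extra (or replaced) columns."""
        df = self.data.copy()
        for name, values in columns.items():
            values = np.asarray(values, dtype=float)
            if values.shape != (self.K,):
                raise ValueError(f"column {name!r} must have shape ({self.K},)")
            df[name] = values
        return DrawsTable(df)

    def subsample(self, k: int, seed: int | np.random.Generator = 0) -> "DrawsTable":
        """Random subsample of k draws without replacement."""
        if k > self.K:
            raise ValueError(f"cannot subsample {k} from {self.K} draws")
        rng = np.random.default_rng(seed)
        idx = rng.choice(self.K, size=k, replace=False)
        idx.sort()
        return DrawsTable(self.data.iloc[idx].reset_index(drop=True))

    # -- I/O -------------------------------------------------------------

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "DrawsTable":
        return cls(pd.read_csv(path))
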