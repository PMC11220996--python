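"""Area x year panel container for count data with population offsets."""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property
from typing import Sequence

import numpy as np
import pandas as pd

from .graphs import SpatialGraph

__all__ = ["PanelData", "PanelError"]


class PanelError(ValueError):
    """Malformed or incomplete panel."""


@dataclass
class PanelData:
    """Complete (area x year) grid of counts, populations and covariates.

    Arrays are area-major: ``y[i, t]`` is the count for ``area_ids[i]`` in
    ``years[t]``; the covariate matrix ``X`` has one row per cell in the
    same order (``row = i * T + t``) and excludes the intercept column
    (added at fit time when the model requests one).  Populations (and
    hence counts) are recorded in millions of persons.
    """

    area_ids: tuple
    years: tuple
    y: np.ndarray          # (n, T) non-negative integers
    population: np.ndarray  # (n, T) positive, millions
    X: np.ndarray          # (n*T, p)
    covariate_names: tuple = ()
    graph: SpatialGraph | None = None

    def __post_init__(self) -> None:
        self.area_ids = tuple(self.area_ids)
        self.years = tuple(self.years)
        self.y = np.asarray(self.y)
        self.population = np.asarray(self.population, dtype=float)
        self.X = np.asarray(self.X, dtype=float)
        n, T = len(self.area_ids), len(self.years)
        if self.y.shape != (n, T):
            raise PanelError(f"counts have shape {self.y.shape}, expected {(n, T)}")
        if self.population.shape != (n, T):
            raise PanelError(
                f"populations have shape {self.population.shape}, expected {(n, T)}"
            )
        if self.X.ndim != 2 or self.X.shape[0] != n * T:
            raise PanelError(
                f"covariates have shape {self.X.shape}, expected ({n * T}, p)"
            )
        if not self.covariate_names:
            self.covariate_names = tuple(
                f"PC{k + 1}" for k in range(self.X.shape[1])
            )
        self.covariate_names = tuple(self.covariate_names)
        if len(self.covariate_names) != self.X.shape[1]:
            raise PanelError("covariate name count does not match X columns")
        if np.any(self.y < 0):
            raise PanelError("counts must be non-negative")
        if np.any(self.population <= 0):
            raise PanelError("populations must be positive")
        if self.graph is not None and self.graph.area_ids != self.area_ids:
            raise PanelError("graph area ids do not match panel area ids")

    # -- dimensions ----------------------------------------------------
    @property
    def n_areas(self) -> int:
        return len(self.area_ids)

    @property
    def n_times(self) -> int:
        return len(self.years)

    @property
    def n_cells(self) -> int:
        return self.n_areas * self.n_times

    @property
    def n_covariates(self) -> int:
        return self.X.shape[1]

    @cached_property
    def log_offset(self) -> np.ndarray:
        """log population, shape (n, T)."""
        return np.log(self.population)

    # -- conversion ----------------------------------------------------
    def to_dataframe(self) -> pd.DataFrame:
        n, T = self.n_areas, self.n_times
        df = pd.DataFrame(
            {
                "area_id": np.repeat(self.area_ids, T),
                "year": np.tile(self.years, n),
                "count": self.y.reshape(-1),
                "population": self.population.reshape(-1),
            }
        )
        for k, name in enumerate(self.covariate_names):
            df[name] = self.X[:, k]
        return df

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, graph: SpatialGraph | None = None,
        area_ids: Sequence | None = None,
    ) -> "PanelData":
        required = {"area_id", "year", "count", "population"}
        missing = required - set(df.columns)
        if missing:
            raise PanelError(f"panel is missing column(s): {sorted(missing)}")
        if area_ids is None:
            area_ids = (
                tuple(graph.area_ids) if graph is not None
                else tuple(pd.unique(df["area_id"]))
            )
        years = tuple(np.asarray(sorted(pd.unique(df["year"]))).tolist())
        n, T = len(area_ids), len(years)
        if len(df) != n * T or df.duplicated(["area_id", "year"]).any():
            raise PanelError(
                f"panel is not a complete area x year grid: {len(df)} rows, "
                f"expected {n} areas x {T} years = {n * T}"
            )
        extra = set(df["area_id"]) - set(area_ids)
        if extra:
            raise PanelError(f"panel has unknown area id(s): {sorted(extra)[:5]}")
        cov_names = [c for c in df.columns if c not in required]
        a_idx = df["area_id"].map({a: i for i, a in enumerate(area_ids)}).to_numpy()
        t_idx = df["year"].map({yr: t for t, yr in enumerate(years)}).to_numpy()
        flat = a_idx * T + t_idx
        order = np.argsort(flat)
        dfo = df.iloc[order]
        return cls(
            area_ids=tuple(area_ids),
            years=years,
            y=dfo["count"].to_numpy().reshape(n, T),
            population=dfo["population"].to_numpy(dtype=float).reshape(n, T),
            X=dfo[cov_names].to_numpy(dtype=float) if cov_names else np.empty((n * T, 0)),
            covariate_names=tuple(cov_names),
            graph=graph,
        )

    def with_covariates(self, X: np.ndarray, names: Sequence[str]) -> "PanelData":
        """Return a copy with a replaced covariate matrix."""
        return PanelData(
            self.area_ids, self.years, self.y, self.population,
            X, tuple(names), self.graph,
        )
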