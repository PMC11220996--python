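"""Correlation-matrix PCA turning a wide indicator table into model covariates.

Food-security indicator tables mix units (kcal/capita, percentages, index
values), so components are extracted from the correlation matrix, i.e. PCA
on standardised indicators.  The component count is fixed by configuration
(ten in the reference pipeline); a Kaiser-rule helper is provided but not
applied automatically.  Eigenvector signs are pinned so that the
largest-magnitude loading of each component is positive, making loadings
reproducible across platforms.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["ComponentModel", "fit_components", "transform", "kaiser_rule"]

KEY_COLUMNS = ("area_id", "year")


def _indicator_matrix(table: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    cols = [c for c in table.columns if c not in KEY_COLUMNS]
    X = table[cols].to_numpy(dtype=float)
    if np.isnan(X).any():
        bad = [c for c in cols if table[c].isna().any()]
        raise ValueError(f"missing values in indicator column(s): {bad[:5]}")
    return X, cols


@dataclass
class ComponentModel:
    """Fitted PCA rotation: standardisation constants plus loadings.

    ``loadings`` holds all ``p`` orthonormal eigenvectors (columns, ordered
    by decreasing eigenvalue); ``variance_ratio`` the corresponding
    fractions of total variance (non-increasing, summing to 1);
    ``n_keep`` how many components the transform emits.
    """

    columns: tuple
    means: np.ndarray
    sds: np.ndarray
    loadings: np.ndarray       # (p, p), orthonormal columns
    eigenvalues: np.ndarray    # (p,), descending
    n_keep: int

    @property
    def variance_ratio(self) -> np.ndarray:
        return self.eigenvalues / self.eigenvalues.sum()

    def explained(self, k: int | None = None) -> float:
        """Cumulative variance fraction of the first k (default n_keep) components."""
        k = self.n_keep if k is None else k
        return float(self.variance_ratio[:k].sum())

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "columns": list(self.columns),
                    "means": self.means.tolist(),
                    "sds": self.sds.tolist(),
                    "loadings": self.loadings.tolist(),
                    "eigenvalues": self.eigenvalues.tolist(),
                    "n_keep": self.n_keep,
                },
                fh,
            )

    @classmethod
    def from_json(cls, path) -> "ComponentModel":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            columns=tuple(d["columns"]),
            means=np.asarray(d["means"]),
            sds=np.asarray(d["sds"]),
            loadings=np.asarray(d["loadings"]),
            eigenvalues=np.asarray(d["eigenvalues"]),
            n_keep=int(d["n_keep"]),
        )

    def loadings_table(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.loadings[:, : self.n_keep],
            index=list(self.columns),
            columns=[f"PC{k + 1}" for k in range(self.n_keep)],
        )
        df.index.name = "indicator"
        return df

    def variance_table(self) -> pd.DataFrame:
        p = len(self.eigenvalues)
        return pd.DataFrame(
            {
                "component": [f"PC{k + 1}" for k in range(p)],
                "eigenvalue": self.eigenvalues,
                "variance_fraction": self.variance_ratio,
                "cumulative_fraction": np.cumsum(self.variance_ratio),
            }
        )


def fit_components(table: pd.DataFrame, n_keep: int) -> ComponentModel:
    """Eigendecomposition of the indicator correlation matrix.

    Key columns (``area_id``, ``year``) are ignored; every other column is
    treated as an indicator.  Constant columns and missing values are
    errors.
    """
    X, cols = _indicator_matrix(table)
    if X.shape[0] < 2:
        raise ValueError("need at least two rows to fit components")
    if not 1 <= n_keep <= X.shape[1]:
        raise ValueError(f"n_keep must be in [1, {X.shape[1]}], got {n_keep}")
    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=1)
    if np.any(sds == 0):
        bad = [c for c, s in zip(cols, sds) if s == 0]
        raise ValueError(f"constant indicator column(s): {bad[:5]}")
    Z = (X - means) / sds
    corr = (Z.T @ Z) / (X.shape[0] - 1)
    eigvals, eigvecs = np.linalg.eigh(corr)
    order = np.argsort(eigvals)[::-1]
    eigvals = np.clip(eigvals[order], 0.0, None)
    eigvecs = eigvecs[:, order]
    # pin signs: largest-magnitude loading of each component positive
    for k in range(eigvecs.shape[1]):
        j = np.argmax(np.abs(eigvecs[:, k]))
        if eigvecs[j, k] < 0:
            eigvecs[:, k] = -eigvecs[:, k]
    return ComponentModel(
        columns=tuple(cols), means=means, sds=sds,
        loadings=eigvecs, eigenvalues=eigvals, n_keep=int(n_keep),
    )


def transform(model: ComponentModel, table: pd.DataFrame) -> np.ndarray:
    """Component scores of ``table`` under a fitted model, (rows, n_keep)."""
    X, cols = _indicator_matrix(table)
    if tuple(cols) != model.columns:
        raise ValueError(
            "indicator columns do not match the fitted model "
            f"(got {cols[:3]}..., fitted on {list(model.columns[:3])}...)"
        )
    Z = (X - model.means) / model.sds
    return Z @ model.loadings[:, : model.n_keep]


def kaiser_rule(model: ComponentModel) -> int:
    """Number of components with eigenvalue > 1 (helper, not the default rule)."""
    return int(np.sum(model.eigenvalues > 1.0))
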