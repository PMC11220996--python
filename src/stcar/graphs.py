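"""Spatial and temporal neighbourhood structures and CAR primitives.

Areal space-time models describe a quantity observed on a fixed set of
regions (countries, districts) over consecutive time points.  Spatial
dependence enters through a symmetric binary adjacency matrix ``W``
(``w_ij = 1`` when areas *i* and *j* share a border) and the Leroux
conditional-autoregressive (CAR) prior, whose precision matrix

.. math::

    Q(W, \\rho) = \\rho (W_d - W) + (1 - \\rho) I

interpolates between independence (``rho = 0``, :math:`Q = I`) and the
intrinsic CAR (``rho = 1``, singular :math:`Q`).  ``W_d`` is the diagonal
matrix of neighbour counts.  Temporal dependence uses the same machinery on
the path graph over time points (``z_ij = 1`` iff ``|i - j| = 1``).

This module owns every CAR primitive used by the model and sampling code:
graph construction and validation, the Leroux precision with its
eigenvalue-based log-determinant, the univariate CAR full conditional, exact
multivariate CAR draws, and Moran's I for checking spatial autocorrelation.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from functools import cached_property
from typing import Iterable, Sequence

import networkx as nx
import numpy as np

__all__ = [
    "SpatialGraph",
    "TemporalGraph",
    "LerouxPrecision",
    "build_graph",
    "lattice_graph",
    "random_geometric_graph",
    "leroux_precision",
    "leroux_logdet",
    "car_logpdf",
    "car_full_conditional",
    "simulate_car",
    "morans_i",
]


class GraphError(ValueError):
    """Invalid neighbourhood structure or graph/data mismatch."""


class _Adjacency:
    """Shared behaviour for symmetric binary adjacency structures.

    Subclasses must provide ``W`` (dense 0/1 symmetric, zero diagonal) and
    ``labels``.  Degrees, the CAR structure matrix ``W_d - W``, its
    eigenvalues, and a greedy vertex colouring (used for parallel
    single-site updates) are derived lazily and cached.
    """

    W: np.ndarray

    def _validate(self) -> None:
        W = self.W
        if W.ndim != 2 or W.shape[0] != W.shape[1]:
            raise GraphError(f"adjacency must be square, got shape {W.shape}")
        if not np.array_equal(W, W.T):
            raise GraphError("adjacency matrix must be symmetric")
        if np.any(np.diag(W) != 0):
            raise GraphError("adjacency diagonal must be zero (no self-edges)")
        if not np.isin(W, (0.0, 1.0)).all():
            raise GraphError("adjacency entries must be 0 or 1")

    @property
    def n_nodes(self) -> int:
        return self.W.shape[0]

    @cached_property
    def degrees(self) -> np.ndarray:
        """Neighbour count per node, d_i = sum_j w_ij."""
        return self.W.sum(axis=1)

    @cached_property
    def islands(self) -> np.ndarray:
        """Indices of degree-zero nodes."""
        return np.flatnonzero(self.degrees == 0)

    @cached_property
    def structure(self) -> np.ndarray:
        """CAR structure matrix W_d - W (the graph Laplacian)."""
        return np.diag(self.degrees) - self.W

    @cached_property
    def eigenvalues(self) -> np.ndarray:
        """Eigenvalues of W_d - W, ascending.  All >= 0; smallest is 0."""
        return np.linalg.eigvalsh(self.structure)

    @cached_property
    def coloring(self) -> list[np.ndarray]:
        """Partition of nodes into independent sets (greedy colouring).

        Nodes sharing a colour are pairwise non-adjacent, so their CAR full
        conditionals given the rest are mutually independent and can be
        Metropolis-updated simultaneously.
        """
        g = nx.from_numpy_array(self.W)
        colors = nx.greedy_color(g, strategy="largest_first")
        k = max(colors.values(), default=0) + 1
        return [
            np.array(sorted(i for i, c in colors.items() if c == ci), dtype=int)
            for ci in range(k)
        ]

    @property
    def edges(self) -> list[tuple[int, int]]:
        i, j = np.nonzero(np.triu(self.W))
        return list(zip(i.tolist(), j.tolist()))


@dataclass(frozen=True)
class SpatialGraph(_Adjacency):
    """Symmetric binary spatial adjacency among labelled areas.

    Parameters
    ----------
    area_ids : tuple of str
        Ordered area labels; row/column *k* of ``W`` corresponds to
        ``area_ids[k]``.
    W : ndarray of shape (n, n)
        0/1 symmetric adjacency with zero diagonal.
    """

    area_ids: tuple
    W: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "area_ids", tuple(self.area_ids))
        W = np.asarray(self.W, dtype=float)
        object.__setattr__(self, "W", W)
        if len(self.area_ids) != W.shape[0]:
            raise GraphError(
                f"{len(self.area_ids)} area ids but adjacency of shape {W.shape}"
            )
        if len(set(self.area_ids)) != len(self.area_ids):
            raise GraphError("duplicate area ids")
        self._validate()
        if self.islands.size:
            names = [self.area_ids[i] for i in self.islands]
            warnings.warn(
                f"graph has {len(names)} island area(s) with no neighbours: {names}",
                stacklevel=2,
            )

    @property
    def n_areas(self) -> int:
        return self.n_nodes

    def index(self, area_id) -> int:
        return self.area_ids.index(area_id)

    # -- serialization -------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "area_ids": list(self.area_ids),
            "edges": [[self.area_ids[i], self.area_ids[j]] for i, j in self.edges],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SpatialGraph":
        return build_graph(d["edges"], d["area_ids"])

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "SpatialGraph":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass(frozen=True)
class TemporalGraph(_Adjacency):
    """Path-graph adjacency over T consecutive time points (z_ij = 1 iff |i-j| = 1)."""

    n_times: int
    W: np.ndarray = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.n_times < 1:
            raise GraphError("need at least one time point")
        Z = np.zeros((self.n_times, self.n_times))
        idx = np.arange(self.n_times - 1)
        Z[idx, idx + 1] = 1.0
        Z[idx + 1, idx] = 1.0
        object.__setattr__(self, "W", Z)

    @property
    def Z(self) -> np.ndarray:
        return self.W


# ---------------------------------------------------------------------------
# constructors
# ---------------------------------------------------------------------------

def build_graph(edge_list: Iterable[Sequence], area_ids: Sequence) -> SpatialGraph:
    """Build a :class:`SpatialGraph` from an edge list.

    Edges are undirected: ``(a, b)`` and ``(b, a)`` denote the same border
    and duplicates are collapsed with a warning.  Self-edges and unknown
    area ids are errors.
    """
    area_ids = list(area_ids)
    pos = {a: k for k, a in enumerate(area_ids)}
    if len(pos) != len(area_ids):
        raise GraphError("duplicate area ids")
    n = len(area_ids)
    W = np.zeros((n, n))
    dupes = 0
    for edge in edge_list:
        a, b = edge[0], edge[1]
        if a not in pos or b not in pos:
            missing = a if a not in pos else b
            raise GraphError(f"edge endpoint {missing!r} is not a known area id")
        if a == b:
            raise GraphError(f"self-edge on area {a!r}")
        i, j = pos[a], pos[b]
        if W[i, j]:
            dupes += 1
        W[i, j] = W[j, i] = 1.0
    if dupes:
        warnings.warn(f"{dupes} duplicate edge(s) collapsed", stacklevel=2)
    with warnings.catch_warnings():
        # island warnings are expected for deliberately empty graphs; still
        # surface them to the caller
        return SpatialGraph(tuple(area_ids), W)


def lattice_graph(n_areas: int, area_ids: Sequence | None = None) -> SpatialGraph:
    """Rook-adjacency lattice with ``n_areas`` nodes.

    A near-square grid is built and trimmed (row-major) to exactly
    ``n_areas`` nodes; the result stays connected.  This is the default
    deterministic stand-in for a real contiguity matrix in synthetic runs.
    """
    if n_areas < 1:
        raise GraphError("n_areas must be positive")
    ncols = int(np.ceil(np.sqrt(n_areas)))
    nrows = int(np.ceil(n_areas / ncols))
    if area_ids is None:
        width = len(str(n_areas))
        area_ids = [f"A{k:0{width}d}" for k in range(1, n_areas + 1)]
    W = np.zeros((n_areas, n_areas))
    for k in range(n_areas):
        r, c = divmod(k, ncols)
        for rr, cc in ((r, c + 1), (r + 1, c)):
            kk = rr * ncols + cc
            if rr < nrows and cc < ncols and kk < n_areas:
                W[k, kk] = W[kk, k] = 1.0
    return SpatialGraph(tuple(area_ids), W)


def random_geometric_graph(
    n_areas: int, radius: float = 0.25, seed: int | None = None,
    area_ids: Sequence | None = None,
) -> SpatialGraph:
    """Seeded random geometric graph on the unit square (alternative stand-in)."""
    g = nx.random_geometric_graph(n_areas, radius, seed=seed)
    W = nx.to_numpy_array(g)
    if area_ids is None:
        width = len(str(n_areas))
        area_ids = [f"A{k:0{width}d}" for k in range(1, n_areas + 1)]
    return SpatialGraph(tuple(area_ids), W)


# ---------------------------------------------------------------------------
# Leroux precision
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LerouxPrecision:
    """Leroux CAR precision Q(W, rho) = rho (W_d - W) + (1 - rho) I.

    Holds the source graph, the dependence parameter and the dense precision
    matrix, plus the precomputed eigenvalues ``lambda_k`` of ``W_d - W`` so
    that ``log det Q = sum_k log(rho * lambda_k + 1 - rho)`` is O(n) for any
    rho.
    """

    graph: _Adjacency
    rho: float
    Q: np.ndarray = field(repr=False)
    eigenvalues: np.ndarray = field(repr=False)

    @property
    def logdet(self) -> float:
        return leroux_logdet(self.eigenvalues, self.rho)

    @cached_property
    def cholesky(self) -> np.ndarray:
        return np.linalg.cholesky(self.Q)

    def logpdf(self, u: np.ndarray, tau2: float) -> float:
        """Log-density of u ~ N(0, tau2 * Q^{-1})."""
        return car_quad_logpdf(
            float(u @ self.Q @ u), self.logdet, len(u), tau2
        )


def leroux_precision(graph: _Adjacency, rho: float) -> LerouxPrecision:
    """Construct the Leroux precision for a graph at dependence ``rho``.

    ``rho`` must lie in [0, 1].  At ``rho = 1`` the matrix is the (singular)
    intrinsic-CAR precision; density evaluation there raises from
    :func:`leroux_logdet`.
    """
    if not 0.0 <= rho <= 1.0:
        raise ValueError(f"rho must lie in [0, 1], got {rho}")
    n = graph.n_nodes
    Q = rho * graph.structure + (1.0 - rho) * np.eye(n)
    return LerouxPrecision(graph, float(rho), Q, graph.eigenvalues)


def leroux_logdet(eigenvalues: np.ndarray, rho: float) -> float:
    """log det Q(W, rho) from the eigenvalues of W_d - W."""
    vals = rho * eigenvalues + (1.0 - rho)
    if np.any(vals <= 0.0):
        raise ValueError(
            "Q(W, rho) is singular (intrinsic limit rho = 1); "
            "its density is improper and cannot be evaluated"
        )
    return float(np.sum(np.log(vals)))


def car_quad_logpdf(quad: float, logdet: float, m: int, tau2: float) -> float:
    """N(0, tau2 Q^{-1}) log-density given the quadratic form u'Qu."""
    if tau2 <= 0:
        raise ValueError("tau2 must be positive")
    return -0.5 * m * np.log(2.0 * np.pi * tau2) + 0.5 * logdet - 0.5 * quad / tau2


def car_logpdf(u: np.ndarray, graph: _Adjacency, rho: float, tau2: float) -> float:
    """Log-density of ``u`` under the Leroux CAR prior CAR(rho, tau2, W)."""
    prec = leroux_precision(graph, rho)
    return prec.logpdf(np.asarray(u, dtype=float), tau2)


def car_full_conditional(
    phi: np.ndarray, i: int, rho: float, tau2: float, graph: _Adjacency
) -> tuple[float, float]:
    """Gaussian full conditional of one CAR coordinate given the rest.

    Returns ``(mean, variance)`` with

    .. math::

        \\mathrm{mean} = \\frac{\\rho \\sum_j w_{ij} \\phi_j}
                              {\\rho d_i + 1 - \\rho},
        \\qquad
        \\mathrm{var} = \\frac{\\tau^2}{\\rho d_i + 1 - \\rho}.

    At ``rho = 1`` this is the intrinsic-CAR conditional (neighbour mean,
    variance tau2 / d_i), defined only for areas with at least one
    neighbour.
    """
    if tau2 <= 0:
        raise ValueError("tau2 must be positive")
    if not 0.0 <= rho <= 1.0:
        raise ValueError(f"rho must lie in [0, 1], got {rho}")
    d_i = graph.degrees[i]
    denom = rho * d_i + 1.0 - rho
    if denom <= 0.0:
        raise ValueError(
            f"node {i} is isolated and rho = 1: full conditional is undefined"
        )
    nbr_sum = float(graph.W[i] @ np.asarray(phi, dtype=float))
    return rho * nbr_sum / denom, tau2 / denom


def simulate_car(
    graph: _Adjacency,
    rho: float,
    tau2: float,
    seed=None,
    size: int = 1,
    center: bool = True,
) -> np.ndarray:
    """Draw from the multivariate CAR prior N(0, tau2 Q(W, rho)^{-1}).

    Uses a Cholesky factor of the precision: with ``Q = L L'`` and
    ``z ~ N(0, I)``, solving ``L' x = z`` gives ``x ~ N(0, Q^{-1})``.
    Requires ``rho < 1`` (proper prior).  When ``center`` is true each draw
    is shifted to sum to zero, matching the identifiability convention used
    at fitting time.

    Returns an array of shape ``(n,)`` when ``size == 1``, else
    ``(size, n)``.
    """
    if not 0.0 <= rho < 1.0:
        raise ValueError("simulate_car requires rho in [0, 1)")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    prec = leroux_precision(graph, rho)
    L = prec.cholesky
    assert np.all(np.diag(L) > 0.0), "Leroux precision must be positive definite"
    z = rng.standard_normal((graph.n_nodes, size))
    x = np.linalg.solve(L.T, z) * np.sqrt(tau2)
    if center:
        x -= x.mean(axis=0, keepdims=True)
    out = x.T
    return out[0] if size == 1 else out


# ---------------------------------------------------------------------------
# Moran's I
# ---------------------------------------------------------------------------

def morans_i(values: np.ndarray, graph: _Adjacency) -> float:
    """Global Moran's I with raw binary weights.

    .. math::

        I = \\frac{n}{S_0}
            \\frac{\\sum_{ij} w_{ij} (x_i - \\bar x)(x_j - \\bar x)}
                 {\\sum_i (x_i - \\bar x)^2},
        \\qquad S_0 = \\sum_{ij} w_{ij}.

    Values near +1 indicate clustering of similar values among neighbours,
    values near -1 indicate local dispersion.  No row standardisation is
    applied.
    """
    x = np.asarray(values, dtype=float)
    if x.shape != (graph.n_nodes,):
        raise ValueError(
            f"need one value per node: got {x.shape}, graph has {graph.n_nodes}"
        )
    s0 = graph.W.sum()
    if s0 == 0:
        raise GraphError("graph has no edges: Moran's I undefined")
    xc = x - x.mean()
    denom = float(xc @ xc)
    if denom == 0.0:
        raise ValueError("constant input: Moran's I undefined")
    cross = float(xc @ graph.W @ xc)
    return (graph.n_nodes / s0) * cross / denom
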