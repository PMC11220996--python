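"""Readers and writers: panels (CSV), adjacency (edge list / GAL / JSON), YAML configs."""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
import yaml

from .graphs import SpatialGraph, build_graph
from .panel import PanelData, PanelError

__all__ = [
    "read_panel_csv",
    "write_panel_csv",
    "read_edge_list",
    "write_edge_list",
    "read_gal",
    "read_adjacency",
    "read_yaml",
    "write_json",
]


def read_panel_csv(path, graph: SpatialGraph | None = None) -> PanelData:
    """Read a long-format panel CSV (area_id, year, count, population, covariates...)."""
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise PanelError(f"cannot parse panel CSV {path}: {exc}") from exc
    return PanelData.from_dataframe(df, graph=graph)


def write_panel_csv(panel: PanelData, path) -> None:
    panel.to_dataframe().to_csv(path, index=False)


def read_edge_list(path, area_ids=None) -> SpatialGraph:
    """Two-column text/CSV edge list of area-id pairs; header optional.

    Area ids default to the sorted distinct endpoints.  A first line whose
    tokens look like column labels (``from,to`` / ``source,target`` /
    ``area_i,area_j``) is skipped.
    """
    header_tokens = {"from", "to", "source", "target", "area_i", "area_j"}
    edges = []
    with open(path) as fh:
        for lineno, line in enumerate(fh):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = [p.strip() for p in line.replace(",", " ").split()]
            if len(parts) != 2:
                raise PanelError(
                    f"{path}:{lineno + 1}: expected two columns, got {len(parts)}"
                )
            if lineno == 0 and all(p.lower() in header_tokens for p in parts):
                continue
            edges.append(tuple(parts))
    if area_ids is None:
        area_ids = sorted({a for e in edges for a in e})
    return build_graph(edges, area_ids)


def write_edge_list(graph: SpatialGraph, path) -> None:
    with open(path, "w") as fh:
        fh.write("from,to\n")
        for i, j in graph.edges:
            fh.write(f"{graph.area_ids[i]},{graph.area_ids[j]}\n")


def read_gal(path, area_ids=None) -> SpatialGraph:
    """GAL-style neighbour file: a count line, then per-area neighbour lists.

    Entries are 1-based positional indices (or literal area ids) mapped onto
    the ordered area list; 0-based indexing is used everywhere internally.
    """
    with open(path) as fh:
        tokens = fh.read().split()
    if not tokens:
        raise PanelError(f"{path}: empty GAL file")
    # header may be "n" or the 4-field variant "0 n file key"; take the count
    try:
        if len(tokens) >= 4 and tokens[0] == "0":
            n = int(tokens[1])
            pos = 4
        else:
            n = int(tokens[0])
            pos = 1
    except ValueError as exc:
        raise PanelError(f"{path}: malformed GAL header") from exc
    if area_ids is None:
        area_ids = [str(k) for k in range(1, n + 1)]
    if len(area_ids) != n:
        raise PanelError(
            f"{path}: GAL header says {n} areas but {len(area_ids)} ids supplied"
        )
    id_set = set(area_ids)

    def to_id(token):
        if token in id_set:
            return token
        try:
            k = int(token)
        except ValueError:
            raise PanelError(f"{path}: unknown area {token!r}") from None
        if not 1 <= k <= n:
            raise PanelError(f"{path}: 1-based index {k} out of range")
        return area_ids[k - 1]

    edges = []
    for _ in range(n):
        if pos + 1 > len(tokens):
            raise PanelError(f"{path}: truncated GAL file")
        a = to_id(tokens[pos])
        deg = int(tokens[pos + 1])
        pos += 2
        nbrs = tokens[pos:pos + deg]
        if len(nbrs) != deg:
            raise PanelError(f"{path}: truncated neighbour list for {a}")
        pos += deg
        for b in nbrs:
            b = to_id(b)
            if (b, a) not in edges:   # GAL lists each edge twice
                edges.append((a, b))
    return build_graph(edges, area_ids)


def read_adjacency(path, area_ids=None) -> SpatialGraph:
    """Dispatch on extension: .json, .gal, else edge list."""
    suffix = Path(path).suffix.lower()
    if suffix == ".json":
        return SpatialGraph.from_json(path)
    if suffix == ".gal":
        return read_gal(path, area_ids)
    return read_edge_list(path, area_ids)


def read_yaml(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1)
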