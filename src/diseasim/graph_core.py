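"""Loading and cleaning of protein-protein interaction (PPI) networks.

A PPI network is modelled as a simple undirected graph: nodes are proteins
(opaque, case-sensitive string identifiers) and an edge joins two proteins
that physically bind.  Self-loops and duplicate interactions are removed on
load, cross-species rows can be filtered out of BioGRID exports, and all
topology computations downstream run on the largest connected component.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import networkx as nx
import pandas as pd

__all__ = [
    "load_edge_list",
    "largest_connected_component",
    "edge_density",
    "write_edge_list",
    "connected_components_by_size",
]

#: BioGRID tab2 column names used by the reader.
_BIOGRID_SYMBOL_A = "Official Symbol Interactor A"
_BIOGRID_SYMBOL_B = "Official Symbol Interactor B"
_BIOGRID_ORG_A = "Organism Interactor A"
_BIOGRID_ORG_B = "Organism Interactor B"


class EdgeListParseError(ValueError):
    """Raised for a malformed row; carries the 1-based line number."""

    def __init__(self, path, line_number, message):
        self.line_number = line_number
        super().__init__(f"{path}:{line_number}: {message}")


def _add_edge(g: nx.Graph, u: str, v: str) -> None:
    if u == v:
        return  # self-loop
    g.add_edge(u, v)  # duplicates collapse in nx.Graph


def load_edge_list(
    path,
    format: str = "plain-tsv",
    species_filter: int | str | None = None,
    interaction_type: str | None = None,
) -> nx.Graph:
    """Read an interaction file into a simple undirected graph.

    Parameters
    ----------
    path
        TSV file.  ``plain-tsv``: two columns per row, ``#`` comment lines
        ignored.  ``biogrid-tab``: BioGRID tab2 export, parsed by header
        name (unknown columns ignored).
    species_filter
        For ``biogrid-tab``: keep only rows where both interactors belong
        to this organism (NCBI taxon id, e.g. 9606).
    interaction_type
        For ``biogrid-tab``: optional filter on the ``Experimental System
        Type`` column (e.g. ``"physical"``); by default all rows are kept.

    Self-loops and duplicate edges never survive; row order is irrelevant.
    """
    path = Path(path)
    if format == "plain-tsv":
        return _load_plain(path)
    if format == "biogrid-tab":
        return _load_biogrid(path, species_filter, interaction_type)
    raise ValueError(f"unknown edge-list format: {format!r}")


def _load_plain(path: Path) -> nx.Graph:
    g = nx.Graph()
    n_rows = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2 or not fields[0].strip() or not fields[1].strip():
                raise EdgeListParseError(path, lineno, f"expected two tab-separated columns, got {line!r}")
            n_rows += 1
            _add_edge(g, fields[0].strip(), fields[1].strip())
    if n_rows == 0:
        warnings.warn(f"{path}: no interaction rows; returning an empty graph")
    return g


def _load_biogrid(path: Path, species_filter, interaction_type) -> nx.Graph:
    df = pd.read_csv(path, sep="\t", comment=None, dtype=str)
    for col in (_BIOGRID_SYMBOL_A, _BIOGRID_SYMBOL_B):
        if col not in df.columns:
            raise EdgeListParseError(path, 1, f"missing BioGRID column {col!r}")
    if interaction_type is not None and "Experimental System Type" in df.columns:
        df = df[df["Experimental System Type"] == interaction_type]
    if species_filter is not None:
        taxon = str(species_filter)
        if _BIOGRID_ORG_A not in df.columns or _BIOGRID_ORG_B not in df.columns:
            raise EdgeListParseError(path, 1, "species filter requested but organism columns are absent")
        df = df[(df[_BIOGRID_ORG_A] == taxon) & (df[_BIOGRID_ORG_B] == taxon)]
    g = nx.Graph()
    for u, v in zip(df[_BIOGRID_SYMBOL_A], df[_BIOGRID_SYMBOL_B]):
        if pd.isna(u) or pd.isna(v):
            continue
        _add_edge(g, str(u), str(v))
    if g.number_of_edges() == 0:
        warnings.warn(f"{path}: no interactions survived parsing/filters")
    return g


def connected_components_by_size(g: nx.Graph) -> list[set]:
    """Connected components ordered by (node count, edge count) descending,
    ties broken by the lexicographically smallest member node id."""
    comps = [set(c) for c in nx.connected_components(g)]
    return sorted(
        comps,
        key=lambda c: (-len(c), -g.subgraph(c).number_of_edges(), min(map(str, c))),
    )


def largest_connected_component(g: nx.Graph) -> nx.Graph:
    """Induced subgraph on the largest connected component (deterministic
    tie-break: node count, then edge count, then smallest member id)."""
    if g.number_of_nodes() == 0:
        return nx.Graph()
    comps = connected_components_by_size(g)
    return g.subgraph(comps[0]).copy()


def edge_density(g: nx.Graph) -> float:
    """Proportion of present edges to possible edges, ``2m / (n(n-1))``."""
    n = g.number_of_nodes()
    if n < 2:
        raise ValueError("edge density requires at least 2 nodes")
    return 2.0 * g.number_of_edges() / (n * (n - 1))


def write_edge_list(g: nx.Graph, path) -> None:
    """Canonical edge-list TSV: endpoints sorted within a row, rows sorted.

    Re-reading the output with :func:`load_edge_list` reproduces the edge
    set bit-exactly, so the format round-trips.
    """
    rows = sorted(tuple(sorted((str(u), str(v)))) for u, v in g.edges())
    with open(path, "w") as fh:
        fh.write("#node_a\tnode_b\n")
        for u, v in rows:
            fh.write(f"{u}\t{v}\n")
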