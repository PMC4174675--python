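"""Graphlet degree vectors: 73-orbit signature counting.

``count_signatures`` counts, for every node, how often it occupies each of
the 73 automorphism orbits across all connected induced subgraphs on 2-5
nodes.  It enumerates every such subgraph exactly once (rooted enumeration
at each subgraph's minimum node with an exclusive-neighbourhood frontier)
and classifies it in O(1) through a lookup table generated *forwards* from
the catalogue by applying all node permutations to each graphlet.

``count_signatures_bruteforce`` is the independent reference: it enumerates
subsets around one node, keeps the connected ones, and classifies each by
explicit isomorphism search against the catalogue, resolving the node's
orbit through the matched permutation.  The two implementations share only
the frozen catalogue.
"""

from __future__ import annotations

from functools import lru_cache
from itertools import combinations

import networkx as nx
import numpy as np

from .graphlet_catalog import (
    GRAPHLETS,
    N_ORBITS,
    classify_subgraph,
)

__all__ = ["count_signatures", "count_signatures_bruteforce", "signature_frame"]

_PAIRS = {s: list(combinations(range(s), 2)) for s in (2, 3, 4, 5)}

_ORACLE_MAX_NODES = 40


@lru_cache(maxsize=1)
def _orbit_tables() -> dict[int, dict[int, tuple[int, ...]]]:
    """mask -> per-position orbit numbers, for labelled graphs on 2-5 nodes.

    Generated by mapping every catalogue graphlet through all node
    permutations; masks of non-graphlet (disconnected) labelled graphs are
    simply absent.
    """
    from itertools import permutations

    tables: dict[int, dict[int, tuple[int, ...]]] = {2: {}, 3: {}, 4: {}, 5: {}}
    for g in GRAPHLETS:
        s = g.n_nodes
        pair_index = {p: b for b, p in enumerate(_PAIRS[s])}
        for perm in permutations(range(s)):
            mask = 0
            for u, v in g.edges:
                i, j = perm[u], perm[v]
                mask |= 1 << pair_index[(i, j) if i < j else (j, i)]
            orbits = [0] * s
            for gnode in range(s):
                orbits[perm[gnode]] = g.orbits[gnode]
            tables[s][mask] = tuple(orbits)
    return tables


def _index_graph(g: nx.Graph) -> tuple[list, dict, list[int]]:
    """Deterministic node order plus adjacency bitmasks."""
    nodes = sorted(g.nodes(), key=str)
    index = {v: i for i, v in enumerate(nodes)}
    adj = [0] * len(nodes)
    for u, v in g.edges():
        iu, iv = index[u], index[v]
        if iu == iv:
            continue
        adj[iu] |= 1 << iv
        adj[iv] |= 1 << iu
    return nodes, index, adj


def _mask_of(sub: tuple[int, ...], adj: list[int]) -> int:
    mask = 0
    b = 0
    s = len(sub)
    for i in range(s):
        ai = adj[sub[i]]
        for j in range(i + 1, s):
            if ai >> sub[j] & 1:
                mask |= 1 << b
            b += 1
    return mask


def count_signatures(g: nx.Graph) -> dict:
    """Graphlet signature (73-vector of orbit counts) for every node.

    Works on any simple undirected graph; isolated nodes receive the zero
    vector.  ``counts[0]`` always equals the node's degree.
    """
    nodes, _, adj = _index_graph(g)
    n = len(nodes)
    tables = _orbit_tables()
    counts = np.zeros((n, N_ORBITS), dtype=np.int64)

    def record(sub: tuple[int, ...]) -> None:
        ordered = tuple(sorted(sub))
        orbits = tables[len(ordered)][_mask_of(ordered, adj)]
        for node_i, orb in zip(ordered, orbits):
            counts[node_i, orb] += 1

    # Rooted enumeration: each connected subgraph is found exactly once,
    # from its minimum node, growing along an exclusive frontier.
    for root in range(n):
        allowed = ~((1 << (root + 1)) - 1)  # nodes strictly greater than root

        def extend(sub: tuple[int, ...], frontier: list[int], closed: int) -> None:
            if len(sub) >= 2:
                record(sub)
            if len(sub) == 5:
                return
            for i, u in enumerate(frontier):
                new_closed = closed
                for w in frontier[i:]:
                    new_closed |= 1 << w
                fresh = adj[u] & allowed & ~new_closed
                new_frontier = frontier[i + 1 :] + _bits(fresh)
                extend(sub + (u,), new_frontier, new_closed | fresh)

        first = adj[root] & allowed
        extend((root,), _bits(first), (1 << root) | first)

    return {nodes[i]: counts[i] for i in range(n)}


def _bits(mask: int) -> list[int]:
    out = []
    while mask:
        low = mask & -mask
        out.append(low.bit_length() - 1)
        mask ^= low
    return out


def signature_frame(signatures: dict):
    """Signatures as a DataFrame (rows: sorted node ids, columns o0..o72)."""
    import pandas as pd

    nodes = sorted(signatures, key=str)
    data = np.vstack([signatures[v] for v in nodes]) if nodes else np.zeros((0, N_ORBITS), int)
    return pd.DataFrame(data, index=nodes, columns=[f"o{i}" for i in range(N_ORBITS)])


# ---------------------------------------------------------------------------
# Brute-force oracle
# ---------------------------------------------------------------------------


def count_signatures_bruteforce(g: nx.Graph, node) -> np.ndarray:
    """Reference signature of one node by exhaustive subset enumeration.

    Every subset of up to four further nodes (within distance 4 of ``node``)
    is tested for inducing a connected subgraph; connected ones are
    classified by permutation isomorphism search against the catalogue.
    Exponential in neighbourhood size, hence refused above
    ``40`` nodes.
    """
    if g.number_of_nodes() > _ORACLE_MAX_NODES:
        raise ValueError(
            f"brute-force oracle is limited to graphs with <= {_ORACLE_MAX_NODES} nodes"
        )
    if node not in g:
        raise KeyError(node)

    ball = set(nx.single_source_shortest_path_length(g, node, cutoff=4))
    others = sorted(ball - {node}, key=str)
    counts = np.zeros(N_ORBITS, dtype=np.int64)
    cache: dict[tuple[int, int], tuple[int, ...]] = {}

    for k in range(1, min(4, len(others)) + 1):
        for extra in combinations(others, k):
            sub_nodes = (node, *extra)
            sg = g.subgraph(sub_nodes)
            if not nx.is_connected(sg):
                continue
            # canonical local labelling: position 0 is the probed node
            idx = {v: i for i, v in enumerate(sub_nodes)}
            edges = tuple(sorted((min(idx[a], idx[b]), max(idx[a], idx[b])) for a, b in sg.edges()))
            key = (len(sub_nodes), edges)
            orbits = cache.get(key)
            if orbits is None:
                _, orbits = classify_subgraph(len(sub_nodes), edges)
                cache[key] = orbits
            counts[orbits[0]] += 1
    return counts
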