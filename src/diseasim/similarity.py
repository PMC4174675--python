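"""The three disease-disease similarity measures.

* annotation-based: Jaccard index of the two diseases' gene sets;
* function-based: Jaccard index of their enriched GO biological-process
  term sets;
* topology-based: the mean of AllSig (maximum graphlet-signature similarity
  over all cross-disease gene pairs in the PPI network) and ShareSig
  (maximum over the genes the diseases share; 0 when they share none).

Genes absent from the network's largest component are excluded from the
topology measure; a pair with no network-resident genes on either side is
scored as absent (NaN) and excluded from downstream evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .graphlet_similarity import orbit_weights, pairwise_signature_similarity, signature_similarity

__all__ = [
    "sim_annotation",
    "sim_function",
    "all_sig",
    "share_sig",
    "sim_topology",
    "similarity_matrix",
    "SimilarityMatrix",
    "MEASURES",
]

MEASURES = ("annotation", "function", "topology")


def _jaccard(a: set, b: set) -> float:
    union = len(a | b)
    return len(a & b) / union if union else float("nan")


def sim_annotation(gi: set, gj: set) -> float:
    """Jaccard index of the two gene sets; NaN when both are empty."""
    if not gi and not gj:
        return float("nan")
    return _jaccard(set(gi), set(gj))


def sim_function(fi, fj) -> float:
    """Jaccard index of two enriched-term sets.

    An empty enriched set is an informative enrichment outcome, so a pair
    with one empty side scores 0; only both-empty is 0 as well (no overlap).
    """
    ti = fi if isinstance(fi, (set, frozenset)) else fi.terms
    tj = fj if isinstance(fj, (set, frozenset)) else fj.terms
    if not ti or not tj:
        return 0.0
    return _jaccard(set(ti), set(tj))


def _restrict(genes: set, signatures: dict) -> list:
    return [g for g in genes if g in signatures]


def all_sig(gi: set, gj: set, signatures: dict, weights=None) -> float:
    """Maximum SigSim between a network gene of one disease and one of the
    other; NaN when either side has no gene in the network.  Equals 1
    whenever the diseases share a network gene."""
    gi_net, gj_net = _restrict(gi, signatures), _restrict(gj, signatures)
    if not gi_net or not gj_net:
        return float("nan")
    if set(gi_net) & set(gj_net):
        return 1.0
    w = orbit_weights() if weights is None else weights
    return max(
        signature_similarity(signatures[u], signatures[v], w)
        for u in gi_net
        for v in gj_net
    )


def share_sig(
    gi: set,
    gj: set,
    signatures: dict,
    weights=None,
    exclude_identical: bool = False,
) -> float:
    """Maximum SigSim among the network genes shared by both diseases.

    0 when no network gene is shared.  By default the maximum ranges over
    all (ordered) pairs from the shared set, including a gene with itself,
    so any shared network gene gives 1; with ``exclude_identical`` only
    distinct shared genes are compared (0 when fewer than two are shared).
    """
    shared = set(_restrict(gi, signatures)) & set(_restrict(gj, signatures))
    if not shared:
        return 0.0
    if not exclude_identical:
        return 1.0
    if len(shared) < 2:
        return 0.0
    w = orbit_weights() if weights is None else weights
    return max(
        signature_similarity(signatures[u], signatures[v], w)
        for u, v in combinations(sorted(shared, key=str), 2)
    )


def sim_topology(
    gi: set, gj: set, signatures: dict, weights=None, exclude_identical: bool = False
) -> float:
    """Mean of AllSig and ShareSig; NaN when AllSig is undefined."""
    a = all_sig(gi, gj, signatures, weights)
    if np.isnan(a):
        return float("nan")
    s = share_sig(gi, gj, signatures, weights, exclude_identical)
    return 0.5 * (a + s)


@dataclass
class SimilarityMatrix:
    """Symmetric disease-by-disease score matrix with NaN absent markers."""

    diseases: list
    scores: np.ndarray
    measure: str

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.scores, index=self.diseases, columns=self.diseases)

    def to_long_frame(self) -> pd.DataFrame:
        """Long format over unordered pairs: disease_a, disease_b, measure, score."""
        rows = [
            (self.diseases[i], self.diseases[j], self.measure, self.scores[i, j])
            for i, j in combinations(range(len(self.diseases)), 2)
        ]
        return pd.DataFrame(rows, columns=["disease_a", "disease_b", "measure", "score"])

    def pair_scores(self) -> dict:
        """Unordered pair -> score, NaN pairs included."""
        return {
            frozenset((self.diseases[i], self.diseases[j])): self.scores[i, j]
            for i, j in combinations(range(len(self.diseases)), 2)
        }


def similarity_matrix(
    measure: str,
    dmap: dict,
    signatures: dict | None = None,
    weights=None,
    enriched: dict | None = None,
    exclude_identical: bool = False,
) -> SimilarityMatrix:
    """Score every unordered disease pair under one measure.

    ``dmap`` maps disease code -> gene set.  The topology measure needs
    ``signatures`` (node -> 73-vector); the function measure needs
    ``enriched`` (disease -> EnrichedTermSet or term set).  Disease order is
    deterministic (sorted codes) and scores are invariant to input order.
    """
    diseases = sorted(dmap, key=str)
    n = len(diseases)
    scores = np.full((n, n), np.nan)

    if measure == "annotation":
        for i in range(n):
            for j in range(i, n):
                scores[i, j] = scores[j, i] = sim_annotation(dmap[diseases[i]], dmap[diseases[j]])
    elif measure == "function":
        if enriched is None:
            raise ValueError("function measure needs per-disease enriched term sets")
        missing = [d for d in diseases if d not in enriched]
        if missing:
            raise ValueError(f"enrichment missing for diseases: {missing[:5]}")
        for i in range(n):
            for j in range(i, n):
                scores[i, j] = scores[j, i] = sim_function(
                    enriched[diseases[i]], enriched[diseases[j]]
                )
    elif measure == "topology":
        if signatures is None:
            raise ValueError("topology measure needs graphlet signatures")
        w = orbit_weights() if weights is None else weights
        scores = _topology_matrix(diseases, dmap, signatures, w, exclude_identical)
    else:
        raise ValueError(f"unknown measure {measure!r}; expected one of {MEASURES}")

    return SimilarityMatrix(diseases=diseases, scores=scores, measure=measure)


def _topology_matrix(diseases, dmap, signatures, weights, exclude_identical):
    """Topology scores for all pairs via one precomputed SigSim matrix."""
    net_sets = {d: sorted(set(_restrict(dmap[d], signatures)), key=str) for d in diseases}
    genes = sorted({g for gs in net_sets.values() for g in gs}, key=str)
    gene_index = {g: i for i, g in enumerate(genes)}
    if genes:
        sig_matrix = np.vstack([signatures[g] for g in genes])
        sim = pairwise_signature_similarity(sig_matrix, weights)
    else:
        sim = np.zeros((0, 0))

    n = len(diseases)
    scores = np.full((n, n), np.nan)
    idx = {d: np.array([gene_index[g] for g in net_sets[d]], dtype=int) for d in diseases}
    for i in range(n):
        for j in range(i, n):
            ii, jj = idx[diseases[i]], idx[diseases[j]]
            if len(ii) == 0 or len(jj) == 0:
                continue
            shared = set(net_sets[diseases[i]]) & set(net_sets[diseases[j]])
            a = 1.0 if shared else float(sim[np.ix_(ii, jj)].max())
            if not shared:
                s = 0.0
            elif not exclude_identical:
                s = 1.0
            elif len(shared) < 2:
                s = 0.0
            else:
                si = np.array([gene_index[g] for g in sorted(shared, key=str)])
                block = sim[np.ix_(si, si)]
                s = float(block[np.triu_indices(len(si), k=1)].max())
            scores[i, j] = scores[j, i] = 0.5 * (a + s)
    return scores
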