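"""GO ontology handling and per-disease term overrepresentation.

Annotations are read from GAF, electronically inferred ones (evidence code
IEA) are discarded by default, and each gene's terms are closed upward
through the ontology (a gene annotated to a term is considered annotated to
all its ancestors).  A disease's functional profile F_i is then the set of
biological-process terms overrepresented among its genes: hypergeometric
upper-tail p-values, Benjamini-Hochberg corrected per disease, kept below a
significance level (default 0.05 on the adjusted p-value).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import obonet
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

__all__ = [
    "load_ontology",
    "load_gaf",
    "propagate",
    "enriched_terms",
    "remove_iea",
    "AnnotationSet",
    "EnrichedTermSet",
    "bp_universe",
]

BIOLOGICAL_PROCESS = "biological_process"
DEFAULT_RELATIONS = ("is_a", "part_of")


@dataclass
class AnnotationSet:
    """Gene -> GO term assignments with per-pair evidence codes."""

    assignments: dict[str, set[str]] = field(default_factory=dict)
    evidence: dict[tuple[str, str], set[str]] = field(default_factory=dict)

    def add(self, gene: str, term: str, code: str | None = None) -> None:
        self.assignments.setdefault(gene, set()).add(term)
        if code:
            self.evidence.setdefault((gene, term), set()).add(code)


@dataclass
class EnrichedTermSet:
    """Significant terms of one disease with raw and adjusted p-values."""

    table: pd.DataFrame  # columns: term, raw_p, adj_p (significant rows only)

    @property
    def terms(self) -> set[str]:
        return set(self.table["term"])

    def __len__(self) -> int:
        return len(self.table)


def load_ontology(path) -> nx.MultiDiGraph:
    """Read an OBO file into a child->parent relation graph.

    Obsolete terms are excluded; each node carries its ``namespace``
    attribute.  A cyclic propagation graph is a fatal validation error.
    """
    graph = obonet.read_obo(path, ignore_obsolete=True)
    if not nx.is_directed_acyclic_graph(graph):
        raise ValueError(f"{path}: ontology propagation graph contains a cycle")
    return graph


def load_gaf(path, remove_iea: bool = True) -> AnnotationSet:
    """Read GAF 2.x annotations (gene symbol, term, evidence code).

    ``remove_iea`` drops 'Inferred from Electronic Annotation' rows, which
    have not been reviewed by curators.
    """
    from Bio.UniProt.GOA import gafiterator

    annotations = AnnotationSet()
    with open(path) as fh:
        for rec in gafiterator(fh):
            code = rec["Evidence"]
            if remove_iea and code == "IEA":
                continue
            if rec["Qualifier"] and any(q.startswith("NOT") for q in rec["Qualifier"]):
                continue
            annotations.add(rec["DB_Object_Symbol"], rec["GO_ID"], code)
    return annotations


def remove_iea(annotations: AnnotationSet) -> AnnotationSet:
    """Drop assignments whose only evidence is electronic inference (IEA)."""
    out = AnnotationSet()
    for gene, terms in annotations.assignments.items():
        for term in terms:
            codes = annotations.evidence.get((gene, term), set())
            kept = {c for c in codes if c != "IEA"}
            if kept or not codes:
                for c in kept or {None}:
                    out.add(gene, term, c)
    return out


def term_ancestors(
    ontology: nx.MultiDiGraph, term: str, relations=DEFAULT_RELATIONS
) -> set[str]:
    """Ancestors of ``term`` along the chosen relations, same namespace only."""
    namespace = ontology.nodes[term].get("namespace")
    out: set[str] = set()
    stack = [term]
    while stack:
        t = stack.pop()
        for _, parent, rel in ontology.out_edges(t, keys=True):
            if rel not in relations:
                continue
            if ontology.nodes[parent].get("namespace") != namespace:
                continue
            if parent not in out:
                out.add(parent)
                stack.append(parent)
    return out


def propagate(
    annotations: AnnotationSet,
    ontology: nx.MultiDiGraph,
    relations=DEFAULT_RELATIONS,
) -> AnnotationSet:
    """Close every gene's term set upward through the ontology (idempotent).

    Terms absent from the ontology are dropped with a warning.
    """
    closure_cache: dict[str, set[str]] = {}
    out = AnnotationSet(evidence=dict(annotations.evidence))
    unknown: set[str] = set()
    for gene, terms in annotations.assignments.items():
        closed: set[str] = set()
        for term in terms:
            if term not in ontology.nodes:
                unknown.add(term)
                continue
            if term not in closure_cache:
                closure_cache[term] = {term} | term_ancestors(ontology, term, relations)
            closed |= closure_cache[term]
        if closed:
            out.assignments[gene] = closed
    if unknown:
        warnings.warn(f"dropped annotations to {len(unknown)} unknown term(s): {sorted(unknown)[:5]}")
    return out


def bp_universe(annotations: AnnotationSet, ontology: nx.MultiDiGraph) -> set[str]:
    """Genes carrying at least one biological-process annotation."""
    return {
        gene
        for gene, terms in annotations.assignments.items()
        if any(
            ontology.nodes[t].get("namespace") == BIOLOGICAL_PROCESS
            for t in terms
            if t in ontology.nodes
        )
    }


def enriched_terms(
    genes: set[str],
    annotations: AnnotationSet,
    ontology: nx.MultiDiGraph,
    universe: set[str] | None = None,
    alpha: float = 0.05,
    use_adjusted: bool = True,
    namespace: str = BIOLOGICAL_PROCESS,
) -> EnrichedTermSet:
    """Overrepresented terms of one gene set (one disease).

    For every term of the chosen namespace annotating at least one of the
    genes, the raw p-value is the hypergeometric upper tail P(X >= k) with
    population ``|universe|``, ``K`` annotated genes in the universe, and
    ``|genes|`` draws.  Benjamini-Hochberg runs across this disease's tested
    terms; rows with (adjusted, by default) p < ``alpha`` are kept.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    empty = EnrichedTermSet(pd.DataFrame(columns=["term", "raw_p", "adj_p"]))
    if not genes:
        return empty
    if universe is None:
        universe = bp_universe(annotations, ontology)
    missing = set(genes) - set(universe)
    if missing:
        raise ValueError(f"genes outside the universe: {sorted(missing)[:5]}")

    term_to_genes: dict[str, set[str]] = {}
    for gene in universe:
        for term in annotations.assignments.get(gene, ()):
            if term in ontology.nodes and ontology.nodes[term].get("namespace") == namespace:
                term_to_genes.setdefault(term, set()).add(gene)

    tested = sorted(t for t, tg in term_to_genes.items() if tg & genes)
    if not tested:
        return empty
    N, n = len(universe), len(genes)
    raw = np.array(
        [
            hypergeom.sf(len(term_to_genes[t] & genes) - 1, N, len(term_to_genes[t]), n)
            for t in tested
        ]
    )
    _, adj, _, _ = multipletests(raw, method="fdr_bh")
    table = pd.DataFrame({"term": tested, "raw_p": raw, "adj_p": adj})
    keep = table["adj_p"] < alpha if use_adjusted else table["raw_p"] < alpha
    return EnrichedTermSet(table[keep].reset_index(drop=True))
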