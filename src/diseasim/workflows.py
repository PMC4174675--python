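"""End-to-end pipelines gluing the building blocks together.

These are the convenience routes used by the command line, the examples and
the evaluation scripts: compute graphlet signatures on a network's largest
component, run per-disease GO enrichment, score all disease pairs under the
three measures, and benchmark them against comorbidity labels.
"""

from __future__ import annotations

import numpy as np

from .evaluation import comorbidity_labels, randomized_baseline, roc
from .go_enrichment import bp_universe, enriched_terms, propagate, remove_iea
from .graph_core import largest_connected_component
from .graphlet_counting import count_signatures
from .similarity import MEASURES, similarity_matrix

__all__ = [
    "network_signatures",
    "disease_enrichment",
    "all_similarity_matrices",
    "comorbidity_benchmark",
]


def network_signatures(graph) -> dict:
    """Graphlet signatures of the network's largest connected component."""
    return count_signatures(largest_connected_component(graph))


def disease_enrichment(dmap, annotations, ontology, alpha=0.05, iea_filtered=False):
    """Per-disease enriched biological-process term sets (F_i).

    Annotations are IEA-filtered (unless already done) and propagated
    upward once; the enrichment universe is shared across diseases.  Genes
    outside the universe (unannotated) are ignored for enrichment.
    """
    ann = annotations if iea_filtered else remove_iea(annotations)
    ann = propagate(ann, ontology)
    universe = bp_universe(ann, ontology)
    return {
        d: enriched_terms(set(genes) & universe, ann, ontology, universe=universe, alpha=alpha)
        for d, genes in dmap.items()
    }


def all_similarity_matrices(dmap, graph=None, annotations=None, ontology=None,
                            signatures=None, enriched=None, alpha=0.05,
                            measures=MEASURES):
    """Similarity matrices for the requested measures, computing whatever
    intermediate resources (signatures, enrichment) were not supplied."""
    out = {}
    if "topology" in measures and signatures is None:
        if graph is None:
            raise ValueError("topology measure needs a graph or precomputed signatures")
        signatures = network_signatures(graph)
    if "function" in measures and enriched is None:
        if annotations is None or ontology is None:
            raise ValueError("function measure needs annotations+ontology or enrichment")
        enriched = disease_enrichment(dmap, annotations, ontology, alpha=alpha)
    for measure in measures:
        out[measure] = similarity_matrix(
            measure, dmap, signatures=signatures, enriched=enriched
        )
    return out


def comorbidity_benchmark(
    sims: dict,
    records,
    dmap=None,
    phi_threshold=0.06,
    t_threshold=1.96,
    min_genes=1,
    baseline_reps=30,
    seed=0,
):
    """ROC/AUC of each measure against comorbidity labels, with the
    permutation baseline.  Returns a plain-dict report."""
    positives = comorbidity_labels(records, phi_threshold, t_threshold)
    report = {"phi_threshold": phi_threshold, "n_positive_pairs": len(positives), "measures": {}}
    for measure, sim in sims.items():
        r = roc(sim, positives, dmap=dmap, min_genes=min_genes)
        base_mean, base_sd = randomized_baseline(
            sim, positives, reps=baseline_reps, seed=seed, dmap=dmap, min_genes=min_genes
        )
        report["measures"][measure] = {
            "auc": r.auc,
            "n_pos": r.n_pos,
            "n_neg": r.n_neg,
            "n_excluded": r.n_excluded,
            "baseline_auc_mean": base_mean,
            "baseline_auc_sd": base_sd,
        }
    return report
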