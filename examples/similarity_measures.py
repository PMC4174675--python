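"""The three disease-disease similarity measures on a small synthetic study.

Generates a compact fixture (protein network, disease-gene map, GO
annotations), computes the annotation-, function- and topology-based
scores, and prints them for the planted "mechanistically related" pairs
against the background of unrelated pairs.
"""

import numpy as np

from diseasim import FixtureConfig, generate_fixture
from diseasim.workflows import all_similarity_matrices, disease_enrichment, network_signatures

cfg = FixtureConfig(seed=29, n_proteins=220, n_diseases=40, n_modules=14,
                    n_offnet_genes=50, overlap_fraction=0.25)
fx = generate_fixture(cfg)

signatures = network_signatures(fx.graph)
enriched = disease_enrichment(fx.dmap, fx.annotations, fx.ontology)
sims = all_similarity_matrices(fx.dmap, signatures=signatures, enriched=enriched)
scores = {m: sims[m].pair_scores() for m in sims}

print(f"{len(fx.dmap)} diseases, {len(fx.planted)} planted related pairs\n")
print(f"{'pair':12s} {'tier':12s} {'annotation':>10s} {'function':>9s} {'topology':>9s}")
for p in sorted(fx.planted, key=lambda p: -p.phi_target):
    row = [scores[m][p.key] for m in ("annotation", "function", "topology")]
    print(f"{p.a}-{p.b:8s} {p.tier:12s} " + " ".join(f"{v:9.3f}" for v in row))

background = {
    m: np.nanmean([v for k, v in scores[m].items() if k not in fx.planted_keys])
    for m in scores
}
print("\nmean over unplanted pairs: " + "  ".join(f"{m}={v:.3f}" for m, v in background.items()))
print(
    "\nGene-sharing pairs saturate the annotation and topology scores;"
    "\nproximity pairs are visible to the function and topology measures"
    "\nonly, through shared enriched GO terms and paralog-twin wiring."
)
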