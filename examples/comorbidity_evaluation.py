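"""Benchmarking similarity measures against comorbidity labels.

Positive pairs are those whose phi-correlation (binary Pearson correlation
of disease co-occurrence in a patient population) exceeds 0.06 and is
significant at the 5% level (t >= 1.96).  Each measure's ROC AUC is
compared with a permutation baseline in which scores are redrawn from
their own empirical distribution.
"""

from diseasim import FixtureConfig, generate_fixture
from diseasim.workflows import (
    all_similarity_matrices,
    comorbidity_benchmark,
    disease_enrichment,
    network_signatures,
)

cfg = FixtureConfig(seed=29, n_proteins=220, n_diseases=40, n_modules=14,
                    n_offnet_genes=50, overlap_fraction=0.25)
fx = generate_fixture(cfg)

sims = all_similarity_matrices(
    fx.dmap,
    signatures=network_signatures(fx.graph),
    enriched=disease_enrichment(fx.dmap, fx.annotations, fx.ontology),
)
report = comorbidity_benchmark(sims, fx.comorbidity, dmap=fx.dmap,
                               phi_threshold=0.06, baseline_reps=30, seed=1)

print(f"{report['n_positive_pairs']} comorbidity-positive pairs at phi > 0.06\n")
for measure, stats in report["measures"].items():
    print(
        f"{measure:11s} AUC = {stats['auc']:.4f}   "
        f"baseline = {stats['baseline_auc_mean']:.4f} ± {stats['baseline_auc_sd']:.4f}"
    )
print(
    "\nAn AUC well above the ~0.5 baseline means the measure ranks truly"
    "\ncomorbid pairs above unrelated ones far better than chance."
)
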