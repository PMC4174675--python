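"""Synthetic fixtures: PPI graph, disease-gene map, GO annotations, comorbidity.

The generator emulates the joint structure the similarity measures exploit:

* a sparse connected protein network (scale-free by default) into which
  *paralog twins* - node pairs with identical neighbourhoods, as arise from
  gene duplication - are planted;
* a disease-gene map whose gene sets are concentrated in network
  neighbourhoods, with a configurable set of planted "mechanistically
  related" disease pairs spanning a ladder of relatedness: the weakest
  related pairs merely occupy the same network region (one twin each), the
  middle of the ladder additionally shares genes that are absent from the
  network, and the strongest pairs share genes inside the network;
* a small three-namespace GO DAG whose biological-process leaves correspond
  to network regions, so that neighbourhood-concentrated gene sets come out
  coherently annotated;
* a comorbidity table in which each planted pair's co-occurrence count is
  inverted from its target phi-correlation (stronger relatedness = higher
  phi), while unplanted pairs sit at the independence expectation.

Everything is deterministic under a fixed seed, and the planted pairs are
returned as ground truth.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .go_enrichment import AnnotationSet
from .evaluation import ComorbidityRecord

__all__ = [
    "FixtureConfig",
    "PlantedPair",
    "Fixture",
    "generate_ppi",
    "generate_disease_map",
    "generate_go",
    "generate_comorbidity",
    "generate_gwas",
    "generate_fixture",
    "write_fixture",
    "write_obo",
    "write_gaf",
]

_STREAMS = {"ppi": 1, "disease": 2, "go": 3, "comorbidity": 4, "gwas": 5}

BP_ROOT, MF_ROOT, CC_ROOT = "GO:0008150", "GO:0003674", "GO:0005575"


@dataclass(frozen=True)
class FixtureConfig:
    """Knobs of the synthetic study; defaults are the reference conditions."""

    seed: int = 17
    n_proteins: int = 700
    n_offnet_genes: int = 120  # disease genes absent from the PPI network
    n_diseases: int = 200
    graph_model: str = "barabasi-albert"  # or "erdos-renyi"
    ba_m: int = 2
    er_p: float = 0.02
    size_min: int = 4  # genes per disease: heavy-tailed, clipped
    size_max: int = 25
    size_alpha: float = 2.0
    overlap_fraction: float = 0.10  # planted pairs = round(fraction * n_diseases)
    comorbidity_effect: float = 0.08  # phi scale of planted pairs
    population: int = 1_000_000
    prevalence_range: tuple[int, int] = (8_000, 30_000)
    n_modules: int = 35  # BP leaf terms / network regions
    region_fraction: float = 0.75  # fraction of a disease's genes from its region
    couple_signals: bool = True  # False: shared genes only, no common region/twins

    def n_planted(self) -> int:
        return round(self.overlap_fraction * self.n_diseases)


@dataclass(frozen=True)
class PlantedPair:
    a: str  # ICD-9 codes
    b: str
    phi_target: float
    tier: str  # "proximity" (weak half) or "gene-sharing" (strong half)
    shared_genes: tuple[str, ...] = ()

    @property
    def key(self) -> frozenset:
        return frozenset((self.a, self.b))


@dataclass
class Fixture:
    config: FixtureConfig
    graph: nx.Graph
    dmap: dict
    planted: list[PlantedPair]
    ontology: nx.MultiDiGraph
    annotations: AnnotationSet  # includes IEA rows, as a real GAF would
    comorbidity: list[ComorbidityRecord]
    gwas: dict
    source_ids: dict = field(default_factory=dict)  # raw disease id -> icd9

    @property
    def planted_keys(self) -> set[frozenset]:
        return {p.key for p in self.planted}


def _rng(cfg: FixtureConfig, stream: str) -> np.random.Generator:
    return np.random.default_rng([cfg.seed, _STREAMS[stream]])


def _gene_name(i: int) -> str:
    return f"P{i:04d}"


# ---------------------------------------------------------------------------
# PPI graph
# ---------------------------------------------------------------------------


def generate_ppi(cfg: FixtureConfig) -> nx.Graph:
    """Connected simple protein network with planted paralog twin pairs.

    One twin pair per planned planted disease pair is added by duplicating
    the neighbourhood of a moderate-degree node; the pairs are recorded in
    ``g.graph["paralog_pairs"]``.  The graph also carries a deterministic
    partition into ``n_modules`` BFS cells (``g.graph["modules"]``), the
    network regions that anchor disease gene sets and GO leaf terms.
    """
    if cfg.n_proteins < 10:
        raise ValueError("need at least 10 proteins")
    rng = _rng(cfg, "ppi")
    seed = int(rng.integers(2**31))
    if cfg.graph_model == "barabasi-albert":
        base = nx.barabasi_albert_graph(cfg.n_proteins, cfg.ba_m, seed=seed)
    elif cfg.graph_model == "erdos-renyi":
        base = nx.gnp_random_graph(cfg.n_proteins, cfg.er_p, seed=seed)
        comps = sorted(nx.connected_components(base), key=len, reverse=True)
        if len(comps) > 1:
            warnings.warn(
                f"random graph disconnected; using its largest component "
                f"({len(comps[0])} of {cfg.n_proteins} nodes)"
            )
        base = base.subgraph(comps[0]).copy()
    else:
        raise ValueError(f"unknown graph model {cfg.graph_model!r}")

    g = nx.relabel_nodes(base, {v: _gene_name(v) for v in base.nodes()})
    twins = []
    candidates = sorted(v for v in g.nodes() if 2 <= g.degree(v) <= 6)
    chosen = rng.choice(len(candidates), size=min(cfg.n_planted(), len(candidates)), replace=False)
    for k, ci in enumerate(sorted(int(c) for c in chosen)):
        v = candidates[ci]
        twin = f"T{k:04d}"
        g.add_node(twin)
        for u in list(g.neighbors(v)):
            g.add_edge(twin, u)
        twins.append((v, twin))
    g.graph["paralog_pairs"] = twins

    nodes = sorted(g.nodes())
    seed_idx = rng.choice(len(nodes), size=min(cfg.n_modules, len(nodes)), replace=False)
    seeds = [nodes[int(i)] for i in sorted(seed_idx)]
    g.graph["modules"] = _module_partition(g, seeds)
    return g


# ---------------------------------------------------------------------------
# Disease-gene map with planted related pairs
# ---------------------------------------------------------------------------


def _ball(g: nx.Graph, center, radius: int) -> list:
    return sorted(nx.single_source_shortest_path_length(g, center, cutoff=radius))


def _draw_size(rng, cfg: FixtureConfig) -> int:
    return int(min(cfg.size_min + math.floor(rng.pareto(cfg.size_alpha) * 2), cfg.size_max))


def _region_pool(g: nx.Graph, anchor, minimum: int) -> list:
    """The anchor's module cell, widened to its 2-ball when the cell is small."""
    modules = g.graph["modules"]
    cell = sorted(v for v, m in modules.items() if m == modules[anchor])
    if len(cell) < minimum:
        cell = sorted(set(cell) | set(_ball(g, anchor, 2)))
    return cell


def _sample_gene_set(rng, cfg, g, pool_all, anchor, size, forced=(), exclude=()):
    """Region-concentrated gene set: most genes from the anchor's module cell."""
    genes = set(forced)
    exclude = set(exclude) - genes
    if anchor is not None and cfg.couple_signals:
        region = [x for x in _region_pool(g, anchor, size) if x not in genes and x not in exclude]
        n_region = min(int(round(cfg.region_fraction * size)), len(region))
        if n_region > 0:
            picks = rng.choice(len(region), size=n_region, replace=False)
            genes |= {region[int(i)] for i in picks}
    rest = [x for x in pool_all if x not in genes and x not in exclude]
    while len(genes) < size and rest:
        i = int(rng.integers(len(rest)))
        genes.add(rest.pop(i))
    return genes


def _sample_region_mix(rng, cfg, g, pool_all, anchor, decoy, same_fraction, size, forced, exclude):
    """Like :func:`_sample_gene_set`, but the region draw is split between
    the anchor's module and a decoy module in ratio ``same_fraction``."""
    genes = set(forced)
    exclude = set(exclude) - genes
    if anchor is not None and cfg.couple_signals:
        n_region = int(round(cfg.region_fraction * size))
        if same_fraction >= 1.0:
            n_same, n_other = n_region, 0
        else:
            # graded mixing, but never fewer than 2 genes from either module:
            # the decoy keeps the weaker tiers' functional profiles strictly
            # wider than their partner's
            n_other = max(2, n_region - round(same_fraction * (n_region - 2)) - 2)
            n_same = max(2, n_region - n_other)
        for center, want in ((anchor, n_same), (decoy, n_other)):
            if center is None or want <= 0:
                continue
            pool = [x for x in _region_pool(g, center, size) if x not in genes and x not in exclude]
            if pool:
                picks = rng.choice(len(pool), size=min(want, len(pool)), replace=False)
                genes |= {pool[int(i)] for i in picks}
    rest = [x for x in pool_all if x not in genes and x not in exclude]
    while len(genes) < size and rest:
        i = int(rng.integers(len(rest)))
        genes.add(rest.pop(i))
    return genes


def generate_disease_map(cfg: FixtureConfig, g: nx.Graph) -> tuple[dict, list[PlantedPair]]:
    """Disease-gene map plus the planted ground-truth pairs.

    Disease identifiers are 3-digit ICD-9 codes.  Gene-set sizes follow a
    clipped heavy-tailed distribution.  Planted pairs are built around the
    graph's paralog twins; the weaker ("proximity") half of the ladder gets
    phi factors 0.3-0.95 of ``comorbidity_effect`` - sharing no network
    gene, the upper part of that half sharing one off-network gene - while
    the stronger ("gene-sharing") half gets factors 1.4-1.65 and shares 2-4
    network genes drawn from the common region.
    """
    if not 0 <= cfg.overlap_fraction <= 1:
        raise ValueError("overlap_fraction must be in [0, 1]")
    rng = _rng(cfg, "disease")
    codes = [f"{int(c):03d}" for c in rng.choice(np.arange(1, 1000), size=cfg.n_diseases, replace=False)]
    offnet = [f"G{i:04d}" for i in range(cfg.n_offnet_genes)]
    network_genes = sorted(g.nodes())
    pool_all = network_genes + offnet
    twins = list(g.graph.get("paralog_pairs", []))

    n_pairs = min(cfg.n_planted(), len(twins), cfg.n_diseases // 2)
    order = rng.permutation(cfg.n_diseases)
    pair_codes = [(codes[order[2 * k]], codes[order[2 * k + 1]]) for k in range(n_pairs)]

    n_weak = n_pairs // 2
    factors = np.concatenate(
        [
            np.linspace(0.3, 0.95, n_weak) if n_weak else [],
            np.linspace(1.4, 1.65, n_pairs - n_weak) if n_pairs - n_weak else [],
        ]
    )

    dmap: dict[str, set] = {}
    planted: list[PlantedPair] = []
    planted_codes: set[str] = set()
    # twin bases and their duplicates are reserved for their own planted
    # pair; no other disease samples them, so each remains specific to a
    # single disease (surviving a pleiotropic-gene filter)
    all_twin_nodes = {x for pair in twins for x in pair}
    modules = g.graph.get("modules", {})
    cell_size: dict[int, int] = {}
    for m in modules.values():
        cell_size[m] = cell_size.get(m, 0) + 1
    # planted pairs draw from their base node's cell: prefer roomy cells
    twins = sorted(twins, key=lambda uv: (-cell_size.get(modules.get(uv[0]), 0), uv[0]))
    for k, (code_a, code_b) in enumerate(pair_codes):
        factor = float(factors[k])
        strong = factor > 1.0
        u, twin = twins[k]
        # both region draws anchor on the base node: the twin may have been
        # assigned to a neighbouring cell by the balanced partition
        anchor = u if cfg.couple_signals else None
        size_a = int(np.clip(_draw_size(rng, cfg), 8 if strong else 6, 12))
        size_b = int(np.clip(_draw_size(rng, cfg), 8 if strong else 6, 12))
        shared: set = set()
        if strong:
            n_shared = max(2, round(0.25 * min(size_a, size_b)))
            region = [
                x for x in _region_pool(g, u, 8) if x not in all_twin_nodes
            ] or [x for x in network_genes if x not in all_twin_nodes]
            picks = rng.choice(len(region), size=min(n_shared, len(region)), replace=False)
            shared = {region[int(i)] for i in picks}
        elif factor >= 0.6:
            shared = {offnet[int(rng.integers(len(offnet)))]}  # off-network only
        genes_a = _sample_gene_set(
            rng, cfg, g, pool_all, anchor, size_a,
            forced=shared | ({u} if cfg.couple_signals else set()),
            exclude=all_twin_nodes - {u},
        )
        # the partner must not pick up undesigned overlap with the first set,
        # and for the weaker tiers only part of its region draw comes from
        # the common module - the rest from a decoy module - so functional
        # overlap grades with relatedness
        decoy = None
        if cfg.couple_signals and not strong and modules:
            others = [v for v in network_genes if modules.get(v) != modules.get(u)]
            decoy = others[int(rng.integers(len(others)))] if others else None
        genes_b = _sample_region_mix(
            rng, cfg, g, pool_all,
            anchor=anchor, decoy=decoy,
            same_fraction=1.0 if strong else factor,
            size=size_b,
            forced=shared | ({twin} if cfg.couple_signals else set()),
            exclude=(genes_a - shared) | (all_twin_nodes - {twin}),
        )
        dmap[code_a] = genes_a
        dmap[code_b] = genes_b
        planted_codes |= {code_a, code_b}
        planted.append(
            PlantedPair(
                a=code_a,
                b=code_b,
                phi_target=factor * cfg.comorbidity_effect,
                tier="gene-sharing" if strong else "proximity",
                shared_genes=tuple(sorted(shared)),
            )
        )

    for code in codes:
        if code in planted_codes:
            continue
        anchor = network_genes[int(rng.integers(len(network_genes)))] if cfg.couple_signals else None
        dmap[code] = _sample_gene_set(
            rng, cfg, g, pool_all, anchor, _draw_size(rng, cfg), exclude=all_twin_nodes
        )
    return dmap, planted


# ---------------------------------------------------------------------------
# GO ontology and annotations
# ---------------------------------------------------------------------------


def _module_partition(g: nx.Graph, seeds: list) -> dict:
    """Deterministic balanced multi-source BFS partition of the nodes.

    Seeds claim unassigned neighbours in rotation, so no cell can swallow
    the whole neighbourhood of a hub; cells are capped near the average
    size.  Unreached nodes join the first cell.
    """
    cap = max(3, math.ceil(1.6 * g.number_of_nodes() / max(1, len(seeds))))
    assignment = {s: i for i, s in enumerate(seeds)}
    frontiers = {i: [s] for i, s in enumerate(seeds)}
    sizes = {i: 1 for i in range(len(seeds))}
    progress = True
    while progress:
        progress = False
        for i in range(len(seeds)):
            if sizes[i] >= cap:
                continue
            claimed = None
            new_frontier = []
            for v in frontiers[i]:
                if claimed is None:
                    for w in sorted(g.neighbors(v)):
                        if w not in assignment:
                            claimed = w
                            break
                if claimed is None or any(w not in assignment for w in g.neighbors(v)):
                    new_frontier.append(v)
            if claimed is not None:
                assignment[claimed] = i
                sizes[i] += 1
                new_frontier.append(claimed)
                progress = True
            frontiers[i] = new_frontier
    for v in g.nodes():
        assignment.setdefault(v, 0)
    return assignment


def generate_go(cfg: FixtureConfig, g: nx.Graph, extra_genes: list | None = None):
    """Small three-namespace GO DAG plus gene annotations.

    Biological-process leaves mirror network regions: the network is
    partitioned into ``n_modules`` BFS cells and every protein is annotated
    (evidence IDA) to its cell's leaf term, with a sprinkling of noise terms
    and of IEA-coded rows that the loader is expected to discard.  Leaves
    attach to mid-level terms by is_a, a quarter of them also to a second
    mid-level term by part_of, giving a genuine DAG.
    """
    rng = _rng(cfg, "go")
    onto = nx.MultiDiGraph()

    def add_term(tid, name, namespace):
        onto.add_node(tid, name=name, namespace=namespace)

    add_term(BP_ROOT, "biological_process", "biological_process")
    add_term(MF_ROOT, "molecular_function", "molecular_function")
    add_term(CC_ROOT, "cellular_component", "cellular_component")

    n_mid = max(2, cfg.n_modules // 5)
    mids = [f"GO:01{m:05d}" for m in range(n_mid)]
    for m, tid in enumerate(mids):
        add_term(tid, f"process group {m}", "biological_process")
        onto.add_edge(tid, BP_ROOT, key="is_a")
    leaves = [f"GO:02{m:05d}" for m in range(cfg.n_modules)]
    for m, tid in enumerate(leaves):
        add_term(tid, f"module process {m}", "biological_process")
        onto.add_edge(tid, mids[m % n_mid], key="is_a")
        if m % 4 == 0:
            onto.add_edge(tid, mids[(m // 4 + 1) % n_mid], key="part_of")
    mf_terms = [f"GO:03{m:05d}" for m in range(6)]
    cc_terms = [f"GO:04{m:05d}" for m in range(6)]
    for m, tid in enumerate(mf_terms):
        add_term(tid, f"activity {m}", "molecular_function")
        onto.add_edge(tid, MF_ROOT, key="is_a")
    for m, tid in enumerate(cc_terms):
        add_term(tid, f"compartment {m}", "cellular_component")
        onto.add_edge(tid, CC_ROOT, key="is_a")

    nodes = sorted(g.nodes())
    modules = g.graph["modules"]

    ann = AnnotationSet()
    for gene in nodes:
        if rng.random() < 0.03:  # electronically inferred only: must vanish
            ann.add(gene, leaves[modules[gene] % len(leaves)], "IEA")
        else:
            ann.add(gene, leaves[modules[gene] % len(leaves)], "IDA")
        if rng.random() < 0.10:  # noise term
            ann.add(gene, leaves[int(rng.integers(len(leaves)))], "IMP")
        code = "IEA" if rng.random() < 0.3 else "IDA"
        ann.add(gene, mf_terms[int(rng.integers(len(mf_terms)))], code)
        if rng.random() < 0.5:
            ann.add(gene, cc_terms[int(rng.integers(len(cc_terms)))], "IDA")
    for gene in extra_genes or []:
        ann.add(gene, leaves[int(rng.integers(len(leaves)))], "IDA")
    return onto, ann


# ---------------------------------------------------------------------------
# Comorbidity and GWAS tables
# ---------------------------------------------------------------------------


def generate_comorbidity(
    dmap: dict, planted: list[PlantedPair], cfg: FixtureConfig
) -> list[ComorbidityRecord]:
    """Co-occurrence counts for every disease pair.

    Unplanted pairs sit at the independence expectation ``P_i P_j / N``;
    planted pairs get the count that inverts the phi-correlation formula at
    their target phi (rounded to whole patients, clipped to min(P_i, P_j)).
    """
    from itertools import combinations

    rng = _rng(cfg, "comorbidity")
    lo, hi = cfg.prevalence_range
    n = cfg.population
    if hi >= n:
        raise ValueError("population must exceed every prevalence")
    codes = sorted(dmap)
    prev = {c: int(rng.integers(lo, hi + 1)) for c in codes}
    targets = {p.key: p.phi_target for p in planted}

    records = []
    for a, b in combinations(codes, 2):
        p_i, p_j = prev[a], prev[b]
        phi = targets.get(frozenset((a, b)), 0.0)
        denom = math.sqrt(p_i * p_j * (n - p_i) * (n - p_j))
        c_ij = int(round((phi * denom + p_i * p_j) / n))
        cap = min(p_i, p_j)
        if c_ij > cap:
            warnings.warn(f"target phi {phi} infeasible for pair ({a}, {b}); clipping")
            c_ij = cap
        records.append(ComorbidityRecord.from_counts(a, b, c_ij, p_i, p_j, n))
    return records


def generate_gwas(cfg: FixtureConfig, dmap: dict) -> dict:
    """Per-disease gene subsets standing in for author-reported GWAS genes.

    About half the diseases are 'studied'; each reports ~60% of its genes.
    """
    rng = _rng(cfg, "gwas")
    table = {}
    for code in sorted(dmap):
        if rng.random() < 0.5:
            genes = sorted(dmap[code])
            k = max(1, int(round(0.6 * len(genes))))
            picks = rng.choice(len(genes), size=k, replace=False)
            table[code] = {genes[int(i)] for i in picks}
    return table


# ---------------------------------------------------------------------------
# Orchestration and file output
# ---------------------------------------------------------------------------


def generate_fixture(cfg: FixtureConfig | None = None) -> Fixture:
    """Build the full synthetic study (graph, diseases, GO, comorbidity, GWAS)."""
    cfg = cfg or FixtureConfig()
    g = generate_ppi(cfg)
    dmap, planted = generate_disease_map(cfg, g)
    offnet = sorted({x for gs in dmap.values() for x in gs if x not in g})
    onto, ann = generate_go(cfg, g, extra_genes=offnet)
    comorbidity = generate_comorbidity(dmap, planted, cfg)
    gwas = generate_gwas(cfg, dmap)
    source_ids = {f"D{i:04d}": code for i, code in enumerate(sorted(dmap))}
    return Fixture(
        config=cfg,
        graph=g,
        dmap=dmap,
        planted=planted,
        ontology=onto,
        annotations=ann,
        comorbidity=comorbidity,
        gwas=gwas,
        source_ids=source_ids,
    )


def write_obo(onto: nx.MultiDiGraph, path) -> None:
    with open(path, "w") as fh:
        fh.write("format-version: 1.2\nontology: synthetic-go\n")
        for tid in sorted(onto.nodes()):
            attrs = onto.nodes[tid]
            fh.write(f"\n[Term]\nid: {tid}\nname: {attrs['name']}\n")
            fh.write(f"namespace: {attrs['namespace']}\n")
            for _, parent, rel in sorted(onto.out_edges(tid, keys=True)):
                if rel == "is_a":
                    fh.write(f"is_a: {parent} ! {onto.nodes[parent]['name']}\n")
                else:
                    fh.write(f"relationship: {rel} {parent} ! {onto.nodes[parent]['name']}\n")
        # one obsolete stanza: loaders must skip it
        fh.write("\n[Term]\nid: GO:0999999\nname: withdrawn process\n")
        fh.write("namespace: biological_process\nis_obsolete: true\n")


def write_gaf(ann: AnnotationSet, path) -> None:
    with open(path, "w") as fh:
        fh.write("!gaf-version: 2.2\n")
        for gene in sorted(ann.assignments):
            for term in sorted(ann.assignments[gene]):
                codes = sorted(ann.evidence.get((gene, term), {"IDA"}))
                for code in codes:
                    fields = [
                        "SYN", gene, gene, "", term, "SYN:0000001", code, "",
                        "P", "", "", "protein", "taxon:9606", "20200101", "SYN", "", "",
                    ]
                    fh.write("\t".join(fields) + "\n")


def write_fixture(fx: Fixture, out_dir) -> None:
    """Emit every file format the loaders consume, plus ground truth JSON."""
    from pathlib import Path

    from .graph_core import write_edge_list
    from .associations import write_disease_gene_map

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_edge_list(fx.graph, out / "ppi.tsv")
    write_disease_gene_map(fx.dmap, out / "disease_gene_map.tsv")

    code_of = fx.source_ids
    rng = _rng(fx.config, "disease")  # suffixes only decorate the mapping file
    with open(out / "associations.tsv", "w") as fh:
        fh.write("#disease_id\tgene_id\n")
        for did in sorted(code_of):
            for gene in sorted(fx.dmap[code_of[did]]):
                fh.write(f"{did}\t{gene}\n")
    with open(out / "id_mapping.tsv", "w") as fh:
        for did in sorted(code_of):
            suffix = f".{int(rng.integers(10))}"  # loaders must truncate this
            fh.write(f"{did}\t{code_of[did]}{suffix}\n")

    write_obo(fx.ontology, out / "go.obo")
    write_gaf(fx.annotations, out / "annotations.gaf")

    with open(out / "comorbidity.tsv", "w") as fh:
        fh.write("icd9_a\ticd9_b\tC_ij\tP_i\tP_j\tN\n")
        for r in fx.comorbidity:
            fh.write(f"{r.a}\t{r.b}\t{r.c_ij}\t{r.p_i}\t{r.p_j}\t{r.n}\n")
    with open(out / "gwas.tsv", "w") as fh:
        fh.write("#icd9\tgene\n")
        for code in sorted(fx.gwas):
            for gene in sorted(fx.gwas[code]):
                fh.write(f"{code}\t{gene}\n")
    with open(out / "truth.json", "w") as fh:
        json.dump(
            {
                "seed": fx.config.seed,
                "planted_pairs": [
                    {
                        "a": p.a,
                        "b": p.b,
                        "phi_target": p.phi_target,
                        "tier": p.tier,
                        "shared_genes": list(p.shared_genes),
                    }
                    for p in fx.planted
                ],
            },
            fh,
            indent=2,
        )
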