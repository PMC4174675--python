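# Methods

This note records the models implemented by `diseasim`, the conventions and
numerical choices behind them, what the synthetic data generator does and
does not emulate, and the design decisions taken where the design was
genuinely open.

## Input model

A PPI network is a simple undirected graph over opaque, case-sensitive
protein identifiers.  Self-loops and duplicate interactions are removed on
load; in BioGRID exports, rows whose two interactors belong to different
organisms can be filtered out, and parsing is by column header so that
format revisions with reordered or extra columns still load.  All topology
computations run on the largest connected component (LCC): small isolated
components carry little topological information and disappear implicitly
when the LCC is taken.  Component ties are broken deterministically by node
count, then edge count, then the lexicographically smallest member — real
networks essentially never tie, but determinism keeps runs reproducible.

Disease–gene association tables arrive keyed by source vocabularies (OMIM,
MeSH, DO, UMLS).  A user-supplied mapping converts them to ICD-9; codes
are truncated to the category (3-digit) level — numeric codes keep three
digits, E-codes the letter plus three digits, V-codes the letter plus two,
matching the standard ICD-9 structure — and the gene sets of source
diseases that collapse onto one code are unioned.  Gene identifiers are
treated as exact strings: identifier harmonisation is an upstream curation
task, not something this package guesses at.

## Graphlet signatures

A graphlet is a connected induced subgraph on 2–5 nodes; there are 30
non-isomorphic graphlets and 73 automorphism orbits across them.  The
catalogue ships as frozen data (edge lists plus per-node orbit labels) in
the canonical ordering — graphlets by node count, then edge count, then
the published within-class order; orbit numbers within a graphlet increase
with (node degree, sorted neighbour-degree multiset).  The test-suite
re-derives the orbit partition of every graphlet by explicit
automorphism-group computation and checks the 73-orbit total, so the data
cannot silently drift.

Counting uses a rooted enumeration: every connected induced subgraph of
size 2–5 is visited exactly once (grown from its minimum node along an
exclusive frontier) and classified in O(1) via a lookup table produced by
applying all node permutations to each catalogue graphlet.  An independent
brute-force oracle enumerates node-containing subsets, filters for
connectivity, and classifies by permutation isomorphism search; the two
implementations share only the catalogue and are required to agree exactly
on batches of random graphs.

Orbit weights are `w_i = 1 − log(o_i)/log(73)`, where the dependency count
`o_i` is the number of distinct orbits a node occupying orbit `i`
necessarily touches within its own graphlet (orbit 0, the degree, depends
only on itself: `o_0 = 1`, `w_0 = 1`).  The counts are derived
programmatically from the catalogue by exactly this definition rather than
copied from a table; the derivation reproduces every value that could be
checked by hand (all 2–4-node orbits, the 5-cycle, the complete graph,
and others).

Signature similarity compares two 73-vectors orbit by orbit on a log
scale, normalised so the result lies in [0, 1] and equals 1 exactly when
the vectors are identical.  The pairwise matrix over all network genes is
computed vectorised with row chunking (64 rows per block) to bound memory.

## Disease similarity

* annotation: Jaccard of the gene sets; a pair with two empty sets is
  undefined (NaN), since nothing was compared.
* function: Jaccard of the enriched-term sets.  An empty enriched set is a
  legitimate enrichment outcome, so a pair with one empty side scores 0
  rather than NaN.
* topology: mean of AllSig and ShareSig.  Genes absent from the LCC are
  silently excluded; a pair with no network-resident genes on either side
  is NaN and excluded from evaluation (a flag in the ROC routine can
  zero-fill instead).  ShareSig's pair domain is ambiguous in principle:
  the default takes the maximum over the shared gene set including a gene
  paired with itself — hence 1.0 whenever any network gene is shared — and
  an `exclude_identical` option restricts to distinct shared genes (0 when
  fewer than two are shared).  Both behaviours are implemented and tested;
  neither is privileged beyond the default.

Under the defaults, a pair sharing a network gene scores
`(1 + 1)/2 = 1.0` and a non-sharing pair at most `AllSig/2 ≤ 0.5`, so
gene-sharing pairs always outrank non-sharing ones — a structural property
the tests assert.

## GO enrichment

Annotations with evidence code IEA (electronically inferred, uncurated)
are dropped by default at load.  Terms are propagated upward through
`is_a` and `part_of` within the term's namespace (both relations are the
common convention; the set is configurable), idempotently.  The
enrichment universe defaults to all genes with at least one
biological-process annotation — the only set the data itself determines —
and is overridable.  For one disease, every biological-process term
annotating at least one of its genes is tested with the hypergeometric
upper tail P(X ≥ k); Benjamini–Hochberg runs per disease across its tested
terms (the functional profile F_i is built disease by disease), and terms
with adjusted p < 0.05 are kept.  Whether the cutoff applies to raw or
adjusted p is ambiguous in principle; adjusted is the default (otherwise
the correction would be decorative) with a flag for raw.

## Evaluation

ICD-9 concordance uses the 17 standard chapters plus the E and V
supplementary blocks; "same category" means same chapter (the endocrine
block 240–279 is one chapter).  The test is a one-sided Mann–Whitney U
(same-chapter scores greater), exact for small tie-free samples and a
tie-corrected normal approximation otherwise.

Comorbidity strength is the φ-correlation — the Pearson correlation of the
two binary disease-presence indicators, computed from the co-occurrence
count, the two prevalences and the population size — with significance
assessed by `t = φ·sqrt(n−2)/sqrt(1−φ²)` at `n = max(P_i, P_j)`
observations.  Positive labels require φ above a threshold (default 0.06)
and `t ≥ 1.96` (inclusive).  GWAS labels call two diseases associated when
they share at least one reported gene; the p-value and replication filters
on GWAS associations are upstream curation, documented as expectations on
the input table.

ROC curves sweep the similarity score as a decision threshold.  The AUC is
computed by rank averaging, so it equals the Mann–Whitney statistic
`U/(n_pos·n_neg)` with half-credit for ties; tests verify it against an
O(n²) concordance count.  The random baseline redraws each pair's score
from the empirical score distribution — by default an exact permutation of
the realised scores, with a resampling variant behind a flag — for 30
repetitions, reporting mean ± sd.  Pairs with undefined scores are
excluded from both and counted.

## The synthetic study

The generator emulates the joint structure the measures exploit, with all
randomness driven by one seed (fixed seed ⇒ byte-identical files).

* **Network**: scale-free (preferential attachment, 700 proteins, 2 edges
  per arrival) by default; sparse-uniform optional.  One *paralog twin* —
  a duplicate of a moderate-degree node's neighbourhood, as gene
  duplication produces — is planted per planned related disease pair.
  Twins are topologically identical to their base, giving a clean
  proximity signal that survives the pleiotropy filter because twins are
  reserved for their own pair.  The network is deterministically
  partitioned into 35 balanced BFS cells ("modules"), which double as
  network regions and GO leaf terms.
* **Diseases**: 200, keyed by distinct random 3-digit ICD-9 codes.
  Gene-set sizes follow a clipped heavy-tailed (Pareto) distribution with
  minimum 4 and maximum 25 — most diseases have few genes, a few have
  many.  75% of a disease's genes come from its anchor module, the rest
  uniformly from the gene universe (the network plus 120 genes absent
  from it, mirroring disease genes without interaction data).
* **Planted related pairs**: 10% of the disease count (20 pairs by
  default), spanning a ladder of relatedness.  The weaker half
  ("proximity", φ targets 0.3–0.95 × the 0.08 effect) shares no network
  gene: both diseases draw from the same module, carry the twin pair, and
  the second disease mixes in a decoy module in proportion to its
  weakness (never fewer than two decoy genes, so its functional profile
  is strictly wider than its partner's); the upper part of that half
  additionally shares one off-network gene.  The stronger half
  ("gene-sharing", φ targets 1.4–1.65 × effect) shares 2–4 network genes
  from the common module.  This coupling — stronger comorbidity planted
  with stronger molecular overlap — is what makes the measured AUC rise
  as the φ threshold sweeps 0.02–0.10.  A `couple_signals=False` switch
  drops the region/twin structure, leaving shared genes as the only
  signal, to test the measures in isolation.
* **Comorbidity**: prevalences uniform in 8,000–30,000 persons out of a
  million.  Unplanted pairs get the independence count `P_iP_j/N`;
  planted pairs get the count that inverts the φ formula at their target,
  rounded to whole patients and clipped to `min(P_i, P_j)`.  Rounding
  keeps realised φ within ≈2·10⁻⁴ of target at these prevalences; the
  lowest planted φ still clears `t ≥ 1.96` because prevalences are
  bounded below.
* **GO**: three namespaces; biological-process leaves correspond to the
  35 network modules, attached to mid-level terms by `is_a` (a quarter
  also by `part_of` to a second mid-level term, giving a genuine DAG).
  Every protein is annotated to its module's leaf, with ~10% noise terms,
  a sprinkling of IEA-coded rows the loader must discard, and
  molecular-function/cellular-component annotations to exercise the
  namespace filter.  One obsolete term is written to the OBO output.
* **GWAS**: about half the diseases "studied", each reporting ~60% of its
  genes.

What the generator does **not** emulate: the size (thousands of nodes) and
deep signature diversity of real interactomes, literature-driven
ascertainment bias, annotation depth heterogeneity, negative comorbidity
(protective associations), and identifier noise.  Passing tests therefore
demonstrate correctness of the computations and recoverability of planted
structure under realistic shapes — not expected effect sizes on real data,
where published AUCs for comparable analyses are nearer 0.7–0.85 than the
0.95+ seen on the clean fixture.

## Problem sizes and numerics

The reference study (700 proteins + 20 twins, 200 diseases, 19,900 pairs)
keeps the full test-suite at a few minutes: signature counting on the
scale-free fixture enumerates a few million induced subgraphs, and the
pairwise SigSim matrix over the ~300 network-resident disease genes is a
chunked dense computation.  The oracle-equivalence batch uses 100 random
graphs with up to 25 nodes, the scale at which exhaustive enumeration
stays cheap.  Scores are float64 throughout; equality tests on counts are
exact, on similarities at `pytest.approx` defaults.  Degenerate inputs
(empty graphs, empty gene sets, all-pleiotropic maps, degenerate
prevalences, saturated φ) return documented markers or raise early with
named errors rather than propagating NaNs silently.

## Known limitations

* The graphlet counter is pure Python; it is comfortable at desk scale
  (≤ ~2,000 nodes) but would need an ORCA-style combinatorial counter for
  full interactome work.
* Orbit dependency counts are derived from the catalogue by definition;
  no external table is bundled to cross-check them beyond the hand-checked
  anchors in the tests.
* The function measure inherits the instability of enrichment on very
  small universes; on fixtures with fewer than ~100 annotated genes its
  per-disease profiles are frequently empty.
* ICD-9 chapter boundaries are hard-coded to the standard 17+2 blocks;
  jurisdictional variants are not modelled.
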