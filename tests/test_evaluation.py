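import itertools
import math

import numpy as np
import pytest

from diseasim.evaluation import (
    ComorbidityRecord,
    category_score_test,
    comorbidity_labels,
    gwas_labels,
    icd9_chapter,
    load_comorbidity,
    phi_correlation,
    phi_t_statistic,
    randomized_baseline,
    roc,
    same_category,
)
from diseasim.similarity import SimilarityMatrix


def _sim(diseases, pair_scores):
    n = len(diseases)
    scores = np.full((n, n), np.nan)
    np.fill_diagonal(scores, 1.0)
    idx = {d: i for i, d in enumerate(diseases)}
    for (a, b), s in pair_scores.items():
        scores[idx[a], idx[b]] = scores[idx[b], idx[a]] = s
    return SimilarityMatrix(diseases=list(diseases), scores=scores, measure="test")


class TestIcd9Chapters:
    def test_endocrine_pair_same_chapter(self):
        assert same_category("250", "245") is True

    def test_endocrine_vs_circulatory(self):
        assert same_category("250", "401") is False

    def test_reflexive(self):
        assert same_category("428", "428") is True

    def test_e_and_v_codes(self):
        assert same_category("E850", "E930") is True
        assert same_category("V10", "E850") is False
        assert icd9_chapter("V10").startswith("supplementary")

    def test_unknown_code_named_in_error(self):
        with pytest.raises(ValueError, match="XYZ"):
            icd9_chapter("XYZ")


class TestCategoryScoreTest:
    def test_identical_distributions_give_flat_p(self):
        # same-chapter and different-chapter pairs with interleaved scores
        diseases = ["240", "241", "242", "400", "401"]
        scores = {}
        vals = iter([0.1, 0.5, 0.3, 0.2, 0.4, 0.35, 0.15, 0.45, 0.25, 0.05])
        for a, b in itertools.combinations(diseases, 2):
            scores[(a, b)] = next(vals)
        res = category_score_test(_sim(diseases, scores))
        assert 0.05 < res.p_value

    def test_perfect_separation_three_vs_three_exact(self):
        # 3 same-chapter scores all above 3 different-chapter scores:
        # one-sided exact p = 1 / C(6,3) = 0.05
        diseases = ["240", "241", "242", "400"]
        scores = {
            ("240", "241"): 0.9,
            ("240", "242"): 0.8,
            ("241", "242"): 0.7,
            ("240", "400"): 0.3,
            ("241", "400"): 0.2,
            ("242", "400"): 0.1,
        }
        res = category_score_test(_sim(diseases, scores))
        assert res.p_value == pytest.approx(1 / 20)
        assert res.n_same == 3 and res.n_diff == 3
        assert res.same_mean > res.diff_mean

    def test_p_matches_exact_u_enumeration(self):
        # brute-force the one-sided U null over all label permutations
        diseases = ["240", "241", "242", "400", "401"]
        rng = np.random.default_rng(3)
        scores = {p: float(rng.uniform()) for p in itertools.combinations(diseases, 2)}
        res = category_score_test(_sim(diseases, scores))
        same = [s for (a, b), s in scores.items() if same_category(a, b)]
        diff = [s for (a, b), s in scores.items() if not same_category(a, b)]
        pooled = same + diff
        n1 = len(same)

        def u_stat(group):
            return sum(
                1.0 if x > y else 0.5 if x == y else 0.0 for x in group for y in (set(pooled) - set(group)) or []
            )

        u_obs = sum(1.0 if x > y else 0.5 if x == y else 0.0 for x in same for y in diff)
        count = 0
        total = 0
        for combo in itertools.combinations(range(len(pooled)), n1):
            g1 = [pooled[i] for i in combo]
            g2 = [pooled[i] for i in range(len(pooled)) if i not in combo]
            u = sum(1.0 if x > y else 0.5 if x == y else 0.0 for x in g1 for y in g2)
            total += 1
            if u >= u_obs:
                count += 1
        assert res.p_value == pytest.approx(count / total)

    def test_planted_shift_detected(self):
        diseases = [f"{240 + i}" for i in range(5)] + [f"{400 + i}" for i in range(5)]
        rng = np.random.default_rng(0)
        scores = {}
        for a, b in itertools.combinations(diseases, 2):
            base = rng.uniform(0, 0.3)
            if same_category(a, b) and a.startswith("24") :
                base += 0.5
            scores[(a, b)] = base
        res = category_score_test(_sim(diseases, scores))
        assert res.p_value < 0.05

    def test_empty_group_is_an_error(self):
        diseases = ["240", "241"]
        with pytest.raises(ValueError):
            category_score_test(_sim(diseases, {("240", "241"): 0.5}))


class TestPhi:
    def test_perfect_cooccurrence(self):
        assert phi_correlation(10, 10, 10, 100) == pytest.approx(1.0)

    def test_independence_is_zero(self):
        assert phi_correlation(50, 100, 500, 1000) == pytest.approx(0.0)

    def test_closed_form_example(self):
        # (20*1000 - 100*50) / sqrt(100*50*900*950)
        assert phi_correlation(20, 100, 50, 1000) == pytest.approx(15000 / math.sqrt(4.275e9))

    def test_degenerate_prevalence_is_absent(self):
        assert math.isnan(phi_correlation(0, 0, 10, 100))
        assert math.isnan(phi_correlation(10, 100, 100, 100))

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_pearson_on_expanded_contingency_table(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(250):
            n = int(rng.integers(20, 200))
            p_i = int(rng.integers(1, n))
            p_j = int(rng.integers(1, n))
            c = int(rng.integers(max(0, p_i + p_j - n), min(p_i, p_j) + 1))
            x = np.zeros(n)
            y = np.zeros(n)
            x[:p_i] = 1
            y[:c] = 1
            y[p_i : p_i + (p_j - c)] = 1
            phi = phi_correlation(c, p_i, p_j, n)
            if math.isnan(phi):
                assert p_i in (0, n) or p_j in (0, n)
                continue
            assert phi == pytest.approx(np.corrcoef(x, y)[0, 1], abs=1e-10)


class TestTStatistic:
    def test_zero_phi(self):
        assert phi_t_statistic(0.0, 100, 50) == 0.0

    def test_direct_evaluation(self):
        assert phi_t_statistic(0.5, 27, 10) == pytest.approx(0.5 * 5 / math.sqrt(0.75))

    def test_significance_boundary_inclusive(self):
        # a phi exactly at t = 1.96 for n = 102 must be labelled positive
        n = 102
        phi = 1.96 / math.sqrt(n - 2 + 1.96**2)
        t = phi_t_statistic(phi, n, 50)
        assert t == pytest.approx(1.96)
        rec = ComorbidityRecord(a="100", b="200", phi=phi, t=t)
        assert comorbidity_labels([rec], phi_threshold=0.0) == {frozenset(("100", "200"))}

    def test_saturated_phi_gives_signed_infinity(self):
        assert phi_t_statistic(1.0, 100, 50) == math.inf
        assert phi_t_statistic(-1.0, 100, 50) == -math.inf


class TestComorbidityLabels:
    def test_threshold_rules(self):
        r1 = ComorbidityRecord(a="1", b="2", phi=0.07, t=2.5)
        r2 = ComorbidityRecord(a="1", b="3", phi=0.07, t=1.5)
        r3 = ComorbidityRecord(a="2", b="3", phi=0.05, t=9.0)
        labels = comorbidity_labels([r1, r2, r3], phi_threshold=0.06)
        assert labels == {frozenset(("1", "2"))}

    def test_threshold_sweep_is_nested(self, small_fixture):
        prev = None
        for thr in (0.02, 0.04, 0.06, 0.08, 0.10):
            labels = comorbidity_labels(small_fixture.comorbidity, thr)
            if prev is not None:
                assert labels <= prev
            prev = labels

    def test_load_comorbidity_counts_and_precomputed(self, tmp_path):
        p = tmp_path / "c.tsv"
        p.write_text("icd9_a\ticd9_b\tC_ij\tP_i\tP_j\tN\n100\t200\t20\t100\t50\t1000\n")
        (rec,) = load_comorbidity(p)
        assert rec.phi == pytest.approx(phi_correlation(20, 100, 50, 1000))
        assert rec.t == pytest.approx(phi_t_statistic(rec.phi, 100, 50))
        q = tmp_path / "pre.tsv"
        q.write_text("icd9_a\ticd9_b\tphi\tt\n100\t200\t0.07\t2.5\n")
        (rec2,) = load_comorbidity(q)
        assert rec2.phi == 0.07 and rec2.t == 2.5

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValueError):
            ComorbidityRecord.from_counts("1", "2", c_ij=60, p_i=50, p_j=100, n=1000)


class TestGwasLabels:
    def test_single_shared_gene(self):
        assert gwas_labels({"A": {"g1"}, "B": {"g1"}, "C": {"g2"}}) == {frozenset(("A", "B"))}

    def test_disjoint_tables_are_empty(self):
        assert gwas_labels({"A": {"g1"}, "B": {"g2"}}) == set()

    def test_matches_bruteforce_scan(self, small_fixture):
        table = small_fixture.gwas
        expected = set()
        for a in table:
            for b in table:
                if a < b and set(table[a]) & set(table[b]):
                    expected.add(frozenset((a, b)))
        assert gwas_labels(table) == expected


class TestRoc:
    def test_perfect_separation(self):
        sim = _sim(["a", "b", "c", "d"], {
            ("a", "b"): 0.9, ("a", "c"): 0.8, ("a", "d"): 0.7,
            ("b", "c"): 0.6, ("b", "d"): 0.5, ("c", "d"): 0.4,
        })
        res = roc(sim, {frozenset(("a", "b")), frozenset(("a", "c"))})
        assert res.auc == 1.0
        assert res.points[0] == (0.0, 0.0) and res.points[-1] == (1.0, 1.0)

    def test_three_of_four_concordant(self):
        sim = _sim(["a", "b", "c", "d"], {
            ("a", "b"): 0.9, ("c", "d"): 0.7,  # positives
            ("a", "c"): 0.8, ("b", "d"): 0.6,  # negatives
            ("a", "d"): np.nan, ("b", "c"): np.nan,
        })
        res = roc(sim, {frozenset(("a", "b")), frozenset(("c", "d"))})
        assert res.auc == pytest.approx(0.75)
        assert res.n_excluded == 2

    def test_all_ties_give_half(self):
        pairs = {p: 0.5 for p in [("a", "b"), ("a", "c"), ("b", "c")]}
        sim = _sim(["a", "b", "c"], pairs)
        res = roc(sim, {frozenset(("a", "b"))})
        assert res.auc == pytest.approx(0.5)

    def test_degenerate_labels_error(self):
        sim = _sim(["a", "b"], {("a", "b"): 0.5})
        with pytest.raises(ValueError):
            roc(sim, set())

    def test_min_genes_filter_restricts_pairs(self):
        sim = _sim(
            ["a", "b", "c", "d"],
            {("a", "b"): 0.9, ("a", "c"): 0.1, ("b", "c"): 0.2,
             ("a", "d"): 0.3, ("b", "d"): 0.4, ("c", "d"): 0.5},
        )
        dmap = {"a": {"g1", "g2"}, "b": {"g3", "g4"}, "c": {"g5", "g6"}, "d": {"g7"}}
        res = roc(sim, {frozenset(("a", "b"))}, dmap=dmap, min_genes=2)
        assert res.n_pos + res.n_neg == 3  # pairs touching d are filtered out
        res_all = roc(sim, {frozenset(("a", "b"))}, dmap=dmap, min_genes=1)
        assert res_all.n_pos + res_all.n_neg == 6

    @pytest.mark.parametrize("seed", range(3))
    def test_auc_matches_concordance_bruteforce(self, seed):
        rng = np.random.default_rng(seed)
        diseases = [f"d{i}" for i in range(15)]
        scores, positives = {}, set()
        for a, b in itertools.combinations(diseases, 2):
            scores[(a, b)] = float(rng.choice([0.1, 0.3, 0.3, 0.7, 0.9]))
            if rng.random() < 0.3:
                positives.add(frozenset((a, b)))
        sim = _sim(diseases, scores)
        res = roc(sim, positives)
        pos = [s for p, s in scores.items() if frozenset(p) in positives]
        neg = [s for p, s in scores.items() if frozenset(p) not in positives]
        conc = sum(1.0 if x > y else 0.5 if x == y else 0.0 for x in pos for y in neg)
        assert res.auc == pytest.approx(conc / (len(pos) * len(neg)))


class TestRandomizedBaseline:
    @pytest.fixture()
    def balanced(self):
        rng = np.random.default_rng(12)
        diseases = [f"d{i}" for i in range(25)]
        scores, positives = {}, set()
        for k, (a, b) in enumerate(itertools.combinations(diseases, 2)):
            scores[(a, b)] = float(rng.uniform())
            if k % 2:
                positives.add(frozenset((a, b)))
        return _sim(diseases, scores), positives

    def test_null_mean_near_half(self, balanced):
        sim, positives = balanced
        mean, sd = randomized_baseline(sim, positives, reps=30, seed=5)
        assert 0.45 <= mean <= 0.55
        assert sd >= 0.0

    def test_same_seed_reproduces(self, balanced):
        sim, positives = balanced
        assert randomized_baseline(sim, positives, reps=10, seed=9) == randomized_baseline(
            sim, positives, reps=10, seed=9
        )

    def test_resampling_variant_also_centred(self, balanced):
        sim, positives = balanced
        mean, _ = randomized_baseline(sim, positives, reps=30, seed=5, method="resample")
        assert 0.4 <= mean <= 0.6

    def test_too_few_reps_rejected(self, balanced):
        sim, positives = balanced
        with pytest.raises(ValueError):
            randomized_baseline(sim, positives, reps=1, seed=0)
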