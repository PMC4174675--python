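import math
from itertools import combinations

import networkx as nx
import numpy as np
import pytest

from diseasim.graphlet_counting import count_signatures
from diseasim.graphlet_similarity import signature_similarity
from diseasim.similarity import (
    all_sig,
    share_sig,
    sim_annotation,
    sim_function,
    sim_topology,
    similarity_matrix,
)


@pytest.fixture(scope="module")
def toy_net():
    """A small heterogeneous graph with precomputed signatures."""
    g = nx.Graph(
        [("a", "b"), ("b", "c"), ("c", "a"), ("c", "d"), ("d", "e"), ("e", "f"), ("f", "d"), ("b", "e")]
    )
    return count_signatures(g)


class TestAnnotationMeasure:
    def test_identity_disjoint_and_partial(self):
        assert sim_annotation({"a", "b"}, {"a", "b"}) == 1.0
        assert sim_annotation({"a"}, {"b"}) == 0.0
        assert sim_annotation({"a", "b"}, {"b", "c"}) == pytest.approx(1 / 3)

    def test_both_empty_is_absent(self):
        assert math.isnan(sim_annotation(set(), set()))

    def test_equal_iff_identical(self):
        assert sim_annotation({"x", "y"}, {"x", "y", "z"}) < 1.0


class TestFunctionMeasure:
    def test_identical_and_partial(self):
        assert sim_function({"T1"}, {"T1"}) == 1.0
        assert sim_function({"T1", "T2", "T3"}, {"T2", "T3", "T4"}) == 0.5

    def test_empty_side_scores_zero(self):
        assert sim_function(set(), {"T1"}) == 0.0
        assert sim_function(set(), set()) == 0.0


class TestTopologyMeasure:
    def test_shared_network_gene_saturates(self, toy_net):
        assert all_sig({"a", "b"}, {"b", "f"}, toy_net) == 1.0
        assert share_sig({"a", "b"}, {"b", "f"}, toy_net) == 1.0
        assert sim_topology({"a", "b"}, {"b", "f"}, toy_net) == 1.0

    def test_all_sig_is_max_over_cross_pairs(self, toy_net):
        # {a} vs {d, e}: a has degree 2, both d and e degree 3, so no pair
        # is topologically identical and the maximum stays below 1
        gi, gj = {"a"}, {"d", "e"}
        expected = max(
            signature_similarity(toy_net[u], toy_net[v]) for u in gi for v in gj
        )
        assert all_sig(gi, gj, toy_net) == pytest.approx(expected)
        assert expected < 1.0

    def test_share_sig_zero_without_shared_genes(self, toy_net):
        assert share_sig({"a"}, {"f"}, toy_net) == 0.0
        assert sim_topology({"a"}, {"f"}, toy_net) == pytest.approx(
            0.5 * all_sig({"a"}, {"f"}, toy_net)
        )

    def test_share_sig_exclude_identical_uses_distinct_pairs(self, toy_net):
        # single shared gene: nothing to compare once identical pairs are out
        assert share_sig({"a", "b"}, {"b", "f"}, toy_net, exclude_identical=True) == 0.0
        # two shared genes: the score is SigSim of that single distinct pair
        val = share_sig({"a", "b", "c"}, {"b", "c", "f"}, toy_net, exclude_identical=True)
        assert val == pytest.approx(signature_similarity(toy_net["b"], toy_net["c"]))

    def test_genes_absent_from_network_are_ignored(self, toy_net):
        assert all_sig({"a", "OFF1"}, {"b"}, toy_net) == all_sig({"a"}, {"b"}, toy_net)
        assert math.isnan(all_sig({"OFF1"}, {"b"}, toy_net))
        assert math.isnan(sim_topology({"OFF1"}, {"b"}, toy_net))

    def test_mean_of_terms(self, toy_net):
        gi, gj = {"a"}, {"f"}
        a = all_sig(gi, gj, toy_net)
        assert sim_topology(gi, gj, toy_net) == pytest.approx((a + 0.0) / 2)


class TestSimilarityMatrix:
    def test_matrix_matches_scalar_operations(self, toy_net):
        dmap = {"100": {"a", "b"}, "200": {"e", "f"}, "300": {"b", "c", "OFF"}}
        for measure, scalar in [
            ("annotation", lambda x, y: sim_annotation(dmap[x], dmap[y])),
            ("topology", lambda x, y: sim_topology(dmap[x], dmap[y], toy_net)),
        ]:
            sim = similarity_matrix(measure, dmap, signatures=toy_net)
            for i, j in combinations(range(3), 2):
                a, b = sim.diseases[i], sim.diseases[j]
                assert sim.scores[i, j] == pytest.approx(scalar(a, b))
                assert sim.scores[i, j] == sim.scores[j, i]

    def test_function_matrix(self, toy_net):
        dmap = {"100": {"a"}, "200": {"b"}}
        enriched = {"100": {"T1", "T2"}, "200": {"T2"}}
        sim = similarity_matrix("function", dmap, enriched=enriched)
        assert sim.scores[0, 1] == pytest.approx(0.5)

    def test_disease_order_is_deterministic_and_invariant(self, toy_net):
        d1 = {"300": {"a"}, "100": {"b"}, "200": {"c"}}
        d2 = {"100": {"b"}, "200": {"c"}, "300": {"a"}}
        s1 = similarity_matrix("topology", d1, signatures=toy_net)
        s2 = similarity_matrix("topology", d2, signatures=toy_net)
        assert s1.diseases == s2.diseases == ["100", "200", "300"]
        assert np.allclose(s1.scores, s2.scores, equal_nan=True)

    def test_single_disease(self, toy_net):
        sim = similarity_matrix("annotation", {"100": {"a"}})
        assert sim.scores.shape == (1, 1) and sim.scores[0, 0] == 1.0

    def test_resource_mismatch_is_an_error(self):
        with pytest.raises(ValueError):
            similarity_matrix("topology", {"100": {"a"}})
        with pytest.raises(ValueError):
            similarity_matrix("function", {"100": {"a"}})
        with pytest.raises(ValueError):
            similarity_matrix("flavour", {"100": {"a"}})

    def test_absent_marker_in_long_format(self, toy_net):
        dmap = {"100": {"OFF1"}, "200": {"a"}}
        sim = similarity_matrix("topology", dmap, signatures=toy_net)
        long = sim.to_long_frame()
        assert long["score"].isna().all()


class TestMeasureProperties:
    def test_all_measures_symmetric_and_bounded(self, small_fixture, toy_net):
        dmap = dict(list(small_fixture.dmap.items())[:8])
        sigs = count_signatures(small_fixture.graph)
        enriched = {d: set(list(g)[:2]) for d, g in dmap.items()}  # term sets stand-in
        for measure, kwargs in [
            ("annotation", {}),
            ("function", {"enriched": enriched}),
            ("topology", {"signatures": sigs}),
        ]:
            sim = similarity_matrix(measure, dmap, **kwargs)
            finite = sim.scores[~np.isnan(sim.scores)]
            assert ((finite >= -1e-12) & (finite <= 1 + 1e-12)).all()
            assert np.allclose(sim.scores, sim.scores.T, equal_nan=True)

    def test_sharing_pairs_score_at_least_half(self, small_fixture):
        sigs = count_signatures(small_fixture.graph)
        dmap = small_fixture.dmap
        sim = similarity_matrix("topology", dmap, signatures=sigs)
        for i, j in combinations(range(len(sim.diseases)), 2):
            a, b = sim.diseases[i], sim.diseases[j]
            shared_net = {g for g in dmap[a] & dmap[b] if g in sigs}
            score = sim.scores[i, j]
            if np.isnan(score):
                continue
            if shared_net:
                assert score >= 0.5
            else:
                assert score <= 0.5 + 1e-12  # AllSig/2 bound
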