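"""Threshold edge calling, network assembly, signed transitive simplification."""

import numpy as np
import networkx as nx
import pytest

from oracles import (
    call_edges_by_scan,
    signed_closure,
    transitive_reduction_by_paths,
)
from pertnet import (
    ReconstructionParams,
    RegulatoryEdge,
    SimulationConfig,
    build_network,
    call_regulations,
    consensus_stage,
    reconstruct_network,
    simplify_network,
    simulate_study,
)
from pertnet.profile_io import BiologicalReplicateMatrix
from pertnet.reconstruction import RegulatoryNetwork
from conftest import random_signed_dag, random_digraph


def make_matrix(values, perturbed="src", genes=None):
    values = np.atleast_2d(np.asarray(values, dtype=float))
    if genes is None:
        genes = [f"g{i}" for i in range(values.shape[0])]
    return BiologicalReplicateMatrix(
        perturbation_id="P0", perturbed_gene=perturbed, gene_ids=genes, values=values
    )


def net_from_edges(edges: dict) -> RegulatoryNetwork:
    g = nx.DiGraph()
    for (u, v), s in edges.items():
        g.add_edge(u, v, sign=s, magnitude=5.0, support=1, conflict=False)
    return RegulatoryNetwork(graph=g, perturbed_genes=frozenset(u for u, _ in edges))


class TestCallRegulations:
    def test_threshold_crossing_in_one_replicate_calls_edge(self):
        edges = call_regulations(make_matrix([[3.9, 4.1]]), ReconstructionParams())
        assert len(edges) == 1
        e = edges[0]
        assert (e.target, e.sign, e.support) == ("g0", 1, 1)
        assert e.magnitude == pytest.approx(4.1)

    def test_subthreshold_values_call_nothing(self):
        m = make_matrix([[3.99, -3.2], [0.0, 1.0]])
        assert call_regulations(m, ReconstructionParams()) == []

    def test_conflicting_signs_resolved_by_magnitude(self):
        edges = call_regulations(make_matrix([[-5.0, 4.5]]), ReconstructionParams())
        e = edges[0]
        assert (e.sign, e.support, e.conflict) == (-1, 2, True)
        assert e.magnitude == pytest.approx(5.0)

    def test_self_target_excluded_by_default_included_on_request(self):
        m = make_matrix([[6.0, 6.0], [5.0, 5.0]], perturbed="g0")
        default = call_regulations(m, ReconstructionParams())
        assert [e.target for e in default] == ["g1"]
        kept = call_regulations(m, ReconstructionParams(exclude_self=False))
        assert sorted(e.target for e in kept) == ["g0", "g1"]

    def test_selected_replicate_only_rule(self):
        m = make_matrix([[4.5, 0.0], [0.0, 4.5]])
        params = ReconstructionParams(rule="selected_replicate_only")
        edges = call_regulations(m, params, selected_index=1)
        assert [e.target for e in edges] == ["g1"]
        with pytest.raises(ValueError, match="selected_index"):
            call_regulations(m, params)

    def test_matches_exhaustive_scan_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(30):
            X = rng.normal(scale=3.0, size=(15, 3))
            m = make_matrix(X, perturbed="g3")
            got = sorted(
                (e.target, e.sign, e.magnitude, e.support)
                for e in call_regulations(m, ReconstructionParams())
            )
            expected = sorted(call_edges_by_scan(m.gene_ids, "g3", X, 4.0))
            assert [(t, s, sup) for t, s, _, sup in got] == [
                (t, s, sup) for t, s, _, sup in expected
            ]
            assert np.allclose(
                [mag for *_, mag, _ in got], [mag for *_, mag, _ in expected]
            )

    def test_monotone_in_theta(self):
        rng = np.random.default_rng(1)
        X = rng.normal(scale=3.0, size=(40, 4))
        m = make_matrix(X)
        at4 = {(e.target, e.sign) for e in call_regulations(m, ReconstructionParams(theta=4))}
        at5 = {(e.target, e.sign) for e in call_regulations(m, ReconstructionParams(theta=5))}
        assert at5 <= at4

    def test_invariant_to_replicate_column_permutation(self):
        rng = np.random.default_rng(2)
        X = rng.normal(scale=3.0, size=(20, 4))
        perm = X[:, rng.permutation(4)]
        key = lambda m: {
            (e.target, e.sign, e.magnitude, e.support)
            for e in call_regulations(make_matrix(m), ReconstructionParams())
        }
        assert key(X) == key(perm)


class TestBuildNetwork:
    def test_two_perturbations_two_edges(self):
        e1 = RegulatoryEdge("a", "x", 1, 5.0, 1)
        e2 = RegulatoryEdge("b", "y", -1, 4.5, 2)
        net = build_network([[e1], [e2]], perturbed_genes=["a", "b"])
        assert net.n_edges == 2
        assert net.signed_edges() == {("a", "x", 1), ("b", "y", -1)}

    def test_duplicate_edges_merge_idempotently(self):
        e = RegulatoryEdge("a", "x", 1, 5.0, 1)
        net = build_network([[e], [e]], perturbed_genes=["a"])
        assert net.n_edges == 1
        assert net.graph["a"]["x"]["magnitude"] == pytest.approx(5.0)

    def test_merge_keeps_larger_magnitude_and_records_conflict(self):
        up = RegulatoryEdge("a", "x", 1, 4.2, 1)
        down = RegulatoryEdge("a", "x", -1, 6.0, 1)
        net = build_network([[up], [down]], perturbed_genes=["a"])
        d = net.graph["a"]["x"]
        assert d["sign"] == -1 and d["magnitude"] == pytest.approx(6.0)
        assert d["conflict"]

    def test_perturbed_genes_without_calls_stay_as_nodes(self):
        net = build_network([[]], perturbed_genes=["lonely"])
        assert "lonely" in net.graph

    def test_edge_set_invariant_to_perturbation_order(self):
        e1 = RegulatoryEdge("a", "x", 1, 5.0, 1)
        e2 = RegulatoryEdge("b", "x", -1, 4.5, 1)
        n1 = build_network([[e1], [e2]], perturbed_genes=["a", "b"])
        n2 = build_network([[e2], [e1]], perturbed_genes=["b", "a"])
        assert n1.signed_edges() == n2.signed_edges()


class TestRecovery:
    def test_zero_noise_recovers_planted_edges_and_signs_exactly(self):
        cfg = SimulationConfig(
            n_genes=40, n_perturbations=10, edge_density=0.15,
            effect_size=8.0, noise_sd=1e-9, seed=2,
        )
        study = simulate_study(cfg)
        net = reconstruct_network(consensus_stage(study.profiles))
        assert net.signed_edges() == study.truth.signed_edges()

    def test_planted_recovery_high_precision_recall(self):
        cfg = SimulationConfig(
            n_genes=50, n_perturbations=20, edge_density=0.1,
            effect_size=8.0, noise_sd=0.5, seed=4,
        )
        study = simulate_study(cfg)
        net = reconstruct_network(consensus_stage(study.profiles))
        truth = study.truth.signed_edges()
        found = net.signed_edges()
        tp = len(truth & found)
        assert tp / len(found) >= 0.95
        assert tp / len(truth) >= 0.95


class TestSimplify:
    def test_canonical_transitive_triple_removed(self):
        net = net_from_edges({("a", "b"): 1, ("b", "c"): 1, ("a", "c"): 1})
        out = simplify_network(net)
        assert out.signed_edges() == {("a", "b", 1), ("b", "c", 1)}

    def test_sign_mismatch_retains_edge(self):
        net = net_from_edges({("a", "b"): 1, ("b", "c"): 1, ("a", "c"): -1})
        out = simplify_network(net)
        assert out.n_edges == 3

    def test_cycle_edges_not_self_explained(self):
        # a 3-cycle offers no alternative explanation for any of its edges
        net = net_from_edges({("a", "b"): 1, ("b", "c"): 1, ("c", "a"): 1})
        assert simplify_network(net).n_edges == 3

    def test_never_adds_edges_and_is_idempotent(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            _, edges = random_digraph(rng, max_nodes=6, signed=True)
            net = net_from_edges(edges)
            once = simplify_network(net)
            assert set(once.graph.edges) <= set(net.graph.edges)
            twice = simplify_network(once)
            assert set(twice.graph.edges) == set(once.graph.edges)

    def test_signed_reachability_preserved_on_cyclic_graphs(self):
        rng = np.random.default_rng(6)
        for _ in range(40):
            nodes, edges = random_digraph(rng, max_nodes=5, signed=True)
            net = net_from_edges(edges)
            out = simplify_network(net)
            kept = {
                (u, v): d["sign"] for u, v, d in out.graph.edges(data=True)
            }
            assert signed_closure(nodes, kept) == signed_closure(nodes, edges)

    def test_matches_path_enumeration_oracle_on_signed_dags(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            _, edges = random_signed_dag(rng, max_nodes=6)
            net = net_from_edges(edges)
            got = {
                (u, v): d["sign"]
                for u, v, d in simplify_network(net).graph.edges(data=True)
            }
            assert got == transitive_reduction_by_paths(edges)
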