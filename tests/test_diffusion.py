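"""Biased heterogeneous walk: transition matrix, profiles, TI ranking."""

import networkx as nx
import numpy as np
import pytest

from toxnet.diffusion import (
    build_transition_matrix,
    diffusion_profile,
    raw_transition_entries,
    top_k_by_ti,
    treatment_importance,
)
from toxnet.errors import ValidationError
from toxnet.graphs import HeterogeneousNetwork, WeightedInteractome
from toxnet.propagation import make_priors, propagate_raw
from toxnet.synthetic_data import DISEASE_NODE, DRUG_NODE

from conftest import random_interactome


def hetnet_of(node_types, edges, type_weights=None):
    g = nx.Graph()
    for n, t in node_types.items():
        g.add_node(n, type=t)
    for a, b, c in edges:
        g.add_edge(a, b, confidence=c)
    return HeterogeneousNetwork(g, type_weights or {})


@pytest.fixture
def four_node_hetnet():
    """Centre node with 2 protein neighbours (u=0.5) and 1 process (u=0.4)."""
    return hetnet_of(
        {"c": "protein", "p1": "protein", "p2": "protein", "bp": "biological_process"},
        [("c", "p1", 0.5), ("c", "p2", 0.5), ("c", "bp", 0.4)],
    )


class TestTransitionMatrix:
    def test_raw_entries_follow_type_formula(self, four_node_hetnet):
        raw = raw_transition_entries(four_node_hetnet, "c")
        assert raw == pytest.approx({"p1": 0.25, "p2": 0.25, "bp": 0.4})

    def test_normalized_row(self, four_node_hetnet):
        tm = build_transition_matrix(four_node_hetnet)
        i = tm.index["c"]
        row = dict(zip(tm.nodes, tm.matrix[i].toarray().ravel()))
        assert row["p1"] == pytest.approx(0.25 / 0.9)
        assert row["bp"] == pytest.approx(0.4 / 0.9)

    def test_doubling_type_weight_doubles_raw_mass(self, four_node_hetnet):
        four_node_hetnet.type_weights["biological_process"] = 2.0
        raw = raw_transition_entries(four_node_hetnet, "c")
        assert raw["bp"] == pytest.approx(0.8)

    def test_uniform_weights_and_confidences_split_evenly_within_type(self):
        net = hetnet_of(
            {"c": "protein", "a": "protein", "b": "protein", "x": "drug"},
            [("c", "a", 0.6), ("c", "b", 0.6), ("c", "x", 0.6)],
        )
        raw = raw_transition_entries(net, "c")
        assert raw["a"] == raw["b"] == pytest.approx(0.3)
        assert raw["x"] == pytest.approx(0.6)

    def test_rows_stochastic_on_randomized_fixtures(self):
        """1,000 randomized heterogeneous graphs: every row sums to 1."""
        rng = np.random.default_rng(0)
        types = ["protein", "drug", "disease", "biological_process"]
        for _ in range(1000):
            n = int(rng.integers(4, 12))
            node_types = {f"n{i}": types[int(rng.integers(4))] for i in range(n)}
            g = nx.gnp_random_graph(n, 0.5, seed=int(rng.integers(2**31 - 1)))
            g = nx.relabel_nodes(g, {i: f"n{i}" for i in g.nodes()})
            for a, b in g.edges():
                g[a][b]["confidence"] = float(rng.uniform(0.05, 1.0))
            for node, t in node_types.items():
                if not g.has_node(node):
                    g.add_node(node)
                g.nodes[node]["type"] = t
            weights = {t: float(rng.uniform(0.2, 3.0)) for t in types}
            tm = build_transition_matrix(HeterogeneousNetwork(g, weights))
            sums = np.asarray(tm.matrix.sum(axis=1)).ravel()
            nonzero = [i for i, node in enumerate(tm.nodes) if node not in tm.dangling]
            assert np.all(np.abs(sums[nonzero] - 1.0) < 1e-12)

    def test_isolated_node_flagged_dangling(self):
        net = hetnet_of({"a": "protein", "b": "protein", "x": "drug"}, [("a", "b", 0.5)])
        tm = build_transition_matrix(net)
        assert tm.dangling == {"x"}


class TestDiffusionProfile:
    def test_two_node_closed_form(self):
        net = hetnet_of({"a": "protein", "b": "protein"}, [("a", "b", 0.7)])
        prof = diffusion_profile(build_transition_matrix(net), "a", restart=0.5)
        assert prof.visitation["a"] == pytest.approx(2 / 3, abs=1e-9)
        assert prof.visitation["b"] == pytest.approx(1 / 3, abs=1e-9)

    def test_restart_near_one_concentrates_on_start(self):
        net = hetnet_of({"a": "protein", "b": "protein"}, [("a", "b", 0.7)])
        prof = diffusion_profile(build_transition_matrix(net), "a", restart=0.999)
        assert prof.visitation["a"] > 0.998

    def test_matches_dense_linear_solve(self):
        """Oracle: solve (I − (1−r)Mᵀ)v = r·e directly on a 50-node fixture."""
        rng = np.random.default_rng(5)
        inter = random_interactome(50, 0.1, rng)
        g = inter.graph
        for n in g.nodes():
            g.nodes[n]["type"] = "protein"
        tm = build_transition_matrix(HeterogeneousNetwork(g))
        start = tm.nodes[0]
        r = 0.5
        M = tm.matrix.toarray()
        e = np.zeros(len(tm.nodes))
        e[0] = 1.0
        v_exact = np.linalg.solve(np.eye(len(e)) - (1 - r) * M.T, r * e)
        prof = diffusion_profile(tm, start, restart=r, tol=1e-14)
        v = np.array([prof.visitation[n] for n in tm.nodes])
        assert np.max(np.abs(v - v_exact)) < 1e-10

    def test_mass_conserved(self, scenario0):
        tm = build_transition_matrix(scenario0.hetnet)
        prof = diffusion_profile(tm, DRUG_NODE)
        assert sum(prof.visitation.values()) == pytest.approx(1.0, abs=1e-9)

    def test_unknown_start_rejected(self, four_node_hetnet):
        with pytest.raises(ValidationError):
            diffusion_profile(build_transition_matrix(four_node_hetnet), "ghost")

    def test_equals_homogeneous_rwr_on_all_protein_network(self):
        """Cross-module consistency: with equal type weights on an
        all-protein graph, the biased walk reduces to plain RWR."""
        rng = np.random.default_rng(9)
        inter = random_interactome(30, 0.15, rng)
        g = inter.graph
        for n in g.nodes():
            g.nodes[n]["type"] = "protein"
        tm = build_transition_matrix(HeterogeneousNetwork(g))
        start = tm.nodes[0]
        prof = diffusion_profile(tm, start, restart=0.3, tol=1e-14)
        # RWR with a delta prior on the start node: identical linear system
        priors = {n: (1.0 if n == start else 0.0) for n in inter.sorted_nodes()}
        # note: row-normalized Mᵀ equals column-normalized W only when the
        # walk uses per-row normalization over identical weights — on an
        # unweighted-type graph both reduce to u_ij / strength
        rwr = propagate_raw(inter, priors, restart=0.3, tol=1e-14)
        for n in priors:
            assert prof.visitation[n] == pytest.approx(rwr[n], abs=1e-9)


class TestTreatmentImportance:
    def test_elementwise_product_and_symmetry(self):
        net = hetnet_of({"a": "protein", "b": "protein"}, [("a", "b", 0.7)])
        tm = build_transition_matrix(net)
        pa = diffusion_profile(tm, "a")
        pb = diffusion_profile(tm, "b")
        ti = treatment_importance(pa, pb)
        assert ti["a"] == pytest.approx(pa.visitation["a"] * pb.visitation["a"])
        assert treatment_importance(pb, pa) == ti

    def test_universe_mismatch_rejected(self):
        net1 = hetnet_of({"a": "protein", "b": "protein"}, [("a", "b", 0.7)])
        net2 = hetnet_of({"a": "protein", "c": "protein"}, [("a", "c", 0.7)])
        p1 = diffusion_profile(build_transition_matrix(net1), "a")
        p2 = diffusion_profile(build_transition_matrix(net2), "a")
        with pytest.raises(ValidationError):
            treatment_importance(p1, p2)


class TestTopK:
    TYPES = {"a": "protein", "b": "protein", "c": "protein", "bp": "biological_process"}

    def test_k_larger_than_universe_returns_all_positive(self):
        ti = {"a": 0.3, "b": 0.2, "c": 0.0}
        res = top_k_by_ti(ti, k=10, node_types=self.TYPES)
        assert res.genes == {"a", "b"}  # zero-TI node excluded

    def test_tie_at_boundary_broken_by_node_id(self):
        ti = {"a": 0.5, "b": 0.2, "c": 0.2}
        res = top_k_by_ti(ti, k=2, node_types=self.TYPES)
        assert res.genes == {"a", "b"}

    def test_k_one_is_argmax(self):
        ti = {"a": 0.1, "b": 0.9}
        assert top_k_by_ti(ti, k=1, node_types=self.TYPES).genes == {"b"}

    def test_type_filter_excludes_processes(self):
        ti = {"a": 0.1, "bp": 0.9}
        assert top_k_by_ti(ti, k=5, node_types=self.TYPES).genes == {"a"}


class TestParameterRecovery:
    def test_mechanism_genes_rank_in_topk_on_scenario(self, scenario0):
        """≥80% of planted mechanism genes in the top-k TI proteins,
        k = 3 × |planted ∪ seeds|."""
        tm = build_transition_matrix(scenario0.hetnet)
        drug = diffusion_profile(tm, DRUG_NODE)
        disease = diffusion_profile(tm, DISEASE_NODE)
        ti = treatment_importance(drug, disease)
        k = 3 * len(scenario0.planted_mechanism | scenario0.seed_genes)
        top = top_k_by_ti(ti, k=k, node_types=tm.node_types).genes
        frac = len(top & scenario0.planted_mechanism) / len(scenario0.planted_mechanism)
        assert frac >= 0.8
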