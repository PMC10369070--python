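"""Enrichment stack: hypergeometric tests, elim, similarity, clustering."""

import math

import numpy as np
import pytest

from toxnet.enrichment import (
    AnnotationDB,
    TermCluster,
    bh_adjust,
    cluster_terms,
    enrich_classic,
    enrich_elim,
    filter_clusters_by_size,
    filter_significant,
    jaccard,
    null_calibration,
    semantic_similarity,
)
from toxnet.errors import ValidationError
from toxnet.synthetic_data import generate_annotation_dag


def exact_tail(k, N, K, n):
    """Independent oracle: hypergeometric upper tail by full summation."""
    return sum(
        math.comb(K, i) * math.comb(N - K, n - i) / math.comb(N, n)
        for i in range(k, min(K, n) + 1)
    )


@pytest.fixture
def flat_db():
    """Root plus three disjoint leaves over a 100-gene corpus."""
    leaves = {
        "L1": {f"g{i}" for i in range(0, 20)},
        "L2": {f"g{i}" for i in range(20, 50)},
        "L3": {f"g{i}" for i in range(50, 100)},
    }
    return AnnotationDB(
        {**leaves, "root": set()},
        [("L1", "root"), ("L2", "root"), ("L3", "root")],
    )


BACKGROUND = {f"g{i}" for i in range(100)}


class TestAnnotationDB:
    def test_cycle_rejected(self):
        with pytest.raises(ValidationError, match="cycle"):
            AnnotationDB({}, [("A", "B"), ("B", "A")])

    def test_multiple_roots_rejected(self):
        with pytest.raises(ValidationError, match="single root"):
            AnnotationDB({}, [("A", "R1"), ("A", "R2")])

    def test_true_path_propagation(self, flat_db):
        assert flat_db.genes("root") == BACKGROUND

    def test_information_content_of_root_is_zero(self, flat_db):
        assert flat_db.information_content("root") == 0.0


class TestClassicEnrichment:
    def test_matches_exact_tail_oracle(self, flat_db):
        study = {f"g{i}" for i in range(10)}  # 10 of L1's 20 genes
        table = enrich_classic(study, BACKGROUND, flat_db)
        got = dict(zip(table["term"], table["p_value"]))
        assert got["L1"] == pytest.approx(exact_tail(10, 100, 20, 10), abs=1e-12)
        assert got["L2"] == pytest.approx(exact_tail(0, 100, 30, 10), abs=1e-12)
        assert got["root"] == pytest.approx(1.0, abs=1e-12)

    def test_oracle_agreement_on_random_fixtures(self):
        rng = np.random.default_rng(1)
        genes = {f"g{i}" for i in range(80)}
        db, _ = generate_annotation_dag(12, genes=genes, rng_seed=4)
        bg = sorted(genes)
        for _ in range(10):
            study = {bg[i] for i in rng.choice(len(bg), size=15, replace=False)}
            table = enrich_classic(study, genes, db)
            for _, row in table.iterrows():
                pop = db.genes(row["term"]) & genes
                expected = exact_tail(len(pop & study), len(genes), len(pop), len(study))
                assert row["p_value"] == pytest.approx(expected, abs=1e-12)

    def test_small_terms_excluded(self):
        db = AnnotationDB(
            {"small": {"g0", "g1", "g2", "g3"}, "big": {f"g{i}" for i in range(20)}, "root": set()},
            [("small", "root"), ("big", "root")],
        )
        table = enrich_classic({"g0"}, BACKGROUND, db, min_annotated=5)
        assert "small" not in set(table["term"])
        assert "big" in set(table["term"])

    def test_empty_study_rejected(self, flat_db):
        with pytest.raises(ValidationError):
            enrich_classic(set(), BACKGROUND, flat_db)

    def test_study_outside_background_rejected(self, flat_db):
        with pytest.raises(ValidationError):
            enrich_classic({"zz"}, BACKGROUND, flat_db)

    def test_null_calibration(self, flat_db):
        """Random study sets: ≤2% of term tests significant at 0.01."""
        frac = null_calibration(
            flat_db, BACKGROUND, study_size=10, n_sims=1000,
            rng=np.random.default_rng(0),
        )
        assert frac <= 0.02


class TestElim:
    def test_threshold_zero_equals_classic(self, flat_db):
        study = {f"g{i}" for i in range(10)}
        classic = enrich_classic(study, BACKGROUND, flat_db)
        elim = enrich_elim(study, BACKGROUND, flat_db, elim_threshold=0.0)
        assert list(classic["term"]) == list(elim["term"])
        assert np.allclose(classic["p_value"], elim["p_value"])

    def test_threshold_zero_equals_classic_on_random_dags(self):
        rng = np.random.default_rng(2)
        genes = {f"g{i}" for i in range(60)}
        for seed in range(5):
            db, _ = generate_annotation_dag(10, genes=genes, rng_seed=seed)
            study = {sorted(genes)[i] for i in rng.choice(60, size=12, replace=False)}
            classic = enrich_classic(study, genes, db)
            elim = enrich_elim(study, genes, db, elim_threshold=0.0)
            assert dict(zip(classic["term"], classic["p_value"])) == pytest.approx(
                dict(zip(elim["term"], elim["p_value"]))
            )

    def test_significant_leaf_empties_its_parent(self):
        """When a significant leaf holds the parent's whole study overlap,
        the parent's study count drops to 0 and its p-value to 1."""
        leaf = {f"g{i}" for i in range(8)}
        db = AnnotationDB(
            {"leaf": leaf, "mid": set(), "other": {f"g{i}" for i in range(40, 60)}, "root": set()},
            [("leaf", "mid"), ("mid", "root"), ("other", "root")],
        )
        study = set(leaf)
        table = enrich_elim(study, BACKGROUND, db, elim_threshold=0.01)
        rows = {r["term"]: r for _, r in table.iterrows()}
        assert rows["leaf"].p_value < 0.01
        assert rows["mid"].study_count == 0
        assert rows["mid"].p_value == pytest.approx(1.0)


class TestFilterSignificant:
    def test_boundary_strictly_below(self, flat_db):
        import pandas as pd
        table = pd.DataFrame({
            "term": ["a", "b", "c"],
            "p_value": [0.01, 0.0099, 0.5],
        })
        assert filter_significant(table, 0.01) == ["b"]

    def test_empty_table(self):
        import pandas as pd
        assert filter_significant(pd.DataFrame(columns=["term", "p_value"])) == []


class TestSemanticSimilarity:
    def test_self_similarity_is_one(self, flat_db):
        assert semantic_similarity("L1", "L1", flat_db) == 1.0

    def test_root_vs_anything_is_zero(self, flat_db):
        assert semantic_similarity("root", "L1", flat_db) == 0.0

    def test_chain_with_equal_counts_gives_one(self, chain_db):
        # root(100) → A(10) → B(10): IC(A)=IC(B), MICA=A ⇒ similarity 1
        assert semantic_similarity("A", "B", chain_db) == pytest.approx(1.0)

    def test_disjoint_leaves_share_only_root(self, flat_db):
        assert semantic_similarity("L1", "L2", flat_db) == 0.0

    def test_unknown_term_rejected(self, flat_db):
        with pytest.raises(KeyError):
            semantic_similarity("L1", "ghost", flat_db)


class TestClusterTerms:
    def make_table(self, terms, pvals):
        import pandas as pd
        return pd.DataFrame({"term": terms, "p_value": pvals})

    def test_zero_similarity_gives_singletons(self, flat_db):
        table = self.make_table(["L1", "L2", "L3"], [0.001, 0.002, 0.003])
        clusters = cluster_terms(["L1", "L2", "L3"], table, flat_db, sim_threshold=0.7)
        assert sorted(len(c.members) for c in clusters) == [1, 1, 1]

    def test_identical_semantics_give_one_cluster(self, chain_db):
        table = self.make_table(["A", "B"], [0.002, 0.001])
        clusters = cluster_terms(["A", "B"], table, chain_db, sim_threshold=0.7)
        assert len(clusters) == 1
        assert clusters[0].representative == "B"  # lowest p

    def test_output_partitions_input(self, flat_db):
        table = self.make_table(["L1", "L2", "L3"], [0.01, 0.001, 0.001])
        clusters = cluster_terms(["L1", "L2", "L3"], table, flat_db)
        seen = [t for c in clusters for t in c.members]
        assert sorted(seen) == ["L1", "L2", "L3"]


class TestClusterSizeFilter:
    def test_boundary_inclusive(self):
        c3 = TermCluster("a", frozenset({"a", "b", "c"}))
        c2 = TermCluster("x", frozenset({"x", "y"}))
        assert filter_clusters_by_size([c3, c2], 3) == [c3]

    def test_empty_input(self):
        assert filter_clusters_by_size([], 3) == []


class TestJaccard:
    def test_known_value(self):
        assert jaccard({1, 2, 3}, {2, 3, 4}) == 0.5

    def test_identity_and_disjoint(self):
        assert jaccard({1, 2}, {1, 2}) == 1.0
        assert jaccard({1}, {2}) == 0.0

    def test_symmetry(self):
        a, b = {1, 2, 5}, {2, 7}
        assert jaccard(a, b) == jaccard(b, a)

    def test_two_empty_sets_warn_and_give_zero(self, caplog):
        with caplog.at_level("WARNING"):
            assert jaccard(set(), set()) == 0.0


class TestBH:
    def test_monotone_and_bounded(self):
        p = np.array([0.001, 0.02, 0.02, 0.8])
        q = bh_adjust(p)
        assert np.all(q >= p - 1e-15) and np.all(q <= 1.0)
        assert q[0] == pytest.approx(0.004)
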