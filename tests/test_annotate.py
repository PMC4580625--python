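import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.metrics import adjusted_rand_score

from immunomod.annotate import (
    NO_TERM,
    annotate_collection,
    cluster_modules,
    hypergeom_enrichment,
    overlap_fraction,
    overlap_matrix,
)
from immunomod.datatypes import GeneModule, GeneSetCollection, ModuleCollection
from oracles import bh_fdr, hypergeom_by_enumeration


def make_module(name, genes):
    return GeneModule(name=name, marker=name, members=list(genes))


def block_collection(n_blocks=5, per_block=3, size=10):
    """Modules in planted blocks: same-block modules share all genes."""
    modules, labels = [], []
    for b in range(n_blocks):
        genes = [f"B{b}G{i}" for i in range(size)]
        for j in range(per_block):
            modules.append(make_module(f"mod_b{b}_{j}", genes))
            labels.append(b)
    return ModuleCollection(modules), labels


class TestOverlapFraction:
    def test_identical_modules_give_one(self):
        a = make_module("a", ["g1", "g2", "g3", "g4"])
        assert overlap_fraction(a, a) == 1.0

    def test_quarter_overlap_at_cluster_edge_threshold(self):
        a = make_module("a", [f"x{i}" for i in range(75)] + [f"s{i}" for i in range(25)])
        b = make_module("b", [f"y{i}" for i in range(75)] + [f"s{i}" for i in range(25)])
        assert overlap_fraction(a, b) == 0.25

    def test_disjoint_modules_give_zero(self):
        a = make_module("a", ["g1", "g2"])
        b = make_module("b", ["h1", "h2"])
        assert overlap_fraction(a, b) == 0.0

    def test_unequal_sizes_rejected(self):
        with pytest.raises(ValueError, match="equal sizes"):
            overlap_fraction(make_module("a", ["g1"]),
                             make_module("b", ["g1", "g2"]))


class TestOverlapMatrix:
    def test_symmetric_unit_diagonal(self, module_collection):
        m = overlap_matrix(module_collection)
        assert np.allclose(m, m.T)
        assert np.allclose(np.diag(m), 1.0)
        assert ((m.to_numpy() >= 0) & (m.to_numpy() <= 1)).all()


class TestClusterModules:
    def test_perfect_separation_auto_k(self):
        coll, labels = block_collection(n_blocks=2, per_block=4)
        assignment = cluster_modules(overlap_matrix(coll), k="auto")
        assert assignment.n_clusters == 2
        assert adjusted_rand_score(labels, assignment.labels.to_numpy()) == 1.0

    def test_k_equal_n_gives_singletons(self):
        coll, _ = block_collection(n_blocks=2, per_block=2)
        assignment = cluster_modules(overlap_matrix(coll), k=4)
        assert assignment.n_clusters == 4

    def test_planted_five_blocks_recovered_exactly(self):
        coll, labels = block_collection(n_blocks=5, per_block=3)
        assignment = cluster_modules(overlap_matrix(coll), k="auto")
        assert adjusted_rand_score(labels, assignment.labels.to_numpy()) == 1.0

    def test_k_above_n_rejected(self):
        coll, _ = block_collection(n_blocks=2, per_block=2)
        with pytest.raises(ValueError, match="exceeds"):
            cluster_modules(overlap_matrix(coll), k=10)

    def test_cluster_ids_contiguous_from_one(self):
        # maxclust cuts may return fewer clusters than requested when merge
        # heights tie; ids must stay contiguous from 1 regardless
        coll, _ = block_collection(n_blocks=3, per_block=2)
        for k in (2, 3, 5):
            assignment = cluster_modules(overlap_matrix(coll), k=k)
            assert sorted(assignment.labels.unique()) == \
                list(range(1, assignment.n_clusters + 1))


class TestHypergeomEnrichment:
    def test_no_overlap_gives_p_one(self):
        assert hypergeom_enrichment({"A"}, {"B"}, {"A", "B", "C"}) == 1.0

    def test_two_of_two_in_universe_of_four(self):
        # 1 of the C(4,2)=6 equally likely draws contains both annotated genes
        p = hypergeom_enrichment({"A", "B"}, {"A", "B"}, {"A", "B", "C", "D"})
        assert p == pytest.approx(1 / 6)

    def test_module_equal_to_universe(self):
        u = {"A", "B", "C"}
        assert hypergeom_enrichment(u, {"A", "B"}, u) == 1.0

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError, match="universe"):
            hypergeom_enrichment({"A"}, {"A"}, set())

    @pytest.mark.parametrize("universe_size,module_size,set_size", [
        (6, 2, 3), (8, 3, 4), (10, 4, 5), (12, 5, 6), (12, 3, 9),
    ])
    def test_matches_exhaustive_enumeration(self, universe_size, module_size,
                                            set_size):
        universe = {f"g{i}" for i in range(universe_size)}
        rng = np.random.default_rng(universe_size * 100 + module_size)
        genes = sorted(universe)
        for _ in range(5):
            module = set(rng.choice(genes, size=module_size, replace=False))
            ann = set(rng.choice(genes, size=set_size, replace=False))
            expected = hypergeom_by_enumeration(module, ann, universe)
            assert hypergeom_enrichment(module, ann, universe) == \
                pytest.approx(expected, abs=1e-12)


class TestAnnotateCollection:
    @pytest.fixture
    def setup(self):
        universe = {f"g{i}" for i in range(60)}
        modules = ModuleCollection([
            make_module("m1", [f"g{i}" for i in range(10)]),
            make_module("m2", [f"g{i}" for i in range(10, 20)]),
        ])
        refs = [GeneSetCollection({
            "setA": [f"g{i}" for i in range(10)],
            "setB": [f"g{i}" for i in range(10, 20)],
            "setC": [f"g{i}" for i in range(40, 60)],
        }, source="refdb")]
        return modules, refs, universe

    def test_identical_set_is_top_term(self, setup):
        modules, refs, universe = setup
        result = annotate_collection(modules, refs, universe)
        assert result.top_terms.loc["m1", "refdb"] == "setA"
        assert result.top_terms.loc["m2", "refdb"] == "setB"

    def test_bh_single_test_equals_p(self):
        universe = {f"g{i}" for i in range(20)}
        modules = ModuleCollection([make_module("m", [f"g{i}" for i in range(5)])])
        refs = [GeneSetCollection({"s": [f"g{i}" for i in range(5)]}, source="r")]
        result = annotate_collection(modules, refs, universe)
        row = result.table.iloc[0]
        assert row["fdr"] == pytest.approx(row["p"])

    def test_ns_when_nothing_passes(self, setup):
        modules, _, universe = setup
        refs = [GeneSetCollection({"unrelated": ["g40", "g41"]}, source="r")]
        result = annotate_collection(modules, refs, universe)
        assert (result.top_terms["r"] == NO_TERM).all()

    def test_cluster_summary_term_majority_vote(self, setup):
        from immunomod.annotate import ClusterAssignment
        modules, refs, universe = setup
        link = np.array([[0.0, 1.0, 0.5, 2.0]])
        clusters = ClusterAssignment(
            labels=pd.Series([1, 1], index=["m1", "m2"]),
            n_clusters=1, linkage_matrix=link)
        result = annotate_collection(modules, refs, universe, clusters)
        # one vote each for setA and setB; tie broken by smallest FDR then name
        assert result.cluster_terms[1] in ("setA", "setB")


class TestBHOracle:
    def test_three_value_example(self):
        np.testing.assert_allclose(bh_fdr([0.01, 0.02, 0.03]),
                                   [0.03, 0.03, 0.03])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(min_value=1e-12, max_value=1.0), min_size=1,
                    max_size=30))
    def test_statsmodels_bh_matches_direct_formula(self, pvals):
        from statsmodels.stats.multitest import multipletests
        ours = multipletests(np.asarray(pvals), method="fdr_bh")[1]
        np.testing.assert_allclose(ours, bh_fdr(pvals), atol=1e-12)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.permutations(list(range(8))))
    def test_bh_invariant_under_input_permutation(self, perm):
        base = np.array([0.001, 0.01, 0.02, 0.2, 0.5, 0.7, 0.9, 1.0])
        permuted = base[list(perm)]
        q_base = bh_fdr(base)
        q_perm = bh_fdr(permuted)
        np.testing.assert_allclose(q_perm, q_base[list(perm)], atol=1e-12)
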