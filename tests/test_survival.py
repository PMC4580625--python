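import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from lifelines.statistics import logrank_test as lifelines_logrank
from scipy.stats import kstest

from conftest import clinical_from_arrays
from immunomod.datatypes import ExpressionMatrix, GeneModule, Partition
from immunomod.modules import random_gene_sets
from immunomod.survival import (
    concordance_index,
    km_estimate,
    logrank_chi2_many,
    logrank_test,
    median_partition,
    module_score,
    screen,
    truncate_followup,
)
from oracles import harrell_c, km_curve, logrank_chi2


def make_module(name, genes):
    return GeneModule(name=name, marker=name, members=list(genes))


class TestModuleScore:
    def test_single_gene_module_is_that_gene(self, toy_expr):
        ms = module_score(toy_expr, make_module("m", ["G2"]))
        pd.testing.assert_series_equal(ms.scores, toy_expr.data.loc["G2"],
                                       check_names=False)

    def test_constant_genes_give_constant_score(self):
        expr = ExpressionMatrix(pd.DataFrame(
            np.full((3, 4), 7.0), index=["A", "B", "C"],
            columns=["S1", "S2", "S3", "S4"]))
        ms = module_score(expr, make_module("m", ["A", "B", "C"]))
        assert (ms.scores == 7.0).all()

    def test_scores_equal_per_sample_medians(self, toy_expr):
        genes = ["G1", "G3", "G5"]
        ms = module_score(toy_expr, make_module("m", genes))
        for s in toy_expr.sample_ids:
            assert ms.scores[s] == np.median(toy_expr.data.loc[genes, s])

    def test_low_coverage_is_skip_signal_not_exception(self, toy_expr):
        ms = module_score(toy_expr, make_module("m", ["G1", "X1", "X2", "X3"]))
        assert not ms.ok
        assert ms.coverage == 0.25
        assert ms.present_genes == ["G1"]


class TestMedianPartition:
    def test_even_all_distinct_splits_equally(self):
        score = pd.Series([1.0, 2.0, 3.0, 4.0], index=list("ABCD"))
        p = median_partition(score, "module:m")
        assert sorted(p.lo) == ["A", "B"]
        assert sorted(p.hi) == ["C", "D"]

    def test_lo_takes_ties_at_the_median(self):
        # median of (1,2,2,3) is 2; lo takes <= median
        score = pd.Series([1.0, 2.0, 2.0, 3.0], index=list("ABCD"))
        p = median_partition(score, "module:m")
        assert sorted(p.lo) == ["A", "B", "C"]
        assert p.hi == ["D"]

    def test_constant_scores_are_degenerate(self):
        score = pd.Series([2.0] * 4, index=list("ABCD"))
        p = median_partition(score, "module:m")
        assert p.is_degenerate and p.hi == []

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match=">= 4"):
            median_partition(pd.Series([1.0, 2.0], index=["A", "B"]), "x")


class TestKMEstimate:
    def test_no_events_stays_at_one(self):
        clin = clinical_from_arrays([5, 10, 15], [0, 0, 0])
        curve = km_estimate(clin, clin.sample_ids)
        assert (curve.to_numpy() == 1.0).all()

    def test_single_death_among_four(self):
        clin = clinical_from_arrays([10, 20, 30, 40], [1, 0, 0, 0])
        curve = km_estimate(clin, clin.sample_ids)
        assert curve.loc[10.0] == pytest.approx(0.75)

    def test_matches_product_limit_oracle(self, toy_clinical):
        curve = km_estimate(toy_clinical, toy_clinical.sample_ids)
        times, probs = km_curve(toy_clinical.time, toy_clinical.event)
        for t, s in zip(times, probs):
            assert curve.loc[t] == pytest.approx(s)

    def test_monotone_starts_at_one(self, toy_clinical):
        curve = km_estimate(toy_clinical, toy_clinical.sample_ids)
        assert curve.iloc[0] == 1.0
        assert (np.diff(curve.to_numpy()) <= 1e-12).all()


class TestLogrank:
    @staticmethod
    def partition_from_mask(clin, mask):
        labels = pd.Series(np.where(mask, "hi", "lo"), index=clin.sample_ids)
        return Partition(labels=labels, origin="test")

    def test_identical_groups_give_null(self):
        clin = clinical_from_arrays([10, 20, 30, 10, 20, 30],
                                    [1, 1, 0, 1, 1, 0])
        res = logrank_test(clin, self.partition_from_mask(
            clin, [True, True, True, False, False, False]))
        assert res.chi_square == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_matches_hand_accumulation_oracle(self):
        clin = clinical_from_arrays([1, 2, 3, 4], [1, 1, 1, 1])
        mask = [True, True, False, False]
        res = logrank_test(clin, self.partition_from_mask(clin, mask))
        assert res.chi_square == pytest.approx(
            logrank_chi2(clin.time, clin.event, mask))
        assert res.n_hi == res.n_lo == 2
        assert res.direction == -1  # hi died first: worse survival

    def test_matches_lifelines_on_mixed_data(self, toy_clinical):
        mask = [True, False, True, False, True, False]
        res = logrank_test(toy_clinical,
                           self.partition_from_mask(toy_clinical, mask))
        t = toy_clinical.time.to_numpy()
        e = toy_clinical.event.to_numpy()
        m = np.array(mask)
        ll = lifelines_logrank(t[m], t[~m], event_observed_A=e[m],
                               event_observed_B=e[~m])
        assert res.chi_square == pytest.approx(ll.test_statistic)
        assert res.p_value == pytest.approx(ll.p_value)

    def test_label_symmetric(self, toy_clinical):
        mask = np.array([True, False, True, False, False, True])
        a = logrank_test(toy_clinical,
                         self.partition_from_mask(toy_clinical, mask))
        b = logrank_test(toy_clinical,
                         self.partition_from_mask(toy_clinical, ~mask))
        assert a.chi_square == pytest.approx(b.chi_square)
        assert a.p_value == pytest.approx(b.p_value)

    def test_zero_events_undefined(self):
        clin = clinical_from_arrays([10, 20, 30, 40], [0, 0, 0, 0])
        with pytest.raises(ValueError, match="zero events"):
            logrank_test(clin, self.partition_from_mask(
                clin, [True, True, False, False]))

    def test_null_pvalues_uniform_over_many_partitions(self, null_cohort):
        # random partitions of a null cohort: p ~ Uniform(0,1)
        _, clin, _ = null_cohort
        rng = np.random.default_rng(42)
        n = len(clin.sample_ids)
        hi = np.zeros((n, 500), dtype=bool)
        for j in range(500):
            hi[rng.permutation(n)[:n // 2], j] = True
        _, p, _ = logrank_chi2_many(clin.time.to_numpy(),
                                    clin.event.to_numpy(), hi)
        assert kstest(p, "uniform").pvalue > 0.01

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.lists(st.tuples(st.integers(1, 50), st.booleans(),
                              st.booleans()), min_size=4, max_size=12))
    def test_many_kernel_agrees_with_oracle(self, rows):
        times = [r[0] for r in rows]
        events = [int(r[1]) for r in rows]
        mask = [r[2] for r in rows]
        if sum(events) == 0 or all(mask) or not any(mask):
            return
        chi, _, _ = logrank_chi2_many(np.array(times, float),
                                      np.array(events),
                                      np.array(mask)[:, None])
        assert chi[0] == pytest.approx(
            logrank_chi2(times, events, mask), abs=1e-9)


class TestConcordance:
    def test_constant_score_is_half(self, toy_clinical):
        score = pd.Series(3.0, index=toy_clinical.sample_ids)
        res = concordance_index(score, toy_clinical)
        assert res.raw == 0.5 and res.oriented == 0.5

    def test_perfect_risk_ranking_is_one(self):
        clin = clinical_from_arrays([10, 20, 30, 40], [1, 1, 1, 1])
        score = pd.Series([4.0, 3.0, 2.0, 1.0], index=clin.sample_ids)
        res = concordance_index(score, clin)
        assert res.raw == 1.0

    def test_matches_pair_enumeration_oracle(self):
        clin = clinical_from_arrays([12, 5, 30, 22, 9], [1, 1, 0, 1, 1])
        score = pd.Series([0.3, 2.0, 0.1, 1.4, 0.9], index=clin.sample_ids)
        res = concordance_index(score, clin)
        assert res.raw == pytest.approx(
            harrell_c(score.to_numpy(), clin.time, clin.event))

    def test_negated_score_flips_c(self):
        clin = clinical_from_arrays([12, 5, 30, 22, 9], [1, 1, 0, 1, 1])
        score = pd.Series([0.3, 2.0, 0.1, 1.4, 0.9], index=clin.sample_ids)
        a = concordance_index(score, clin)
        b = concordance_index(-score, clin)
        assert a.raw == pytest.approx(1 - b.raw)
        assert a.oriented == pytest.approx(b.oriented)

    def test_no_comparable_pairs_undefined(self):
        clin = clinical_from_arrays([10, 20], [0, 1])
        score = pd.Series([1.0, 2.0], index=clin.sample_ids)
        with pytest.raises(ValueError, match="comparable"):
            concordance_index(score, clin)


class TestTruncate:
    def test_beyond_horizon_censored_at_horizon(self):
        clin = clinical_from_arrays([2000, 1825, 100], [1, 1, 0])
        out = truncate_followup(clin, 1825)
        assert out.time.tolist() == [1825.0, 1825.0, 100.0]
        assert out.event.tolist() == [0, 1, 0]

    def test_identity_when_all_under_horizon(self, toy_clinical):
        out = truncate_followup(toy_clinical, 1825)
        pd.testing.assert_frame_equal(out.data, toy_clinical.data)


class TestScreen:
    def test_planted_modules_flagged(self, tumor_cohort, module_collection):
        expr, clin, _ = tumor_cohort
        sm = screen(expr, clin, module_collection)
        assert (sm.results["p"] < 1e-3).all()
        assert (sm.results["direction"] == 1).all()  # beta<0: hi protective

    def test_random_gene_sets_on_null_cohort_calibrated(self, null_cohort):
        _, clin, _ = null_cohort
        expr = null_cohort[0]
        sets = random_gene_sets(expr.gene_ids, n_sets=200, set_size=100,
                                seed=7)
        sm = screen(expr, clin, sets)
        # note: gene-set scores on one cohort are correlated, so only a loose
        # bound is meaningful here
        assert sm.significant_counts[5e-3] <= 20

    def test_empty_collection_yields_empty_matrix(self, tumor_cohort):
        from immunomod.datatypes import ModuleCollection
        expr, clin, _ = tumor_cohort
        sm = screen(expr, clin, ModuleCollection([]))
        assert len(sm.results) == 0

    def test_coverage_skip_recorded(self, tumor_cohort, module_collection):
        expr, clin, _ = tumor_cohort
        missing = ExpressionMatrix(expr.data.iloc[:10].copy())
        sm = screen(missing, clin, module_collection)
        assert (sm.results["skip_reason"] == "coverage").all()
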