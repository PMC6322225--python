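"""Per-gene scoring, gene-set statistics, and FDR-controlled enrichment."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from pxpn import synthdata as sd
from pxpn.enrichment import (
    ExpressionMatrix,
    bh_adjust,
    enrich,
    filter_genes,
    gene_scores,
    set_statistic,
    welch_t,
)


def matrix_from(values, groups=("A", "A", "A", "B", "B", "B")):
    values = np.atleast_2d(np.asarray(values, dtype=float))
    samples = [f"s{i}" for i in range(values.shape[1])]
    df = pd.DataFrame(values, index=[f"g{i}" for i in range(values.shape[0])], columns=samples)
    return ExpressionMatrix(df, dict(zip(samples, groups)))


class TestExpressionMatrix:
    def test_requires_two_groups(self):
        with pytest.raises(ValueError, match="two group"):
            matrix_from([[1, 2, 3, 4, 5, 6]], groups=["A"] * 6)

    def test_requires_two_samples_per_group(self):
        with pytest.raises(ValueError, match="fewer than 2"):
            matrix_from([[1, 2, 3]], groups=["A", "B", "B"])


class TestFilterGenes:
    def test_planted_zero_rows_removed(self):
        rng = np.random.default_rng(0)
        values = np.abs(rng.normal(5, 1, size=(100, 12))) + 0.1
        zero_rows = rng.choice(100, size=7, replace=False)
        values[zero_rows] = 0.0
        expr = matrix_from(values, groups=["A"] * 6 + ["B"] * 6)
        kept = filter_genes(expr)
        assert len(kept.genes) == 93
        assert set(kept.genes) == {f"g{i}" for i in range(100)} - {f"g{i}" for i in zero_rows}
        # order preserved
        assert list(kept.genes) == [g for g in expr.genes if g in set(kept.genes)]

    def test_identity_when_no_zero_rows(self):
        expr = matrix_from([[1, 2, 3, 4, 5, 6], [2, 2, 2, 2, 2, 2]])
        assert filter_genes(expr).values.equals(expr.values)

    def test_all_zero_matrix_rejected(self):
        with pytest.raises(ValueError, match="no expressed genes"):
            filter_genes(matrix_from([[0, 0, 0, 0, 0, 0]]))


class TestGeneScores:
    def test_identical_groups_score_zero(self):
        expr = matrix_from([[5, 5, 5, 5, 5, 5]])
        assert gene_scores(expr)["g0"] == 0.0

    def test_zero_variance_unequal_means_capped(self):
        expr = matrix_from([[1, 1, 1, 3, 3, 3]])
        assert gene_scores(expr, u_cap=50.0)["g0"] == 50.0
        assert gene_scores(expr, directed=True)["g0"] == 50.0

    def test_matches_hand_welch_t(self):
        a, b = [10.0, 12.0, 11.0], [15.0, 16.0, 17.0]
        expr = matrix_from([a + b])
        t_hand, _ = welch_t(np.array(a), np.array(b))
        t_scipy = stats.ttest_ind(b, a, equal_var=False).statistic
        assert gene_scores(expr, directed=True)["g0"] == pytest.approx(t_hand, abs=1e-9)
        assert t_hand == pytest.approx(t_scipy, abs=1e-9)

    def test_undirected_invariant_to_group_swap(self):
        rng = np.random.default_rng(5)
        values = rng.normal(10, 2, size=(30, 12))
        fwd = matrix_from(values, groups=["A"] * 6 + ["B"] * 6)
        rev = matrix_from(values, groups=["B"] * 6 + ["A"] * 6)
        assert np.allclose(gene_scores(fwd), gene_scores(rev))


class TestSetStatistic:
    def scores(self, values):
        return pd.Series(np.asarray(values, dtype=float), index=[f"g{i}" for i in range(len(values))])

    def test_identical_score_distributions_give_half_p(self):
        s = self.scores([1, 2, 3, 1, 2, 3])
        t, p = set_statistic(s, {"g0", "g1", "g2"})
        assert t == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(0.5, abs=1e-12)

    def test_exhaustive_permutation_on_top_members(self):
        s = self.scores([1, 2, 3, 4, 5, 6])
        _, p = set_statistic(s, {"g4", "g5"}, mode="permutation", exhaustive=True)
        # only the member set itself reaches the top mean: (1+1)/(1+15)
        assert p == pytest.approx(2 / 16)

    def test_parametric_matches_independent_welch(self):
        s = self.scores([0.3, 1.1, 0.2, 2.5, 3.1, 2.8, 0.9, 0.1])
        members = {"g3", "g4", "g5"}
        t, p = set_statistic(s, members)
        x = s[s.index.isin(members)]
        y = s[~s.index.isin(members)]
        ref = stats.ttest_ind(x, y, equal_var=False, alternative="greater")
        assert t == pytest.approx(ref.statistic, abs=1e-9)
        assert p == pytest.approx(ref.pvalue, abs=1e-9)

    def test_sampled_permutation_agrees_with_enumeration(self):
        s = self.scores([0.5, 1.5, 2.5, 3.5, 4.5, 5.5])
        members = {"g3", "g5"}
        _, p_exact = set_statistic(s, members, mode="permutation", exhaustive=True)
        values = s.to_numpy()
        observed = values[[3, 5]].mean()
        count = sum(
            1
            for combo in itertools.combinations(range(6), 2)
            if values[list(combo)].mean() >= observed
        )
        assert p_exact == pytest.approx((1 + count) / (1 + math.comb(6, 2)))
        # a sampled estimate converges to the enumeration frequency count/total
        rng = np.random.default_rng(0)
        _, p_mc = set_statistic(s, members, mode="permutation", n_perm=4000, rng=rng)
        assert p_mc == pytest.approx(count / math.comb(6, 2), abs=0.02)


class TestBhAdjust:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.03])[0] == pytest.approx(0.03)

    def test_hand_step_up(self):
        q = bh_adjust([0.01, 0.02, 0.03, 0.04, 0.05])
        assert np.allclose(q, [0.05] * 5)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 0.0])
        with pytest.raises(ValueError):
            bh_adjust([1.5])

    @settings(max_examples=60, derandomize=True)
    @given(st.lists(st.floats(min_value=1e-6, max_value=1.0), min_size=1, max_size=20))
    def test_q_at_least_p(self, pvals):
        q = bh_adjust(pvals)
        assert np.all(q >= np.asarray(pvals) - 1e-12)
        assert np.all(q <= 1.0 + 1e-12)


class TestEnrich:
    def planted(self, seed, delta=3.0):
        params = sd.SimulationParams(n_pathways=5, effect_size=delta)
        plan = []  # disjoint pathways
        truth = sd.SyntheticTruth(frozenset({"P01"}), frozenset())
        coll = sd.make_collection(params, plan, seed=0)
        expr = sd.simulate_expression(coll, truth, params, seed=seed)
        return coll, expr

    def test_alpha_zero_enriches_nothing(self):
        coll, expr = self.planted(seed=0)
        table = enrich(expr, coll.gene_sets(), alpha=0.0)
        assert not table["enriched"].any()

    def test_planted_pathway_recovered_null_pathways_not(self):
        hits = misses = 0
        for seed in range(20):
            coll, expr = self.planted(seed)
            table = enrich(expr, coll.gene_sets(), alpha=0.05).set_index("set_id")
            ok = bool(table.at["P01", "enriched"]) and not table.drop("P01")["enriched"].any()
            hits += ok
            misses += not ok
        assert hits >= 19

    def test_invariant_to_row_and_sample_order(self):
        coll, expr = self.planted(seed=3)
        shuffled_rows = expr.with_values(expr.values.sample(frac=1, random_state=1))
        shuffled_cols = expr.with_values(
            expr.values[list(reversed(list(expr.values.columns)))]
        )
        base = enrich(expr, coll.gene_sets(), alpha=0.05)
        for other in (shuffled_rows, shuffled_cols):
            table = enrich(other, coll.gene_sets(), alpha=0.05)
            assert np.allclose(base["p"], table["p"], equal_nan=True)

    def test_alpha_monotonicity(self):
        coll, expr = self.planted(seed=4)
        lo = enrich(expr, coll.gene_sets(), alpha=0.01)
        hi = enrich(expr, coll.gene_sets(), alpha=0.20)
        assert set(lo.loc[lo["enriched"], "set_id"]) <= set(hi.loc[hi["enriched"], "set_id"])

    def test_small_sets_marked_untested(self):
        coll, expr = self.planted(seed=5)
        table = enrich(expr, [("tiny", frozenset({"g00000"}))], min_set_size=2)
        row = table.iloc[0]
        assert not row["tested"] and np.isnan(row["p"]) and np.isnan(row["q"])

    def test_type_i_error_controlled_on_null_data(self):
        """With no planted signal, few simulations show any enrichment at q<0.05."""
        params = sd.SimulationParams(n_pathways=10, effect_size=0.0)
        _, plan, truth = sd.default_scenario()
        coll = sd.make_collection(params, plan, seed=0)
        false_positive = 0
        n_sim = 200
        for seed in range(n_sim):
            expr = sd.simulate_expression(coll, truth, params, seed=seed)
            table = enrich(expr, coll.gene_sets(), alpha=0.05)
            false_positive += bool(table["enriched"].any())
        assert false_positive / n_sim <= 0.10
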