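import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import auc_pair_counting, bh_step_up, rank_sum_exact
from netscreen.diagnostics import (
    auc,
    benjamini_hochberg,
    correlate_with_fractions,
    expand_correlated,
    pearson_with_p,
    rank_candidates,
    select_hub,
    wilcoxon_rank_sum,
)
from netscreen.synthetic import SyntheticConfig, gen_expression
from netscreen.types import ExpressionMatrix, GeneSet


class TestAUC:
    def test_perfect_separation(self):
        a, direction = auc([3, 4, 1, 2], ["T2DM", "T2DM", "normal", "normal"])
        assert a == 1.0 and direction == "T2DM"

    def test_all_ties_give_half(self):
        a, _ = auc([5, 5, 5, 5], ["T2DM", "T2DM", "normal", "normal"])
        assert a == pytest.approx(0.5)

    def test_orientation_flips_low_auc(self):
        a, direction = auc([1, 3, 2, 4], ["T2DM", "T2DM", "normal", "normal"])
        assert a == pytest.approx(0.75) and direction == "normal"

    def test_single_label_rejected(self):
        with pytest.raises(ValueError):
            auc([1, 2], ["T2DM", "T2DM"])

    def test_matches_pair_counting_oracle(self):
        rng = np.random.default_rng(17)
        for _ in range(1000):
            n = int(rng.integers(2, 9))
            n_pos = int(rng.integers(1, n))
            labels = np.array(["T2DM"] * n_pos + ["normal"] * (n - n_pos))
            values = rng.integers(0, 5, size=n).astype(float)  # many ties
            a, _ = auc(values, labels)
            assert a == pytest.approx(auc_pair_counting(values, labels, "T2DM"), abs=1e-12)


class TestWilcoxon:
    def test_identical_samples(self):
        assert wilcoxon_rank_sum([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0, abs=1e-9)

    def test_fully_separated_small(self):
        assert wilcoxon_rank_sum([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1, rel=1e-9)

    def test_large_shift_significant(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal(50)
        y = rng.standard_normal(50) + 2.0
        assert wilcoxon_rank_sum(x, y) < 1e-6

    def test_exact_branch_matches_enumeration(self):
        rng = np.random.default_rng(23)
        for _ in range(200):
            n_total = int(rng.integers(3, 13))
            n_x = int(rng.integers(1, n_total))
            values = rng.permutation(np.arange(n_total, dtype=float) * 1.7 + 0.3)
            x, y = values[:n_x], values[n_x:]
            assert wilcoxon_rank_sum(x, y) == pytest.approx(rank_sum_exact(x, y), rel=1e-9)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([], [1.0])


class TestPearson:
    def test_affine_dependence(self):
        x = np.arange(10, dtype=float)
        r, p = pearson_with_p(x, 2 * x + 1)
        assert r == pytest.approx(1.0) and p < 1e-12

    def test_negative_dependence(self):
        x = np.arange(5, dtype=float)
        r, _ = pearson_with_p(x, -x)
        assert r == pytest.approx(-1.0)

    def test_hand_computed_case(self):
        r, p = pearson_with_p([1, 2, 3, 4], [1, 2, 4, 3])
        assert r == pytest.approx(0.8)
        t = 0.8 * math.sqrt(2 / (1 - 0.64))
        from scipy.stats import t as tdist

        assert p == pytest.approx(2 * tdist.sf(t, 2), rel=1e-9)

    def test_zero_variance_flagged(self):
        r, p = pearson_with_p([1, 1, 1], [1, 2, 3])
        assert math.isnan(r) and math.isnan(p)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            pearson_with_p([1, 2], [3, 4])


def expr_from_values(values: dict, groups: list[str]) -> ExpressionMatrix:
    samples = [f"s{i}" for i in range(len(groups))]
    df = pd.DataFrame(values, index=samples).T
    return ExpressionMatrix(df, pd.Series(groups, index=samples))


class TestRankAndHub:
    def test_perfect_candidate(self):
        expr = expr_from_values(
            {"g1": [0, 1, 0, 1, 5, 6, 7, 8], "g2": [1, 2, 3, 4, 4, 3, 2, 1]},
            ["normal"] * 4 + ["T2DM"] * 4,
        )
        out = rank_candidates(expr, GeneSet("cand", {"g1"}))
        row = out.iloc[0]
        assert row["auc"] == 1.0 and bool(row["differential"])

    def test_absent_candidates_skipped_all_absent_rejected(self):
        expr = expr_from_values({"g1": [0, 1, 2, 3]}, ["normal"] * 2 + ["T2DM"] * 2)
        out = rank_candidates(expr, GeneSet("cand", {"g1", "missing"}))
        assert list(out["gene"]) == ["g1"]
        with pytest.raises(ValueError):
            rank_candidates(expr, GeneSet("cand", {"missing"}))

    def test_hub_prefers_differential_over_auc(self):
        results = pd.DataFrame(
            {
                "gene": ["top_auc", "second"],
                "auc": [0.95, 0.80],
                "direction": ["T2DM", "T2DM"],
                "wilcoxon_p": [0.20, 0.01],
                "differential": [False, True],
            }
        )
        assert select_hub(results) == "second"

    def test_hub_tie_break_by_gene_id(self):
        results = pd.DataFrame(
            {
                "gene": ["b", "a"],
                "auc": [0.9, 0.9],
                "direction": ["T2DM", "T2DM"],
                "wilcoxon_p": [0.01, 0.01],
                "differential": [True, True],
            }
        )
        assert select_hub(results) == "a"

    def test_no_differential_gene_means_no_hub(self):
        results = pd.DataFrame(
            {"gene": ["g"], "auc": [0.99], "direction": ["T2DM"],
             "wilcoxon_p": [0.5], "differential": [False]}
        )
        assert select_hub(results) is None

    def test_planted_gene_ranks_first_across_seeds(self):
        hits = 0
        for seed in range(10):
            cfg = SyntheticConfig(seed=seed, n_genes=51, n_samples_per_group=10,
                                  effect_size=3.0, module_loading=0.0)
            expr = gen_expression(cfg, planted_genes=GeneSet("p", {"G0000"}))
            out = rank_candidates(expr, GeneSet("cand", set(expr.genes)))
            hits += out.iloc[0]["gene"] == "G0000"
        assert hits >= 9

    def test_null_auc_matches_pair_counting_expectation(self):
        """Oriented null AUC has the same mean as the brute-force oracle."""
        rng = np.random.default_rng(9)
        labels = np.array(["normal"] * 10 + ["T2DM"] * 8)
        ours, oracle = [], []
        for _ in range(300):
            values = rng.standard_normal(18)
            ours.append(auc(values, labels)[0])
            oracle.append(auc_pair_counting(values, labels, "T2DM"))
        assert np.mean(ours) == pytest.approx(np.mean(oracle), abs=1e-12)
        assert 0.5 < np.mean(ours) < 0.7  # orientation inflates the null mean


class TestExpandCorrelated:
    def test_duplicated_hub_selected_negated_not(self):
        base = np.random.default_rng(0).standard_normal(12)
        samples = [f"s{i}" for i in range(12)]
        df = pd.DataFrame(
            {"hub": base, "copy": base, "anti": -base}, index=samples
        ).T
        expr = ExpressionMatrix(df, pd.Series(["normal"] * 6 + ["T2DM"] * 6, index=samples))
        out = expand_correlated(expr, "hub").set_index("gene")
        assert bool(out.loc["copy", "selected"]) and out.loc["copy", "r"] == pytest.approx(1.0)
        assert not bool(out.loc["anti", "selected"])
        out_abs = expand_correlated(expr, "hub", absolute=True).set_index("gene")
        assert bool(out_abs.loc["anti", "selected"])

    def test_hub_excluded_and_unknown_hub_rejected(self):
        expr = expr_from_values({"g1": [1, 2, 3, 4]}, ["normal"] * 2 + ["T2DM"] * 2)
        with pytest.raises(ValueError):
            expand_correlated(expr, "nope")
        out = expand_correlated(expr, "g1")
        assert "g1" not in set(out["gene"])

    def test_factor_module_recovered_across_seeds(self):
        hits = 0
        module = {f"G{i:04d}" for i in range(5)}
        for seed in range(10):
            cfg = SyntheticConfig(seed=seed, n_genes=50, n_samples_per_group=9,
                                  module_loading=0.99, effect_size=0.0)
            expr = gen_expression(cfg, module_genes=GeneSet("m", module))
            out = expand_correlated(expr, "G0000").set_index("gene")
            selected = set(out.index[out["selected"]])
            ok = (module - {"G0000"}) <= selected and not (selected - module)
            hits += ok
        assert hits >= 9


class TestFractionCorrelation:
    def make_inputs(self, rng, n_types=22, n_genes=20, n_samples=20):
        samples = [f"s{i}" for i in range(n_samples)]
        genes = [f"g{i}" for i in range(n_genes)]
        expr = ExpressionMatrix(
            pd.DataFrame(rng.standard_normal((n_genes, n_samples)), index=genes, columns=samples),
            pd.Series(["normal"] * (n_samples // 2) + ["T2DM"] * (n_samples - n_samples // 2),
                      index=samples),
        )
        fractions = pd.DataFrame(
            rng.standard_normal((n_types, n_samples)),
            index=[f"ct{i}" for i in range(n_types)], columns=samples,
        )
        return expr, genes, fractions

    def test_identical_row_top_tier(self, rng):
        expr, genes, fractions = self.make_inputs(rng)
        fractions.loc["ct0"] = expr.values.loc["g0"]
        out = correlate_with_fractions(expr, GeneSet("g", {"g0"}), fractions)
        row = out.set_index(["gene", "cell_type"]).loc[("g0", "ct0")]
        assert row["r"] == pytest.approx(1.0) and row["tier"] == "***"

    def test_null_calibration(self, rng):
        expr, genes, fractions = self.make_inputs(rng)
        out = correlate_with_fractions(expr, GeneSet("g", set(genes)), fractions)
        hits = int((out["p"] < 0.05).sum())
        n = len(out)
        assert abs(hits - 0.05 * n) <= 3 * np.sqrt(n * 0.05 * 0.95)

    def test_constant_fraction_flagged(self, rng):
        expr, genes, fractions = self.make_inputs(rng, n_types=2)
        fractions.loc["ct0"] = 0.5
        out = correlate_with_fractions(expr, GeneSet("g", {"g0"}), fractions)
        assert out.set_index("cell_type").loc["ct0", "tier"] == "undefined"

    def test_too_few_shared_samples(self, rng):
        expr, genes, fractions = self.make_inputs(rng, n_samples=4)
        with pytest.raises(ValueError):
            correlate_with_fractions(expr, GeneSet("g", {"g0"}), fractions.iloc[:, :2])


class TestBenjaminiHochberg:
    def test_stepup_by_hand(self):
        out = benjamini_hochberg([0.01, 0.02, 0.03])
        assert np.allclose(out, [0.03, 0.03, 0.03])

    def test_single_and_equal_pvalues(self):
        assert benjamini_hochberg([0.2])[0] == pytest.approx(0.2)
        assert np.allclose(benjamini_hochberg([0.1, 0.1, 0.1]), 0.1)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            benjamini_hochberg([0.5, 1.5])

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=30))
    def test_matches_textbook_definition_and_invariants(self, pvals):
        out = benjamini_hochberg(pvals)
        expected = bh_step_up(pvals)
        assert np.allclose(out, expected, atol=1e-12)
        p = np.asarray(pvals)
        assert (out >= p - 1e-12).all() and (out <= 1.0 + 1e-12).all()
        order = np.argsort(p, kind="stable")
        assert (np.diff(out[order]) >= -1e-12).all()
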