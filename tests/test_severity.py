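"""Severity discretization, contingency statistics, bootstrap, correlations."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from grimkit.io import FAUS, Dataset
from grimkit.reference import severity_counts_published
from grimkit.severity import (
    bootstrap_median,
    chi_square,
    classify,
    classify_scores,
    correlation_matrix,
    fisher_exact_2xc,
    mann_whitney_contrast,
    normality_check,
    posthoc_pairwise,
    severity_counts,
)


class TestClassify:
    @pytest.mark.parametrize(
        "score,label",
        [
            (0.0, "mild"),
            (2.99, "mild"),
            (3.0, "moderate"),
            (4.5, "moderate"),
            (6.0, "moderate"),
            (6.01, "severe"),
            (16.0, "severe"),
        ],
    )
    def test_thresholds(self, score, label):
        assert classify(score) == label

    def test_negative_score_rejected(self):
        with pytest.raises(ValueError):
            classify(-0.1)
        with pytest.raises(ValueError, match="position 1"):
            classify_scores([1.0, -2.0])

    def test_vectorized_matches_scalar(self):
        scores = np.linspace(0, 12, 50)
        vec = classify_scores(scores)
        assert list(vec) == [classify(s) for s in scores]


class TestCounts:
    def test_counts_conserve_records(self, paper_ds):
        table = severity_counts(paper_ds)
        assert table.to_numpy().sum() == len(paper_ds.records)
        per_cell = paper_ds.records.groupby(
            ["treatment", "intervention"], observed=True
        ).size()
        for key, row in table.iterrows():
            assert row.sum() == per_cell[key]

    def test_empty_dataset_all_zero(self, paper_ds):
        empty = Dataset(records=paper_ds.records.iloc[:0])
        table = severity_counts(empty)
        assert table.to_numpy().sum() == 0

    def test_row_order_is_bsl_pre_post(self, paper_ds):
        table = severity_counts(paper_ds)
        assert [i for _, i in table.index] == ["bsl", "pre", "post"] * 2


class TestChiSquare:
    def test_matches_direct_formula(self):
        rng = np.random.default_rng(0)
        for _ in range(25):
            table = rng.integers(1, 60, size=(3, 3)).astype(float)
            stat, dof, _ = chi_square(table)
            expected = np.outer(table.sum(1), table.sum(0)) / table.sum()
            direct = ((table - expected) ** 2 / expected).sum()
            assert stat == pytest.approx(direct, abs=1e-9)
            assert dof == 4

    def test_proportional_rows_give_zero(self):
        table = np.array([[10, 20, 30], [20, 40, 60]])
        stat, _, p = chi_square(table)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_zero_marginal_named(self):
        with pytest.raises(ValueError, match="column 2"):
            chi_square(np.array([[1, 2, 0], [3, 4, 0]]))
        with pytest.raises(ValueError, match="row 1"):
            chi_square(np.array([[1, 2], [0, 0]]))


class TestFisherExact:
    @pytest.mark.parametrize("seed", range(15))
    def test_matches_scipy_on_2x2(self, seed):
        rng = np.random.default_rng(seed)
        table = rng.integers(0, 12, size=(2, 2))
        if table.sum(0).min() == 0 or table.sum(1).min() == 0:
            table = table + 1
        _, p_scipy = stats.fisher_exact(table)
        assert fisher_exact_2xc(table) == pytest.approx(p_scipy, abs=1e-10)

    def test_2x3_close_to_chi2_for_large_counts(self):
        table = np.array([[40, 55, 70], [60, 45, 30]])
        p_exact = fisher_exact_2xc(table)
        _, _, p_chi2 = chi_square(table)
        assert p_exact == pytest.approx(p_chi2, abs=0.01)


class TestPosthoc:
    def test_published_oil_pairs_match_printed_values(self):
        """The Oil class-pair adjusted p-values reproduce the study exactly."""
        counts = severity_counts_published().loc["Oil"]
        out = posthoc_pairwise(counts, adjust="fdr").set_index("pair")
        assert out.loc["mild/moderate", "p_adj"] == pytest.approx(0.044, abs=5e-4)
        assert out.loc["mild/severe", "p_adj"] == pytest.approx(0.285, abs=5e-4)
        assert out.loc["moderate/severe", "p_adj"] == pytest.approx(0.627, abs=5e-4)

    def test_published_ccl4_mild_pairs_highly_significant(self):
        counts = severity_counts_published().loc["CCl4"]
        out = posthoc_pairwise(counts, adjust="fdr").set_index("pair")
        assert len(out) == 3
        assert out.loc["mild/moderate", "p_adj"] <= 0.001
        assert out.loc["mild/severe", "p_adj"] <= 0.001
        # the sparse severe column is flagged and gets an exact companion p
        assert bool(out.loc["moderate/severe", "low_expected"])
        assert 0 < out.loc["moderate/severe", "p_exact"] <= 1

    def test_identical_profiles_not_significant(self):
        counts = pd.DataFrame(
            {"mild": [10, 20, 30], "moderate": [5, 10, 15], "severe": [2, 4, 6]},
            index=["bsl", "pre", "post"],
        )
        out = posthoc_pairwise(counts)
        assert (out["p_adj"] > 0.9).all()

    @pytest.mark.parametrize("adjust", ["fdr", "holm", "bonferroni"])
    def test_adjusted_p_at_least_raw(self, adjust, paper_ds):
        counts = severity_counts(paper_ds).loc["CCl4"]
        out = posthoc_pairwise(counts, adjust=adjust)
        assert (out["p_adj"] >= out["p_raw"] - 1e-12).all()

    def test_unknown_adjustment_rejected(self):
        counts = severity_counts_published().loc["Oil"]
        with pytest.raises(ValueError, match="unknown adjustment"):
            posthoc_pairwise(counts, adjust="sidak")


class TestMannWhitneyContrast:
    def test_self_contrast_is_null(self, paper_ds):
        sel = {"treatment": "CCl4", "week": 0}
        res, prov = mann_whitney_contrast(paper_ds, sel, sel)
        assert res.r == pytest.approx(0.0)
        assert prov["n_a"] == prov["n_b"]

    def test_planted_baseline_vs_post_effect(self, paper_ds):
        res, _ = mann_whitney_contrast(
            paper_ds,
            {"treatment": "CCl4", "week": 0},
            {"treatment": "CCl4", "week": 1, "intervention": "post"},
        )
        assert res.r > 0.3
        assert res.p < 0.01

    def test_empty_selector_named(self, paper_ds):
        with pytest.raises(ValueError, match="group_b"):
            mann_whitney_contrast(
                paper_ds, {"week": 0}, {"week": 99}
            )


class TestBootstrap:
    def test_constant_sample(self):
        est = bootstrap_median([4.0] * 10, n_boot=200, seed=0)
        assert est.median == est.ci_low == est.ci_high == 4.0

    def test_deterministic_under_seed(self):
        x = np.random.default_rng(1).normal(size=40)
        a = bootstrap_median(x, n_boot=1000, seed=5)
        b = bootstrap_median(x, n_boot=1000, seed=5)
        assert (a.median, a.ci_low, a.ci_high) == (b.median, b.ci_low, b.ci_high)

    def test_interval_brackets_estimate(self, paper_ds):
        sel = paper_ds.records.query("treatment == 'CCl4' and week == 0")
        est = bootstrap_median(sel["ot_score"], n_boot=2000, seed=1)
        assert est.ci_low <= est.median <= est.ci_high

    def test_ci_width_shrinks_with_sample_size(self):
        rng = np.random.default_rng(2)
        widths = []
        for n in (20, 80, 320):
            w = [
                (
                    lambda e: e.ci_high - e.ci_low
                )(bootstrap_median(rng.normal(size=n), n_boot=500, seed=k))
                for k in range(50)
            ]
            widths.append(np.median(w))
        assert widths[0] > widths[1] > widths[2]

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            bootstrap_median([], seed=0)


class TestCorrelation:
    def test_duplicated_columns_correlate_fully(self, paper_ds):
        records = paper_ds.records.copy()
        for f in FAUS:
            records[f"{f}_score"] = records["ot_score"]
        ds = Dataset(records=records)
        corr = correlation_matrix(ds, "CCl4")
        np.testing.assert_allclose(corr.to_numpy(), 1.0)

    def test_symmetric_with_unit_diagonal(self, paper_ds):
        corr = correlation_matrix(paper_ds, "Oil")
        np.testing.assert_allclose(corr.to_numpy(), corr.to_numpy().T)
        np.testing.assert_allclose(np.diag(corr.to_numpy()), 1.0)

    def test_constant_column_reported_undefined(self, paper_ds):
        records = paper_ds.records.copy()
        records["wc_score"] = 2.0
        corr = correlation_matrix(Dataset(records=records), "CCl4")
        assert corr.loc["wc"].drop("wc").isna().all()

    def test_spearman_option_and_small_group_error(self, paper_ds):
        corr = correlation_matrix(paper_ds, "CCl4", method="spearman")
        assert corr.loc["ot", "ep"] > 0
        tiny = Dataset(records=paper_ds.records.iloc[:2])
        with pytest.raises(ValueError, match=">= 3"):
            correlation_matrix(tiny, paper_ds.records["treatment"].iloc[0])


class TestNormality:
    def test_discrete_tied_scores_grossly_non_normal(self, sim_images):
        images, _ = sim_images
        ot = images.loc[images["ot"] >= 0, "ot"].iloc[:2000]
        p, qq = normality_check(ot)
        assert p < 1e-4
        assert {"theoretical", "observed"} == set(qq.columns)

    def test_null_p_values_roughly_uniform(self):
        rng = np.random.default_rng(3)
        ps = [normality_check(rng.normal(size=100))[0] for _ in range(150)]
        ks = stats.kstest(ps, "uniform")
        assert ks.pvalue > 0.01

    def test_constant_and_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            normality_check([1.0] * 10)
        with pytest.raises(ValueError, match="outside"):
            normality_check([1.0, 2.0])
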