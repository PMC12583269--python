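"""Odds-ratio screen, multiple-imputation logistic pooling, Spearman and
cross-tab statistics."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import stats

from immunorank.association import (
    agonist_candidate_profile,
    binarize_high,
    combined_signature,
    crosstab_signature,
    landscape_by_type,
    multivariable_logistic_mi,
    spearman,
    univariable_or,
    univariable_screen,
)


def _cohort_frame(n=200, seed=0):
    rng = np.random.default_rng(seed)
    ranks = rng.uniform(0, 100, size=(n, 4))
    frame = pd.DataFrame(ranks, columns=[f"rank_{g}" for g in ("CD40", "CD4", "CD8A", "CD28")])
    for g in ("CD40", "CD4", "CD8A", "CD28"):
        frame[f"category_{g}"] = np.where(
            frame[f"rank_{g}"] >= 75, "high", np.where(frame[f"rank_{g}"] < 25, "low", "moderate")
        )
    frame["cancer_type"] = rng.choice(["colorectal", "pancreatic", "ovarian"], size=n)
    frame["rank_CD40LG"] = rng.uniform(0, 100, size=n)
    frame["category_CD40LG"] = np.where(frame["rank_CD40LG"] >= 75, "high", "moderate")
    return frame


class TestBinarizeAndLandscape:
    def test_indicator_matches_rank_threshold(self):
        frame = _cohort_frame()
        ind = binarize_high(frame, "CD40")
        np.testing.assert_array_equal(ind.to_numpy(), (frame["rank_CD40"] >= 75).astype(int))

    def test_untracked_gene_rejected(self):
        with pytest.raises(KeyError):
            binarize_high(_cohort_frame(), "GITR")

    def test_landscape_matches_groupby_oracle(self):
        frame = _cohort_frame(300, seed=3)
        table = landscape_by_type(frame, "CD40", min_samples=1)
        assert table.iloc[0]["cancer_type"] == "All Cancers"
        sums = table[["frac_low", "frac_moderate", "frac_high"]].sum(axis=1)
        np.testing.assert_allclose(sums, 1.0, atol=1e-12)
        for _, row in table.iloc[1:].iterrows():
            sub = frame[frame["cancer_type"] == row["cancer_type"]]
            assert row["frac_high"] == pytest.approx(
                (sub["category_CD40"] == "high").mean()
            )
        # All-Cancers high fraction = count-weighted mean of per-type fractions
        weighted = (table.iloc[1:]["frac_high"] * table.iloc[1:]["n"]).sum() / table.iloc[1:]["n"].sum()
        assert table.iloc[0]["frac_high"] == pytest.approx(weighted)

    def test_min_samples_above_cohort_keeps_only_all_row(self):
        table = landscape_by_type(_cohort_frame(50), "CD40", min_samples=1000)
        assert list(table["cancer_type"]) == ["All Cancers"]


class TestAgonistProfile:
    def test_flag_definition_and_boundary(self):
        frame = pd.DataFrame(
            {
                "cancer_type": ["x"] * 3,
                "rank_CD40": [80.0, 74.9, 80.0],
                "category_CD40": ["high", "moderate", "high"],
                "rank_CD40LG": [50.0, 10.0, 90.0],
            }
        )
        prof = agonist_candidate_profile(frame, min_samples=1)
        all_row = prof[prof["cancer_type"] == "All Cancers"].iloc[0]
        # only the first sample: receptor high AND ligand rank < 75
        assert all_row["n_flagged"] == 1

    def test_receptor_equals_ligand_rejected(self):
        with pytest.raises(ValueError):
            agonist_candidate_profile(_cohort_frame(), receptor="CD40", ligand="CD40")


class TestUnivariableOr:
    @pytest.mark.parametrize(
        "cells,expected,digits",
        [((23, 32, 91, 368), 2.9, 1), ((2, 13, 105, 360), 0.53, 2)],
    )
    def test_published_count_fixtures(self, cells, expected, digits):
        res = univariable_or(*cells)
        assert round(res.odds_ratio, digits) == expected

    def test_symmetric_table(self):
        res = univariable_or(5, 5, 5, 5)
        assert res.odds_ratio == pytest.approx(1.0)
        assert res.ci95[0] < 1.0 < res.ci95[1]
        assert res.p_value == pytest.approx(1.0)

    def test_equals_logistic_mle_on_random_tables(self):
        rng = np.random.default_rng(7)
        checked = 0
        while checked < 100:
            a, b, c, d = rng.integers(1, 80, size=4)
            x = np.repeat([1, 1, 0, 0], [a, b, c, d])
            y = np.repeat([1, 0, 1, 0], [a, b, c, d])
            fit = sm.Logit(y, sm.add_constant(x)).fit(disp=0)
            res = univariable_or(a, b, c, d)
            assert res.odds_ratio == pytest.approx(np.exp(fit.params[1]), rel=1e-6)
            checked += 1

    def test_zero_cell_haldane_corrected(self):
        res = univariable_or(0, 10, 10, 10)
        assert res.corrected
        assert np.isfinite(res.odds_ratio) and res.odds_ratio > 0

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            univariable_or(0, 0, 5, 5)


class TestScreen:
    def _table(self, n, seed, effect=0.0):
        rng = np.random.default_rng(seed)
        z = rng.normal(size=n)
        rank40 = 100 * stats.norm.cdf(z + effect * (rng.random(n) < 0.5))
        frame = pd.DataFrame(
            {
                "rank_CD40": rank40,
                "category_CD40": np.where(rank40 >= 75, "high", "moderate"),
                "age_years": rng.normal(61, 10, n),
                "sex": rng.choice(["male", "female"], n),
                "cancer_type": rng.choice(["a", "b", "c"], n),
                "msi": rng.choice(["stable", "unstable"], n, p=[0.95, 0.05]),
                "tmb_high": rng.choice(["true", "false"], n, p=[0.1, 0.9]),
                "pdl1_positive": rng.choice(["true", "false"], n),
            }
        )
        return frame

    def test_null_false_selection_rate(self):
        selected_counts = 0
        total = 0
        for seed in range(60):
            frame = self._table(250, seed)
            results, selected = univariable_screen(frame, "CD40", [])
            total += len(results)
            selected_counts += len(selected)
        rate = selected_counts / total
        assert 0.01 < rate < 0.12  # ~alpha per candidate under the null

    def test_perfect_predictor_flagged_corrected(self):
        frame = self._table(120, 1)
        frame["category_X"] = frame["category_CD40"]
        frame["rank_X"] = frame["rank_CD40"]
        results, selected = univariable_screen(frame, "CD40", ["X"])
        res = {r.variable: r for r in results}["rna:X"]
        assert res.corrected
        assert "rna:X" in selected

    def test_constant_candidate_skipped(self):
        frame = self._table(80, 2)
        frame["sex"] = "female"
        with pytest.warns(UserWarning, match="constant"):
            results, _ = univariable_screen(frame, "CD40", [])
        assert "sex" not in {r.variable for r in results}


class TestMultivariableMI:
    def test_no_missing_collapses_to_complete_fit(self):
        rng = np.random.default_rng(3)
        n = 500
        x1 = rng.random(n) < 0.4
        x2 = rng.random(n) < 0.3
        logit = -1 + 1.2 * x1 + 0.5 * x2
        y = rng.random(n) < 1 / (1 + np.exp(-logit))
        design = pd.DataFrame({"x1": x1.astype(float), "x2": x2.astype(float)})
        pooled = multivariable_logistic_mi(design, pd.Series(y.astype(int)), m=5, seed=0)
        fit = sm.Logit(y.astype(float), sm.add_constant(design)).fit(disp=0)
        by_name = {r.variable: r for r in pooled}
        for i, name in enumerate(["(intercept)", "x1", "x2"]):
            assert by_name[name].odds_ratio == pytest.approx(np.exp(fit.params.iloc[i]), rel=1e-6)

    def test_seeded_reproducibility(self):
        rng = np.random.default_rng(4)
        n = 300
        x1 = (rng.random(n) < 0.4).astype(float)
        y = (rng.random(n) < 0.3).astype(int)
        x1_missing = x1.copy()
        x1_missing[rng.random(n) < 0.2] = np.nan
        design = pd.DataFrame({"x1": x1_missing, "x2": rng.random(n)})
        a = multivariable_logistic_mi(design, pd.Series(y), m=4, burn_in=3, seed=42)
        b = multivariable_logistic_mi(design, pd.Series(y), m=4, burn_in=3, seed=42)
        assert [r.odds_ratio for r in a] == [r.odds_ratio for r in b]
        assert [r.p_value for r in a] == [r.p_value for r in b]

    def test_identical_columns_rejected(self):
        design = pd.DataFrame({"a": [0.0, 1.0, 0.0, 1.0] * 10, "b": [0.0, 1.0, 0.0, 1.0] * 10})
        with pytest.raises(ValueError, match="'a' and 'b'"):
            multivariable_logistic_mi(design, pd.Series([0, 1] * 20), m=2, seed=0)

    def test_m_below_two_rejected(self):
        with pytest.raises(ValueError):
            multivariable_logistic_mi(
                pd.DataFrame({"a": [0.0, 1.0] * 10}), pd.Series([0, 1] * 10), m=1, seed=0
            )


class TestSpearman:
    def test_perfect_monotone(self):
        x = np.arange(10.0)
        assert spearman(x, x**3)[0] == pytest.approx(1.0)
        assert spearman(x, x[::-1])[0] == pytest.approx(-1.0)

    def test_tied_fixture_matches_pearson_on_midranks(self):
        x = np.array([1.0, 2.0, 2.0, 3.0, 5.0, 5.0, 5.0, 9.0])
        y = np.array([4.0, 4.0, 1.0, 7.0, 7.0, 2.0, 8.0, 8.0])
        rx = stats.rankdata(x)
        ry = stats.rankdata(y)
        oracle = np.corrcoef(rx, ry)[0, 1]
        assert spearman(x, y)[0] == pytest.approx(oracle, abs=1e-12)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            spearman(np.ones(5), np.arange(5.0))


class TestCrosstab:
    def test_published_count_row_percentage(self):
        group_a = pd.Series([True] * 114 + [False] * 400)
        group_b = pd.Series([True] * 59 + [False] * 55 + [True] * 91 + [False] * 309)
        res = crosstab_signature(group_a, group_b)
        assert res.counts == (59, 55, 91, 309)
        assert res.row_percent[0] == 52
        assert res.p_value < 0.001

    def test_balanced_table_p_one(self):
        a = pd.Series([True] * 20 + [False] * 20)
        b = pd.Series(([True] * 10 + [False] * 10) * 2)
        assert crosstab_signature(a, b).p_value == pytest.approx(1.0)

    def test_combined_signature_any_rule(self):
        frame = _cohort_frame(150, seed=9)
        sig = combined_signature(frame, ("CD4", "CD8A"), rule="any")
        oracle = (frame["rank_CD4"] >= 75) | (frame["rank_CD8A"] >= 75)
        np.testing.assert_array_equal(sig.to_numpy(), oracle.to_numpy())
        both = combined_signature(frame, ("CD4", "CD8A"), rule="all")
        assert both.sum() <= sig.sum()
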