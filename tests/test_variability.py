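"""Variance-heterogeneity analyses: Levene models, CVs, paired effects."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ymi.variability import (
    PairingError,
    RankDeficiencyError,
    absolute_bias,
    add_levene_columns,
    fit_metadata_model,
    genotype_enrichment,
    genotype_pvalues,
    group_cv,
    levene_transform,
    measure_correlation,
    merge_temperature_labels,
    paired_effect,
    sex_variability_effect,
)
from ymi.synthetic import PopulationSpec, generate_cohort, sample_population


class TestLeveneTransform:
    def test_single_group_deviations(self):
        out = levene_transform([1.0, 3.0], ["a", "a"])
        assert out["abs_dev"].tolist() == [1.0, 1.0]

    def test_two_groups(self):
        out = levene_transform([0.0, 0.0, -2.0, 2.0], ["a", "a", "b", "b"])
        assert out.loc[out["group"] == "a", "abs_dev"].tolist() == [0.0, 0.0]
        assert out.loc[out["group"] == "b", "abs_dev"].tolist() == [2.0, 2.0]

    def test_singleton_group_excluded(self):
        out = levene_transform([1.0, 2.0, 9.0], ["a", "a", "solo"])
        assert "solo" not in set(out["group"])

    def test_ols_on_transform_reproduces_classical_levene(self, rng):
        """Regression route equals scipy's mean-centered Levene W exactly."""
        import statsmodels.api as sm

        for _ in range(5):
            sizes = rng.integers(5, 15, size=3)
            samples = [rng.normal(0, s, size=n) for s, n in zip([1, 2, 0.5], sizes)]
            y = np.concatenate(samples)
            g = np.repeat(["a", "b", "c"], sizes)
            lev = levene_transform(y, g)
            X = pd.get_dummies(lev["group"], drop_first=True, dtype=float)
            X.insert(0, "const", 1.0)
            fit = sm.OLS(lev["abs_dev"], X).fit()
            w, p = stats.levene(*samples, center="mean")
            assert fit.fvalue == pytest.approx(w, abs=1e-10)
            assert fit.f_pvalue == pytest.approx(p, abs=1e-10)

    def test_add_levene_columns_group_key(self, small_cohort):
        df = small_cohort.cohort.df
        grp = df.groupby(["genotype", "expCond"])["handedness"].transform("mean")
        expected = (df["handedness"] - grp).abs()
        assert np.allclose(df["lev_handedness"], expected, equal_nan=True)


class TestGroupCV:
    def test_three_point_example(self):
        out = group_cv([0.4, 0.5, 0.6], ["g", "g", "g"])
        assert out.loc[0, "cv"] == pytest.approx(0.1 / 0.5)

    def test_constant_group_zero_cv(self):
        out = group_cv([2.0, 2.0, 2.0], ["g"] * 3)
        assert out.loc[0, "cv"] == 0.0

    def test_scale_invariance(self, rng):
        y = rng.gamma(5.0, size=40)
        g = ["a"] * 40
        base = group_cv(y, g).loc[0, "cv"]
        assert group_cv(7.3 * y, g).loc[0, "cv"] == pytest.approx(base)

    def test_nonpositive_mean_flagged(self):
        out = group_cv([-1.0, -2.0, -3.0], ["g"] * 3)
        assert np.isnan(out.loc[0, "cv"])

    def test_min_n_excludes_small_groups(self):
        out = group_cv([1.0, 2.0, 3.0, 4.0, 5.0], ["a", "a", "a", "b", "b"], min_n=3)
        assert set(out["group"]) == {"a"}

    def test_generator_cv_recovery(self):
        """Genotype CVs spanning ~0.2–0.4 are recovered within ±0.02."""
        spec = PopulationSpec(
            n_flies_per_group=2000,
            genotypes=("g1", "g2", "g3"),
            sexes=("both",),
            bias_mean=0.5,
            bias_sd=0.10,
            group_effects={"g2": {"bias": 1.5}, "g3": {"bias": 2.0}},
            seed=11,
        )
        truth, _ = sample_population(spec)
        out = group_cv(truth["p_true"], truth["genotype"]).set_index("group")
        for g, factor in [("g1", 1.0), ("g2", 1.5), ("g3", 2.0)]:
            assert out.loc[g, "cv"] == pytest.approx(0.2 * factor, abs=0.02)


class TestMetadataModel:
    def test_two_group_coefficient(self):
        df = pd.DataFrame(
            {"y": [0.4] * 20 + [0.6] * 20, "grp": ["a"] * 20 + ["b"] * 20}
        )
        res = fit_metadata_model(df, "y", ["grp"])
        assert res.coefficients["grp_b"] == pytest.approx(0.2)
        assert res.intercept == pytest.approx(0.4)

    def test_duplicated_predictor_rank_deficiency(self, rng):
        df = pd.DataFrame(
            {
                "y": rng.standard_normal(30),
                "a": np.repeat(["u", "v", "w"], 10),
            }
        )
        df["a_copy"] = df["a"]
        with pytest.raises(RankDeficiencyError) as err:
            fit_metadata_model(df, "y", ["a", "a_copy"])
        assert any("a_copy" in c for c in err.value.aliased)

    def test_null_predictors_give_uniform_pvalues(self, rng):
        """Noise response on random categorical predictors: p ~ Uniform(0,1)."""
        n = 400
        df = pd.DataFrame({"y": rng.standard_normal(n)})
        preds = []
        for j in range(10):
            df[f"x{j}"] = rng.choice(["a", "b", "c"], size=n)
            preds.append(f"x{j}")
        res = fit_metadata_model(df, "y", preds)
        ks = stats.kstest(res.p_values.to_numpy(), "uniform")
        assert ks.pvalue > 0.01


class TestEnrichment:
    def test_uniform_pvalues_not_enriched(self, rng):
        p = rng.uniform(size=100)
        res = genotype_enrichment(p, alpha=0.05)
        assert res.expected == pytest.approx(5.0)
        assert res.p_value > 0.05

    def test_all_tiny_pvalues_fully_enriched(self):
        res = genotype_enrichment(np.full(200, 0.001), alpha=0.05)
        assert res.n_below == 200
        assert res.p_value < 1e-100

    def test_published_scale_counts_are_enriched(self):
        """47 of 569 below 0.05 is a significant excess over the 28.45 expected."""
        p = np.concatenate([np.full(47, 0.01), np.full(569 - 47, 0.5)])
        res = genotype_enrichment(p, alpha=0.05)
        assert res.n_below == 47
        assert res.p_value < 0.05

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            genotype_enrichment([])
        with pytest.raises(ValueError):
            genotype_enrichment([0.0, 0.5])

    def test_genotype_pvalues_uniform_under_null(self, rng):
        y = rng.normal(0.5, 0.1, 3000)
        g = rng.choice([f"g{i}" for i in range(30)], size=3000)
        p = genotype_pvalues(y, g)
        assert len(p) == 30
        assert stats.kstest(p.to_numpy(), "uniform").pvalue > 0.01


class TestCorrelation:
    def test_perfect_correlations(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        assert measure_correlation(x, x)[0] == pytest.approx(1.0)
        assert measure_correlation(x, -x + 7)[0] == pytest.approx(-1.0)

    def test_five_point_hand_computation(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([2.0, 1.0, 4.0, 3.0, 5.0])
        r_hand = np.cov(x, y, ddof=1)[0, 1] / (x.std(ddof=1) * y.std(ddof=1))
        r, p = measure_correlation(x, y)
        assert r == pytest.approx(r_hand)
        assert 0 < p <= 1

    def test_degenerate_inputs(self):
        with pytest.raises(ValueError):
            measure_correlation([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        with pytest.raises(ValueError):
            measure_correlation([1.0], [2.0])


def _cv_table(rng, n_genotypes=8, n=60, treat_scale=1.0):
    rows = []
    for i in range(n_genotypes):
        mu = 10 + i
        for cond, scale in [("ctrl", 1.0), ("drug", treat_scale)]:
            y = rng.normal(mu, 1.0 * scale * (1 + 0.05 * i), size=n)
            rows.append(pd.DataFrame({"numTurns": y, "genotype": f"g{i}", "expCond": cond}))
    return pd.concat(rows, ignore_index=True)


class TestPairedEffect:
    def test_identical_conditions_null_effect(self, rng):
        df = _cv_table(rng)
        df_dup = pd.concat(
            [df.assign(expCond="ctrl"), df.assign(expCond="drug")], ignore_index=True
        )
        res = paired_effect(df_dup, "numTurns", "ctrl", "drug")
        assert res.effect_pct == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_doubled_treatment_sd_recovered(self, rng):
        df = _cv_table(rng, n_genotypes=12, n=400, treat_scale=2.0)
        res = paired_effect(df, "numTurns", "ctrl", "drug")
        assert res.effect_pct == pytest.approx(100.0, abs=15.0)
        assert res.p_value < 0.01

    def test_antisymmetry_under_condition_swap(self, rng):
        df = _cv_table(rng, n_genotypes=10, n=200, treat_scale=1.5)
        fwd = paired_effect(df, "numTurns", "ctrl", "drug")
        rev = paired_effect(df, "numTurns", "drug", "ctrl")
        assert rev.p_value == pytest.approx(fwd.p_value)
        e = fwd.effect_pct
        assert rev.effect_pct == pytest.approx(-e / (1 + e / 100), abs=3.0)

    def test_no_overlap_raises(self, rng):
        df = _cv_table(rng, n_genotypes=4)
        df.loc[df["expCond"] == "drug", "genotype"] = "other"
        with pytest.raises(PairingError):
            paired_effect(df, "numTurns", "ctrl", "drug")

    def test_type_one_error_calibrated(self, rng):
        """Null design rejects at ≈5%: 100 replicates, count within 3σ."""
        hits = 0
        for _ in range(100):
            df = _cv_table(rng, n_genotypes=10, n=30, treat_scale=1.0)
            if paired_effect(df, "numTurns", "ctrl", "drug").p_value < 0.05:
                hits += 1
        assert hits <= 13  # Binomial(100, 0.05): P(X > 13) < 0.001


class TestMiscellaneous:
    def test_absolute_bias_examples(self):
        assert absolute_bias(0.5) == 0.0
        assert absolute_bias(0.1) == pytest.approx(0.4)
        with pytest.raises(ValueError):
            absolute_bias(1.2)

    def test_absolute_bias_fold_and_compare(self, rng):
        p = rng.uniform(size=1000)
        folded = absolute_bias(p)
        assert np.allclose(folded, np.abs(p - 0.5))
        assert folded.max() <= 0.5

    def test_temperature_merge(self):
        merged = merge_temperature_labels([22.0, 23.0, 32.0, 33.0, 25.0])
        assert merged.tolist() == [23.0, 23.0, 33.0, 33.0, 25.0]

    def test_sex_effect_recovers_injected_inflation(self):
        """A 30% male SD inflation in turn bias shows up with the right sign
        and roughly the right magnitude (half-normal mean scales with SD)."""
        spec = PopulationSpec(
            n_flies_per_group=400,
            genotypes=("g1", "g2", "g3", "g4"),
            sexes=("female", "male"),
            bias_mean=0.5,
            bias_sd=0.1,
            group_effects={("sex", "male"): {"bias": 1.3}},
            seed=21,
        )
        truth, _ = sample_population(spec)
        df = truth.rename(columns={"p_true": "handedness"})
        res = sex_variability_effect(df, "handedness")
        se_pct = res.standard_error * res.effect_pct / res.coefficient
        assert res.effect_pct > 0 and res.p_value < 0.01
        assert res.effect_pct == pytest.approx(30.0, abs=max(2 * se_pct, 5.0))
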