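"""Direct standardization, the two regression stages, selection, reporting."""

import numpy as np
import pandas as pd
import pytest

from admixmort.association import (
    direct_standardize,
    filter_categories,
    fit_stage1,
    fit_stage2,
    highlight_threshold,
    percent_excess,
    projected_excess,
    smr_report,
    standardized_rates,
    stepwise_forward,
)


class TestDirectStandardize:
    def test_standard_age_structure_gives_crude_rate(self):
        table = pd.DataFrame(
            {
                "age_band": ["young", "old"],
                "deaths": [30.0, 90.0],
                "person_years": [600000.0, 400000.0],
            }
        )
        weights = pd.Series([0.6, 0.4], index=["young", "old"])
        crude = (30 + 90) / (600000 + 400000) * 1e5
        assert direct_standardize(table, weights) == pytest.approx(crude)

    def test_equal_weights_average_band_rates(self):
        table = pd.DataFrame(
            {"age_band": ["a", "b"], "deaths": [10.0, 30.0],
             "person_years": [1e5, 1e5]}
        )
        weights = pd.Series([0.5, 0.5], index=["a", "b"])
        assert direct_standardize(table, weights) == pytest.approx(20.0)

    def test_unequal_weights(self):
        table = pd.DataFrame(
            {"age_band": ["a", "b"], "deaths": [10.0, 30.0],
             "person_years": [1e5, 1e5]}
        )
        weights = pd.Series([0.2, 0.8], index=["a", "b"])
        assert direct_standardize(table, weights) == pytest.approx(26.0)

    def test_weights_renormalized_with_warning(self):
        table = pd.DataFrame(
            {"age_band": ["a", "b"], "deaths": [10.0, 30.0],
             "person_years": [1e5, 1e5]}
        )
        with pytest.warns(UserWarning, match="renormalizing"):
            rate = direct_standardize(table, pd.Series([1.0, 1.0], index=["a", "b"]))
        assert rate == pytest.approx(20.0)

    def test_zero_person_years_with_deaths_is_error(self):
        table = pd.DataFrame(
            {"age_band": ["a"], "deaths": [3.0], "person_years": [0.0]}
        )
        with pytest.raises(ValueError, match="zero person-years"):
            direct_standardize(table, pd.Series([1.0], index=["a"]))


class TestFilterCategories:
    def test_boundary_is_inclusive(self):
        table = pd.DataFrame(
            {
                "icd10": ["A", "A", "B", "C"],
                "deaths": [49, 50, 100, 5000],
                "region": ["r1", "r2", "r1", "r1"],
                "year": [2005] * 4,
            }
        )
        retained, totals = filter_categories(table, min_deaths=100)
        assert retained == ["B", "C"]
        assert totals["A"] == 99

    def test_all_below_threshold_gives_empty(self):
        table = pd.DataFrame({"icd10": ["A"], "deaths": [5]})
        retained, _ = filter_categories(table, min_deaths=100)
        assert retained == []

    def test_synthetic_default_matches_recount(self):
        from admixmort.synthetic import default_cohort_config, default_mortality_model, simulate_mortality

        model = default_mortality_model()
        cfg = default_cohort_config(n_individuals=100, seed=0)
        q = np.array([r.concentration / r.concentration.sum() for r in cfg.regions])
        regional = pd.DataFrame(
            q, index=[r.name for r in cfg.regions], columns=["AFR", "EUR", "MAP", "AYM"]
        )
        table = simulate_mortality(model, regional, seed=1)
        retained, totals = filter_categories(table)
        by_hand = sorted(
            icd for icd in model.icd_categories
            if table.loc[table.icd10 == icd, "deaths"].sum() >= 100
        )
        assert retained == by_hand
        assert "C99" not in retained  # the tiny preset stays under 100 deaths


class TestStage1:
    def test_single_region_intercept_only_is_the_mean(self, rng):
        x = rng.uniform(0.2, 0.6, 50)
        cov = pd.DataFrame({"region": ["R1"] * 50})
        m = fit_stage1(cov, pd.Series(x, name="q"), factors=[])
        assert m.regional.loc["R1", "expected"] == pytest.approx(x.mean())

    def test_reference_stratum_offset_worked_example(self):
        """Intercept 0.40, high-class offset -0.06: expected 34% in that stratum.

        Built from a balanced two-level design whose OLS solution is exactly
        the two group means."""
        n = 200
        ses = ["DE"] * n + ["ABC1"] * n
        x = np.array([0.40] * n + [0.34] * n)
        cov = pd.DataFrame({"region": ["R1"] * (2 * n), "ses": ses})
        m = fit_stage1(
            cov, pd.Series(x, name="q"), factors=["ses"], references={"ses": "DE"}
        )
        params = dict(zip(m.result.params.index, m.result.params))
        assert params["Intercept"] == pytest.approx(0.40)
        offset = [v for k, v in params.items() if "ABC1" in k][0]
        assert offset == pytest.approx(-0.06)
        assert 0.40 + offset == pytest.approx(0.34)

    def test_regional_recovery_on_synthetic_offsets(self, rng):
        regions = [f"R{i}" for i in range(6)]
        true_means = np.linspace(0.25, 0.55, 6)
        rows = []
        for r, mu in zip(regions, true_means):
            for _ in range(300):
                rows.append((r, np.clip(rng.normal(mu, 0.08), 0, 1)))
        df = pd.DataFrame(rows, columns=["region", "q"])
        m = fit_stage1(df, df["q"], factors=[])
        got = m.regional["expected"].loc[regions].to_numpy()
        assert np.abs(got - true_means).max() < 3 * 0.08 / np.sqrt(300)

    def test_expectations_clipped_with_warning(self):
        cov = pd.DataFrame({"region": ["R1", "R1"], "z": ["a", "b"]})
        x = pd.Series([-0.2, -0.1], name="q")
        with pytest.warns(UserWarning, match="clipped"):
            m = fit_stage1(cov, x, factors=[])
        assert (m.regional["expected"] >= 0).all()

    def test_mean_evaluation_reproduces_regional_means_without_covariates(self, rng):
        cov = pd.DataFrame({"region": rng.choice(["A", "B", "C"], 200)})
        x = pd.Series(rng.uniform(0, 1, 200), name="q")
        m = fit_stage1(cov, x, factors=[], evaluation="mean")
        direct = x.groupby(cov["region"]).mean()
        np.testing.assert_allclose(
            m.regional["expected"].loc[direct.index], direct, atol=1e-10
        )


class TestStepwise:
    def _noise_frame(self, rng, n=2000):
        return pd.DataFrame(
            {
                "y": rng.normal(size=n),
                "f1": rng.choice(list("ab"), n),
                "f2": rng.choice(list("abc"), n),
                "f3": rng.choice(list("ab"), n),
            }
        )

    def test_pure_noise_rarely_selects(self):
        """Size calibration: at alpha 0.1 per candidate, an empty selection
        in most replicates."""
        rng = np.random.default_rng(7)
        empty = 0
        n_rep = 50
        for _ in range(n_rep):
            df = self._noise_frame(rng)
            sel = stepwise_forward(df, "y", ["f1", "f2", "f3"])
            empty += not sel
        assert empty >= 0.60 * n_rep  # > (1-0.1)^3 would be ~73% if independent

    def test_strong_factor_always_found(self):
        rng = np.random.default_rng(8)
        hits = 0
        for _ in range(20):
            df = self._noise_frame(rng, n=1500)
            df["y"] += np.where(df["f2"] == "a", 1.0, 0.0)
            sel = stepwise_forward(df, "y", ["f1", "f2", "f3"])
            hits += "f2" in sel
        assert hits >= 19

    def test_zero_entry_threshold_selects_nothing(self, rng):
        df = self._noise_frame(rng)
        df["y"] += np.where(df["f1"] == "a", 5.0, 0.0)
        assert stepwise_forward(df, "y", ["f1", "f2"], alpha_enter=0.0) == []

    def test_forced_factors_always_kept(self, rng):
        df = self._noise_frame(rng)
        sel = stepwise_forward(df, "y", ["f1", "f2"], forced=("f3",))
        assert sel[0] == "f3"


class TestStage2:
    def test_two_region_saturated_closed_form(self):
        """Deterministic rates with ratio 2 across a 24-point difference:
        exp(beta) = 2**(1/24) ~ 1.0293."""
        rows = []
        for year in (2005, 2006):
            rows.append(("lo", year, 10.0, 1e6))
            rows.append(("hi", year, 20.0, 1e6))
        rates = pd.DataFrame(rows, columns=["region", "year", "rate", "person_years"])
        x = pd.Series({"lo": 30.0, "hi": 54.0})
        m = fit_stage2(rates, x)
        assert m.smr == pytest.approx(2 ** (1 / 24), rel=1e-6)
        assert m.smr == pytest.approx(1.0293, abs=2e-4)

    def test_null_coverage_approximately_nominal(self):
        """Generative beta = 0: the 95% CI covers 1.0 at about the nominal
        rate over 60 replicates (binomial envelope)."""
        rng = np.random.default_rng(9)
        regions = [f"R{i}" for i in range(15)]
        x = pd.Series(np.linspace(20, 60, 15), index=regions)
        py = 5e5
        cover = 0
        n_rep = 60
        for _ in range(n_rep):
            rows = []
            for r in regions:
                mu = 15.0 / 1e5 * py
                for year in range(7):
                    rows.append((r, year, rng.poisson(mu) / py * 1e5, py))
            rates = pd.DataFrame(
                rows, columns=["region", "year", "rate", "person_years"]
            )
            m = fit_stage2(rates, x)
            cover += m.ci_low <= 1.0 <= m.ci_high
        assert cover >= 0.85 * n_rep

    def test_needs_two_regions(self):
        rates = pd.DataFrame(
            {"region": ["A", "A"], "year": [1, 2], "rate": [5.0, 6.0],
             "person_years": [1e5, 1e5]}
        )
        with pytest.raises(ValueError, match="two regions"):
            fit_stage2(rates, pd.Series({"A": 10.0}))

    def test_gee_variant_agrees_on_strong_signal(self):
        rng = np.random.default_rng(10)
        regions = [f"R{i}" for i in range(10)]
        x = pd.Series(np.linspace(20, 60, 10), index=regions)
        rows = []
        for r in regions:
            rate = 5.0 * np.exp(0.03 * (x[r] - 40))
            for year in range(5):
                rows.append((r, year, rng.poisson(rate * 10) / 10, 1e5))
        rates = pd.DataFrame(rows, columns=["region", "year", "rate", "person_years"])
        m_glm = fit_stage2(rates, x, model="poisson")
        m_gee = fit_stage2(rates, x, model="gee")
        assert m_gee.smr == pytest.approx(m_glm.smr, rel=0.02)


class TestReporting:
    def test_threshold_scaling(self):
        assert highlight_threshold(500) == pytest.approx(0.0001)
        assert highlight_threshold(1) == pytest.approx(0.05)
        assert highlight_threshold(20) == pytest.approx(0.0025)

    def test_boundary_p_not_highlighted(self):
        fits = [
            {"icd": "A", "component": "MAP", "deaths": 500, "smr": 1.1,
             "ci_low": 1.0, "ci_high": 1.2, "p_value": 0.05},
            {"icd": "B", "component": "MAP", "deaths": 500, "smr": 1.2,
             "ci_low": 1.1, "ci_high": 1.3, "p_value": 0.049},
        ]
        table = smr_report(fits, n_categories=1)
        flagged = table.set_index("icd")["highlight"]
        assert not flagged["A"] and flagged["B"]

    def test_excess_projections(self):
        assert percent_excess(1.037) == pytest.approx(3.7)
        assert projected_excess(1.037, 24) == pytest.approx(88.8)
        assert projected_excess(1.037, 5) == pytest.approx(18.5)


class TestStandardizedRates:
    def test_one_row_per_region_year(self):
        from admixmort.synthetic import default_mortality_model, default_cohort_config, simulate_mortality

        model = default_mortality_model()
        cfg = default_cohort_config(n_individuals=100, seed=0)
        q = np.array([r.concentration / r.concentration.sum() for r in cfg.regions])
        regional = pd.DataFrame(
            q, index=[r.name for r in cfg.regions], columns=["AFR", "EUR", "MAP", "AYM"]
        )
        table = simulate_mortality(model, regional, seed=2)
        rates = standardized_rates(table, model.standard_weights, "C23")
        assert len(rates) == 15 * 7
        assert (rates["rate"] > 0).all()
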