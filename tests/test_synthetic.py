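"""Synthetic study generator: divergence, admixture, covariates, mortality."""

import numpy as np
import pandas as pd
import pytest

from admixmort.synthetic import (
    AncestralModel,
    CohortConfig,
    RegionConfig,
    default_ancestral_model,
    default_cohort_config,
    default_covariate_models,
    default_mortality_model,
    masking_cohort_config,
    simulate_admixed_cohort,
    simulate_mortality,
    simulate_reference_panels,
)


def two_pop_model(f=0.038, M=2000):
    return AncestralModel(
        populations=["A", "B"], M=M, tree={"A": (None, f), "B": (None, f)}
    )


class TestReferencePanels:
    def test_no_drift_limit_equals_ancestral(self):
        model = two_pop_model(f=0.0, M=300)
        panel, _ = simulate_reference_panels(model, 5, seed=1)
        np.testing.assert_array_equal(panel.freqs[0], panel.freqs[1])

    def test_invalid_drift_rejected(self):
        with pytest.raises(ValueError, match="drift"):
            AncestralModel(populations=["A", "B"], M=10,
                           tree={"A": (None, 1.0), "B": (None, 0.1)})

    def test_fixed_seed_bit_identical(self):
        model = default_ancestral_model(M=200)
        p1, g1 = simulate_reference_panels(model, 10, seed=42)
        p2, g2 = simulate_reference_panels(model, 10, seed=42)
        np.testing.assert_array_equal(p1.freqs, p2.freqs)
        for pop in model.populations:
            np.testing.assert_array_equal(g1[pop].dosage, g2[pop].dosage)

    def test_expected_pairwise_fst_tree_arithmetic(self):
        model = default_ancestral_model(M=10)
        # MAP and AYM split below NAT: mean of the two edge drifts
        assert model.expected_pairwise_fst("MAP", "AYM") == pytest.approx(0.038)
        # AFR vs EUR: independent drifts from the root
        assert model.expected_pairwise_fst("AFR", "EUR") == pytest.approx(
            (0.20 + 0.08) / 2
        )
        # African most diverged, European intermediate, Natives closest
        d_afr = model.expected_pairwise_fst("AFR", "MAP")
        d_eur = model.expected_pairwise_fst("EUR", "MAP")
        d_nat = model.expected_pairwise_fst("AYM", "MAP")
        assert d_afr > d_eur > d_nat

    def test_realized_fst_tracks_expectation(self):
        """Repeat-seed envelope around the Balding-Nichols expectation."""
        from admixmort.popstruct import fst_wc

        model = two_pop_model(0.10, M=3000)
        ests = []
        for seed in range(5):
            _, genos = simulate_reference_panels(model, 40, seed=seed)
            ests.append(fst_wc(genos["A"], genos["B"]))
        assert abs(np.mean(ests) - 0.10) < 0.01

    def test_contamination_shifts_genotypes_toward_other_pop(self):
        model = default_ancestral_model(M=1000)
        panel, clean = simulate_reference_panels(model, 40, seed=3)
        _, contaminated = simulate_reference_panels(
            model, 40, seed=3, contamination={"MAP": ("EUR", 0.74)}
        )
        # contaminated MAP genotypes sit closer to the EUR frequencies
        dist_clean = np.abs(clean["MAP"].dosage.mean(0) / 2 - panel.freqs[1]).mean()
        dist_cont = np.abs(
            contaminated["MAP"].dosage.mean(0) / 2 - panel.freqs[1]
        ).mean()
        assert dist_cont < dist_clean


class TestAdmixedCohort:
    def test_degenerate_dirichlet_recovers_population_freqs(self):
        model = two_pop_model(0.2, M=400)
        panel, _ = simulate_reference_panels(model, 5, seed=0)
        cfg = CohortConfig(
            regions=[RegionConfig("R1", np.array([5000.0, 0.001]), 400)],
            covariate_model={},
            seed=9,
        )
        genotypes, _, true_q = simulate_admixed_cohort(panel, cfg)
        assert true_q["A"].min() > 0.99
        err = np.abs(genotypes.allele_freq() - panel.freqs[0])
        assert err.mean() < 0.02

    def test_mean_dosage_matches_exact_expectation(self):
        model = default_ancestral_model(M=300)
        panel, _ = simulate_reference_panels(model, 5, seed=1)
        cfg = default_cohort_config(n_individuals=2000, seed=4)
        genotypes, cov, true_q = simulate_admixed_cohort(panel, cfg)
        qbar = true_q[panel.populations].mean().to_numpy()
        expected = 2.0 * qbar @ panel.freqs
        observed = genotypes.dosage.mean(axis=0)
        # binomial Monte-Carlo error at n=2000: sd <= sqrt(2)/sqrt(n) ~ 0.032
        assert np.abs(observed - expected).max() < 5 * np.sqrt(2.0 / 2000) + 0.05

    def test_regional_gradients_point_in_configured_direction(self):
        model = default_ancestral_model(M=50)
        panel, _ = simulate_reference_panels(model, 5, seed=1)
        cfg = default_cohort_config(n_individuals=1500, seed=5)
        _, cov, true_q = simulate_admixed_cohort(panel, cfg)
        merged = true_q.merge(cov[["sample_id", "region"]], on="sample_id")
        reg = merged.groupby("region")[["MAP", "AYM"]].mean()
        # southern (last) regions more Mapuche-like, northern more Aymara-like
        assert reg["MAP"].loc["R15"] > reg["MAP"].loc["R01"]
        assert reg["AYM"].loc["R01"] > reg["AYM"].loc["R15"]

    def test_covariates_couple_to_ancestry(self):
        model = default_ancestral_model(M=50)
        panel, _ = simulate_reference_panels(model, 5, seed=1)
        cfg = default_cohort_config(n_individuals=3000, seed=6)
        _, cov, true_q = simulate_admixed_cohort(panel, cfg)
        merged = true_q.merge(cov, on="sample_id")
        # higher socioeconomic class goes with lower Mapuche-like ancestry
        abc1 = merged.loc[merged["ses"] == "ABC1", "MAP"].mean()
        de = merged.loc[merged["ses"] == "D/E", "MAP"].mean()
        assert abc1 < de

    def test_missing_concentration_is_config_error(self):
        model = two_pop_model(M=20)
        panel, _ = simulate_reference_panels(model, 5, seed=0)
        cfg = CohortConfig(
            regions=[RegionConfig("R1", np.array([1.0, 1.0, 1.0]), 10)],
            covariate_model={},
            seed=0,
        )
        with pytest.raises(ValueError, match="concentration"):
            simulate_admixed_cohort(panel, cfg)

    def test_duplicate_region_labels_rejected(self):
        with pytest.raises(ValueError, match="unique"):
            CohortConfig(
                regions=[
                    RegionConfig("R1", np.array([1.0]), 5),
                    RegionConfig("R1", np.array([1.0]), 5),
                ],
                covariate_model={},
                seed=0,
            )


class TestMortality:
    @pytest.fixture
    def regional(self):
        model = default_ancestral_model(M=10)
        cfg = default_cohort_config(n_individuals=150, seed=2)
        names = [r.name for r in cfg.regions]
        q = np.array([r.concentration / r.concentration.sum() for r in cfg.regions])
        return pd.DataFrame(q, index=names, columns=model.populations)

    def test_null_effects_share_one_rate(self, regional):
        model = default_mortality_model()
        table = simulate_mortality(model, regional, seed=3)
        null = table[table["icd10"] == "NULL"]
        per_region = null.groupby("region").apply(
            lambda d: d["deaths"].sum() / d["person_years"].sum(), include_groups=False
        )
        # all regions share the same expected rate: relative spread is Poisson-level
        assert per_region.max() / per_region.min() < 1.2

    def test_closed_form_rate_ratio(self):
        """24-point ancestry difference at +3.7%/point: ratio 1.037^24 ~ 2.39."""
        model = default_mortality_model()
        regional = pd.DataFrame(
            [[0.0, 0.70, 0.30, 0.0], [0.0, 0.46, 0.54, 0.0]],
            index=["lo", "hi"],
            columns=["AFR", "EUR", "MAP", "AYM"],
        )
        py = model.person_years.iloc[:2].copy()
        py.index = ["lo", "hi"]
        model.person_years = pd.concat([model.person_years, py])
        eff = model.effects["C23"]
        lin = 100.0 * regional.to_numpy() @ eff
        ratio = np.exp(lin[1] - lin[0])
        assert ratio == pytest.approx(1.037**24)
        assert ratio == pytest.approx(2.39, abs=0.01)

    def test_total_deaths_within_poisson_envelope(self, regional):
        model = default_mortality_model()
        table = simulate_mortality(model, regional, seed=11)
        for icd in model.icd_categories:
            sub = table[table["icd10"] == icd]
            expected = 0.0
            eff = np.asarray(model.effects[icd])
            for region in regional.index:
                lin = 100.0 * regional.loc[region].to_numpy() @ eff
                for band in model.age_bands:
                    py = model.person_years.loc[region, band]
                    expected += (
                        len(model.years)
                        * py
                        * model.baseline_per1e5[icd]
                        / 1e5
                        * np.exp(lin + model.age_log_multipliers[band])
                    )
            observed = sub["deaths"].sum()
            assert abs(observed - expected) < 4.0 * np.sqrt(expected) + 1

    def test_seed_reproducible(self, regional):
        model = default_mortality_model()
        t1 = simulate_mortality(model, regional, seed=5)
        t2 = simulate_mortality(model, regional, seed=5)
        pd.testing.assert_frame_equal(t1, t2)

    def test_rows_must_sum_to_one(self):
        model = default_mortality_model()
        bad = pd.DataFrame(
            [[0.5, 0.2, 0.1, 0.1]], index=["R01"], columns=["AFR", "EUR", "MAP", "AYM"]
        )
        with pytest.raises(ValueError, match="sum to 1"):
            simulate_mortality(model, bad, seed=0)

    def test_opposite_effects_attenuate_pooled_sum(self):
        """Equal-and-opposite Native effects: the fitted coefficient on the
        pooled Native sum is much smaller than either split coefficient."""
        from admixmort.association import fit_stage2, standardized_rates

        model = default_mortality_model()
        cfg = masking_cohort_config(n_individuals=150, seed=2)
        names = [r.name for r in cfg.regions]
        q = np.array([r.concentration / r.concentration.sum() for r in cfg.regions])
        regional = pd.DataFrame(q, index=names, columns=["AFR", "EUR", "MAP", "AYM"])
        table = simulate_mortality(model, regional, seed=21)
        rates = standardized_rates(table, model.standard_weights, "J45")
        fits = {}
        for comp in ("MAP", "AYM"):
            fits[comp] = fit_stage2(rates, regional[comp] * 100)
        pooled = fit_stage2(rates, (regional["MAP"] + regional["AYM"]) * 100)
        assert abs(np.log(pooled.smr)) < 0.5 * abs(np.log(fits["MAP"].smr))
        assert abs(np.log(pooled.smr)) < 0.5 * abs(np.log(1.03))
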