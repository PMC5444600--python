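"""End-to-end orchestration on the synthetic study preset.

``run_pipeline`` executes the full chain — reference panels, admixed
cohort, genotype QC and LD pruning, supervised ancestry estimation,
two-stage ecological regression per disease category and ancestry
component, and the sensitivity procedures — from a single seeded
configuration, writing every table plus a config/provenance snapshot to
an output directory.  ``experiment_masking`` runs the headline contrast:
pooled-Native versus split Mapuche-like/Aymara-like reference sets, for
both ancestry-estimation bias and effect masking.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as amio
from .ancestry import ReferencePanel, estimate_ancestry_matrix, estimate_reference_freqs
from .association import (
    filter_categories,
    fit_stage1,
    fit_stage2,
    smr_report,
    standardized_rates,
    stepwise_forward,
)
from .popstruct import ld_prune, qc_filter
from .sensitivity import loo_influence, resample_smr
from .synthetic import (
    default_ancestral_model,
    default_cohort_config,
    default_mortality_model,
    masking_cohort_config,
    simulate_admixed_cohort,
    simulate_mortality,
    simulate_reference_panels,
)

logger = logging.getLogger("admixmort")

COVARIATE_CANDIDATES = ["age_class", "gender", "education", "ses", "salary"]


@dataclass
class PipelineConfig:
    """All knobs of a pipeline run; defaults are the study preset."""

    seed: int = 0
    outdir: str | None = None
    n_individuals: int = 1800
    n_markers: int = 2000
    # reference panels large enough that allele-frequency noise (var pq/2n)
    # is small next to the Native subcomponent divergence (2F pq, F=0.038):
    # the regression attenuation on the Mapuche-Aymara contrast is then
    # 2F/(2F + 1/n) ~ 0.98
    n_per_pop: int = 800
    max_missing: float = 0.05
    min_maf: float = 0.05
    ld_r2_max: float = 0.1
    ld_window: int = 50
    ld_step: int = 5
    reference_set: str = "split"  # "split" or "pooled" Native reference
    stage2_model: str = "poisson"  # or "gee"
    stage1_evaluation: str = "reference"
    min_deaths: int = 100
    focal_icd: str = "C23"
    resample_draws: int = 2000
    resample_scale: float = 1.0
    cohort_preset: str = "default"  # or "masking"

    def __post_init__(self) -> None:
        if self.reference_set not in ("split", "pooled"):
            raise ValueError("reference_set must be 'split' or 'pooled'")
        if self.cohort_preset not in ("default", "masking"):
            raise ValueError("cohort_preset must be 'default' or 'masking'")
        if not (0 <= self.max_missing <= 1 and 0 <= self.min_maf <= 0.5):
            raise ValueError("QC thresholds outside documented ranges")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls(**amio.read_yaml(path))


def _subseeds(seed: int, n: int) -> list[int]:
    """Independent sub-stream seeds derived from one master seed."""
    return [int(s) for s in np.random.SeedSequence(seed).generate_state(n) % (2**31)]


def _prepare_cohort(cfg: PipelineConfig):
    """Panels, cohort, QC'd and pruned genotypes harmonized with the panel."""
    s_panel, s_cohort, s_mort = _subseeds(cfg.seed, 3)
    model = default_ancestral_model(M=cfg.n_markers)
    truth_panel, ref_genos = simulate_reference_panels(model, cfg.n_per_pop, seed=s_panel)
    preset = default_cohort_config if cfg.cohort_preset == "default" else masking_cohort_config
    cohort_cfg = preset(n_individuals=cfg.n_individuals, seed=s_cohort)
    genotypes, covariates, true_q = simulate_admixed_cohort(truth_panel, cohort_cfg)

    qc_geno, report = qc_filter(genotypes, cfg.max_missing, cfg.min_maf)
    logger.info("QC: %s", report.to_dict())
    pruned = ld_prune(qc_geno, cfg.ld_r2_max, cfg.ld_window, cfg.ld_step)
    report.removed_ld = qc_geno.n_variants - pruned.n_variants
    report.variants_out = pruned.n_variants
    logger.info("LD pruning retained %d variants", pruned.n_variants)

    # reference panel from sampled reference genotypes, restricted to the
    # cohort's post-QC variant set
    merged_refs = ref_genos[truth_panel.populations[0]]
    stacked = np.vstack([ref_genos[p].dosage for p in truth_panel.populations])
    samples = sum((ref_genos[p].samples for p in truth_panel.populations), [])
    labels = {
        s: p for p in truth_panel.populations for s in ref_genos[p].samples
    }
    from .genotypes import GenotypeMatrix

    ref_all = GenotypeMatrix(samples=samples, variants=merged_refs.variants.copy(), dosage=stacked)
    keep = merged_refs.variant_keys().isin(pruned.variant_keys())
    ref_all = ref_all.take_variants(np.asarray(keep))
    panel = estimate_reference_freqs(ref_all, labels)
    if cfg.reference_set == "pooled":
        panel = panel.pool(["MAP", "AYM"], "NAT")
    return truth_panel, panel, pruned, covariates, true_q, report, s_mort


def _stage1_all(
    cfg: PipelineConfig, estimates: pd.DataFrame, covariates: pd.DataFrame, components: list[str]
) -> dict:
    """Stepwise selection and stage-1 fit per ancestry component."""
    merged = covariates.merge(estimates, on="sample_id")
    out = {}
    for comp in components:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            selected = stepwise_forward(
                merged, comp, COVARIATE_CANDIDATES, forced=("region",)
            )
            out[comp] = fit_stage1(
                merged,
                merged[comp],
                [f for f in selected if f != "region"],
                evaluation=cfg.stage1_evaluation,
            )
        logger.info("stage 1 [%s]: factors %s", comp, selected)
    return out


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute every stage on the synthetic preset; returns the bundle.

    The bundle maps stage names to in-memory results (QC report, ancestry
    estimates, stage-1 models, association table, sensitivity outputs,
    ground truth).  When ``cfg.outdir`` is set, all tables are also
    written there together with a config snapshot, and a rerun with the
    same config reproduces them bit-for-bit.
    """
    truth_panel, panel, pruned, covariates, true_q, report, s_mort = _prepare_cohort(cfg)

    frame, _ = estimate_ancestry_matrix(pruned, panel)
    components = list(panel.populations)
    if cfg.reference_set == "split":
        frame["NAT_SUM"] = frame["MAP"] + frame["AYM"]
        components = components + ["NAT_SUM"]

    stage1 = _stage1_all(cfg, frame, covariates, components)

    # mortality generated from the realized regional mean of the true Q
    regional_truth = (
        true_q.merge(covariates[["sample_id", "region"]], on="sample_id")
        .groupby("region")[truth_panel.populations]
        .mean()
    )
    mort_model = default_mortality_model()
    mortality = simulate_mortality(mort_model, regional_truth, seed=s_mort)
    weights = mort_model.standard_weights

    retained, totals = filter_categories(mortality, cfg.min_deaths)
    logger.info("categories retained: %s of %s", len(retained), len(totals))

    fits = []
    stage2_models: dict[tuple[str, str], object] = {}
    for icd in retained:
        rates = standardized_rates(mortality, weights, icd)
        for comp in components:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                m2 = fit_stage2(
                    rates, stage1[comp].expectations_pct(), model=cfg.stage2_model
                )
            stage2_models[(icd, comp)] = m2
            fits.append(
                {
                    "icd": icd,
                    "component": comp,
                    "deaths": int(totals[icd]),
                    "smr": m2.smr,
                    "ci_low": m2.ci_low,
                    "ci_high": m2.ci_high,
                    "p_value": m2.p_value,
                }
            )
    association = smr_report(fits, n_categories=len(retained))

    # sensitivity on the focal category and Mapuche-like component
    focal_comp = "MAP" if cfg.reference_set == "split" else "NAT"
    merged = covariates.merge(frame, on="sample_id").set_index("sample_id")
    influence = loo_influence(merged[focal_comp], merged["region"])
    resample = None
    if cfg.focal_icd in retained:
        rates = standardized_rates(mortality, weights, cfg.focal_icd)
        resample = resample_smr(
            stage1[focal_comp].expectations_pct(),
            stage1[focal_comp].se_pct(),
            rates,
            S=cfg.resample_draws,
            seed=_subseeds(cfg.seed, 4)[3],
            scale=cfg.resample_scale,
            model=cfg.stage2_model,
        )

    bundle = {
        "config": asdict(cfg),
        "qc_report": report.to_dict(),
        "ancestry_estimates": frame,
        "stage1": stage1,
        "regional_truth": regional_truth,
        "mortality": mortality,
        "association": association,
        "stage2_models": stage2_models,
        "influence": influence,
        "resample": resample,
        "truth_smr": mort_model.truth_smr(),
        "true_q": true_q,
    }
    if cfg.outdir:
        _write_bundle(bundle, Path(cfg.outdir))
    return bundle


def _write_bundle(bundle: dict, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    amio.write_yaml(bundle["config"], outdir / "config_snapshot.yaml")
    amio.write_json(bundle["qc_report"], outdir / "qc_report.json")
    bundle["ancestry_estimates"].to_csv(outdir / "ancestry_estimates.csv", index=False)
    bundle["regional_truth"].to_csv(outdir / "regional_truth.csv")
    bundle["mortality"].to_csv(outdir / "mortality.csv", index=False)
    bundle["association"].to_csv(outdir / "association.csv", index=False)
    bundle["influence"].to_csv(outdir / "influence.csv", index=False)
    regional = pd.concat(
        {c: m.regional for c, m in bundle["stage1"].items()}, names=["component"]
    )
    regional.to_csv(outdir / "stage1_regional.csv")
    if bundle["resample"] is not None:
        rs = bundle["resample"]
        amio.write_json(
            {
                "median": rs.median,
                "q025": rs.q025,
                "q975": rs.q975,
                "n_requested": rs.n_requested,
                "n_failed": rs.n_failed,
            },
            outdir / "resample_summary.json",
        )
    amio.write_json(bundle["truth_smr"], outdir / "truth_smr.json")
    logger.info("bundle written to %s", outdir)


# ---------------------------------------------------------------------------
# headline experiment: pooled vs split Native reference
# ---------------------------------------------------------------------------

def pooled_vs_split_estimates(
    panel: ReferencePanel, genotypes, min_native: float = 0.5
) -> dict:
    """Pooled-reference Native estimates against the split-panel sum.

    Estimates every individual twice — against the split panel and
    against a two-component panel (European plus both Native
    subcomponents merged) — and summarises the scatter restricted to
    individuals whose split-sum Native proportion is at least
    ``min_native``: OLS slope of pooled on split-sum, and the mean
    underestimation (split-sum minus pooled).
    """
    split_frame, _ = estimate_ancestry_matrix(genotypes, panel)
    merged = panel.pool(["MAP", "AYM"], "NAT")
    idx = [merged.populations.index("EUR"), merged.populations.index("NAT")]
    pooled_panel = ReferencePanel(
        populations=[merged.populations[i] for i in idx],
        freqs=merged.freqs[idx],
        n_samples={p: merged.n_samples[p] for p in ("EUR", "NAT")},
        variants=merged.variants,
    )
    pooled_frame, _ = estimate_ancestry_matrix(genotypes, pooled_panel)
    split_sum = split_frame["MAP"] + split_frame["AYM"]
    pooled = pooled_frame["NAT"]
    mask = split_sum >= min_native
    if mask.sum() < 3:
        raise ValueError("too few high-Native individuals for the scatter summary")
    x, y = split_sum[mask].to_numpy(), pooled[mask].to_numpy()
    slope, intercept = np.polyfit(x, y, 1)
    return {
        "slope": float(slope),
        "intercept": float(intercept),
        "mean_underestimation": float(np.mean(x - y)),
        "n_high_native": int(mask.sum()),
        "split_sum": split_sum,
        "pooled": pooled,
    }


def experiment_masking(cfg: PipelineConfig, n_replicates: int = 1) -> dict:
    """Pooled-vs-split contrast on the opposite-effects preset.

    Uses the positively-correlated Native gradients preset and the
    masking disease category (equal and opposite subcomponent effects).
    Reports, per mortality replicate, the pooled-sum fit and both split
    fits with CIs, plus the pooled-reference estimation-bias scatter.
    """
    cfg = PipelineConfig(**{**asdict(cfg), "cohort_preset": "masking", "reference_set": "split"})
    truth_panel, panel, pruned, covariates, true_q, report, s_mort = _prepare_cohort(cfg)
    frame, _ = estimate_ancestry_matrix(pruned, panel)
    frame["NAT_SUM"] = frame["MAP"] + frame["AYM"]
    stage1 = _stage1_all(cfg, frame, covariates, ["MAP", "AYM", "NAT_SUM"])

    regional_truth = (
        true_q.merge(covariates[["sample_id", "region"]], on="sample_id")
        .groupby("region")[truth_panel.populations]
        .mean()
    )
    mort_model = default_mortality_model()
    weights = mort_model.standard_weights
    icd = "J45"  # the equal-and-opposite preset category

    replicates = []
    for rep in range(n_replicates):
        mortality = simulate_mortality(mort_model, regional_truth, seed=s_mort + rep)
        rates = standardized_rates(mortality, weights, icd)
        row = {"replicate": rep}
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for comp in ("MAP", "AYM", "NAT_SUM"):
                m2 = fit_stage2(rates, stage1[comp].expectations_pct(), model=cfg.stage2_model)
                row[comp] = {
                    "smr": m2.smr,
                    "ci_low": m2.ci_low,
                    "ci_high": m2.ci_high,
                    "p_value": m2.p_value,
                }
        replicates.append(row)

    scatter = pooled_vs_split_estimates(panel, pruned)
    return {
        "icd": icd,
        "truth_smr": mort_model.truth_smr()[icd],
        "replicates": replicates,
        "estimation_bias": {
            k: scatter[k]
            for k in ("slope", "intercept", "mean_underestimation", "n_high_native")
        },
        "stage1": stage1,
        "regional_truth": regional_truth,
    }
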