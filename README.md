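# admixmort

Subcontinental ancestry components and disease-specific mortality: a
tested, reusable implementation of the aggregate-data ("ecological")
design that links genotype-derived ancestry proportions to regional
cause-specific mortality, for population geneticists and epidemiologists
working with admixed cohorts.

The motivating setting is a country settled by several ancestral groups
whose two Native subcomponents (a Mapuche-like and an Aymara-like
component) are genetically close (pairwise Weir–Cockerham Fst ≈ 0.038)
but epidemiologically distinct: pooling them can mask opposite-signed
disease associations, and estimating ancestry against a pooled reference
panel underestimates the Native proportion of subcomponent-dominant
genomes. Everything runs end-to-end on a synthetic study generator with
known ground truth, so each claim the package makes is checkable.

## The model

**Supervised ancestry estimation.** Given fixed reference allele
frequencies `f_km` for K populations, an individual's admixture vector
`q` on the simplex maximises the independent-locus binomial likelihood

    l(q) = Σ_m [ g_m · ln(Σ_k q_k f_km) + (2 − g_m) · ln(Σ_k q_k (1 − f_km)) ]

where `g_m ∈ {0,1,2}` is the alt-allele dosage (missing markers drop
out). The maximiser is found by accelerated EM; an exhaustive
simplex-lattice oracle is provided for verification.

**Two-stage ecological regression.** Stage 1 fits individual ancestry on
individual covariates by OLS, `E[X|Z] = Z'd` (age class, gender,
education, socioeconomic status, salary, region; forward stepwise
selection at α = 0.1), and evaluates the expected ancestry per region.
Stage 2 relates yearly age-standardized disease-specific mortality rates
to the expected regional ancestry in percentage points through a Poisson
log-linear model with person-time offset,

    log(μ) = β · E[X|Z] + Z̃ α + ε,

with cluster-robust (by region) errors, so `exp(β)` is the standardized
mortality ratio (SMR) per 1 % increase in the ancestry component.

**Sensitivity procedures.** Leave-one-out influence of individuals on
regional ancestry means against a 2/n cutoff; propagation of stage-1
uncertainty into the SMR by normal resampling of the regional
expectations; adjustment for additional region-level covariates; an
ancestry-informative-marker filter that drops variants whose 80 %
minor-allele-frequency confidence intervals overlap between reference
groups. A Cox proportional-hazards stage validates an association at the
individual level (hazard ratio per 1 % ancestry).

## Worked example

```python
import admixmort as am

bundle = am.run_pipeline(am.PipelineConfig(seed=1, resample_draws=500))
table = bundle["association"]
focal = table[(table.icd == "C23") & table.component.isin(["MAP", "AYM", "NAT_SUM"])]
print(focal.to_string(index=False))
rs = bundle["resample"]
print(f"resampled SMR (MAP, C23): median {rs.median:.4f} [{rs.q025:.4f}, {rs.q975:.4f}]")
```

prints (seed 1):

```
icd component  deaths    smr  ci_low  ci_high   p_value  highlight
C23       AYM   11619 0.9592   0.955   0.9635 9.333e-12       True
C23       MAP   11619  1.039   1.035    1.043 2.355e-12       True
C23   NAT_SUM   11619  1.144   1.058    1.236  0.002332       True
resampled SMR (MAP, C23): median 1.0379 [1.0347, 1.0412]
```

The focal category is generated with a +3.7 % mortality excess per 1 %
Mapuche-like ancestry and *no* structural Aymara-like effect. The fitted
Mapuche-like SMR of 1.039 [1.035, 1.043] recovers the generative 1.037;
the apparent Aymara-like protection (0.959) is the marginal imprint of
the anti-correlated north–south ancestry gradients — exactly the pattern
that makes separating the subcomponents essential. `highlight` flags
p-values below the Bonferroni-style threshold 0.05 / (number of tested
categories).

The same pipeline is available from the shell:

```sh
admixmort run --seed 1 --outdir out/
admixmort simulate --seed 3 --outdir sim/     # VCF/PLINK + CSV + truth JSON
admixmort fst sim/cohort.vcf sim/references.vcf
admixmort experiment --seed 1 --replicates 10 --out masking.json
```

## Layout

| module | contents |
| --- | --- |
| `admixmort.synthetic` | Balding–Nichols reference panels, Dirichlet-admixed cohorts with ancestry-linked covariates, Poisson regional mortality |
| `admixmort.popstruct` | genotype QC, LD pruning, genetic PCA, Weir–Cockerham Fst |
| `admixmort.ancestry` | supervised estimation, simplex-grid oracle, MAF-CI marker filter |
| `admixmort.association` | direct standardization, stage 1/stepwise, stage 2, SMR report |
| `admixmort.sensitivity` | leave-one-out influence, SMR resampling, regional-covariate adjustment |
| `admixmort.survival` | Cox proportional-hazards validation stage |
| `admixmort.io`, `admixmort.cli`, `admixmort.pipeline` | VCF/PLINK/CSV/YAML interchange, CLI, orchestration |

See `docs/methods.md` for modelling assumptions, parameter defaults and
known limitations.
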