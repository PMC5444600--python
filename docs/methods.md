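# Methods

This note records the models implemented in `admixmort`, the default
parameter choices and why they were made, what the synthetic study
generator does and does not emulate, and the numerical conventions that
affect results.

## Supervised ancestry model

Individuals are modelled as mosaics of K ancestral populations with
known (reference) alternate-allele frequencies `f_km ∈ (0,1)`. Markers
are treated as independent; the dosage at marker m is
`Binomial(2, Σ_k q_k f_km)` given the admixture vector `q` on the
K-simplex. The per-individual log-likelihood is maximised by
expectation–maximisation on the complete-data formulation
(allele-origin indicators as latent variables), which is monotone and
keeps iterates on the simplex without projection. Convergence is
declared when the per-cycle log-likelihood gain falls below 1e-7
(cap 2000 EM-step equivalents). EM steps are wrapped in safeguarded
SQUAREM extrapolation: two EM steps, a per-individual extrapolation with
step length clipped to [−16, −1], accepted only when it does not
decrease the log-likelihood. Extrapolated points are floored at 1e-4
before renormalisation because a multiplicative EM update cannot revive
a component that has collapsed numerically to zero; genuine boundary
optima are still reached by the plain EM steps, and components below
1e-8 are reported as exact zeros. Because the log-likelihood is concave
in `q`, any optimizer reaching the same likelihood is equivalent; a
brute-force simplex-lattice oracle (`grid_oracle`, resolution 0.01,
K ≤ 4) is used in tests to certify optimality.

Reference frequencies are estimated per population as
`(alt count + c) / (2·n_called + 2c)` with pseudocount `c = 0.5`,
keeping frequencies strictly interior so the log-likelihood stays
finite. Missing dosages drop out of the likelihood sum; no imputation.

### Reference-panel size as a design constraint

Estimated panel frequencies carry sampling noise with variance
`p(1−p)/2n` per population. When two reference populations are as close
as the two Native subcomponents here (pairwise Fst F = 0.038, so the
between-population frequency contrast has variance ≈ 2F·p(1−p)), this
noise attenuates the estimated subcomponent contrast like a
regression-dilution factor ≈ `2F / (2F + 1/n)`. The default preset uses
n = 800 individuals per reference population, putting the factor near
0.98 so that downstream regression slopes per percentage point of
ancestry are essentially unattenuated. Smaller panels remain fully
supported; users of few-sample panels should expect proportional
shrinkage of subcomponent contrasts.

## Synthetic study generator

The generator provides ground truth for every downstream stage; its
defaults are the study conditions under which the package's claims are
tested.

**Divergence.** Allele frequencies follow a hierarchical Balding–Nichols
scheme on a small population tree: each node's frequency is
`Beta(p(1−F)/F, (1−p)(1−F)/F)` around its parent's, with drift F equal
to the expected Fst accrued along that edge. Ancestral frequencies are
Uniform(0.05, 0.95) so that the MAF ≥ 5 % QC filter does not interact
with simulated monomorphism. The default tree has an African-like
population (F = 0.20 from the root), a European-like population
(F = 0.08), and a proto-Native node (F = 0.12) splitting into a
Mapuche-like (edge F = 0.016) and an Aymara-like (edge F = 0.060)
component. The expected pairwise Fst between two leaves is approximately
the mean of the drift accumulated since their common ancestor, giving
(0.016 + 0.060)/2 = 0.038 for the Native pair — the calibration target —
while African remains the most diverged and European intermediate. The
drift below the proto-Native node is deliberately asymmetric: the
Aymara-like component models a smaller, more isolated population with
more private drift. This matters scientifically: a merged Native
reference then carries Aymara-specific drift that Mapuche-dominant
genomes do not share, which is precisely the regime in which a pooled
reference underestimates the Native proportion of those genomes. With
perfectly symmetric drift the first-order bias cancels and the
underestimation phenomenon disappears.

**Cohort.** Individual admixture is Dirichlet within region
(concentration = 30 × regional mean vector; spread chosen so individual
proportions vary realistically around the regional mean without mass at
the simplex corners). The default preset has 15 regions with opposite
north–south gradients: Mapuche-like regional means rise linearly from
0.30 to 0.54 while Aymara-like means fall from 0.28 to 0.06, African is
flat at 0.03 and European takes the balance — mirroring the reported
regional extremes of the motivating study. A second preset
(`masking_cohort_config`) gives both Native components a shared rising
trend plus an alternating orthogonal contrast, producing positively
correlated subcomponent means with similar variances — the regime in
which equal-and-opposite effects cancel in the pooled sum. Categorical
covariates (gender, age class, education, socioeconomic status, salary)
are sampled from multinomial-logit models whose log-odds are linear in
`q`; default loadings reproduce the qualitative pattern of lower
socioeconomic status and education with higher Native components, and a
mild male excess in the Mapuche-like component.

**Mortality.** Deaths in each (region, year, ICD category, age band)
cell are Poisson with mean
`person_years × baseline/1e5 × exp(Σ_k effect_k · 100·meanQ_k + age_mult)`,
where `meanQ` is the realized regional mean of the true admixture and
effects are log-rate changes per percentage point, so the ground-truth
SMR per 1 % is `exp(effect)`. No overdispersion is simulated. Default
categories: a focal cancer-like category with +3.7 % per 1 %
Mapuche-like and no structural Aymara-like effect (~10⁴ expected
national deaths over 15 regions × 7 years); an asthma-like category with
equal-and-opposite Native effects ±log 1.03 (the masking preset); a
category with a protective Mapuche-like effect; a null category; and a
tiny category expected to stay under 100 deaths, exercising the
minimum-deaths filter. Placing the focal generative effect on a single
component is deliberate: the method estimates *marginal* per-component
associations, and with anti-correlated regional gradients a
single-component cause already produces an opposite-signed marginal
association on the other subcomponent — the structure the design is
meant to reveal. Per-region person-years (0.4–2.0 million per year
across four age bands with a census-like age structure) are arbitrary
defaults, documented rather than inferred; no public source fixes them.

All generators draw from `numpy.random.default_rng` seeded once per run,
with pipeline sub-streams derived through `SeedSequence`; outputs are
bit-reproducible for a fixed seed.

## Quality control and population structure

QC removes, in order: non-autosomal variants, variants with missing call
rate strictly over 5 %, variants with folded MAF strictly under 5 %
(values exactly at a threshold survive — the thresholds are phrased as
strict inequalities and implemented that way). LD pruning is greedy
left-to-right within a sliding window (defaults window 50 variants,
step 5 — the r² ceiling of 0.1 is the substantive parameter, the window
geometry is common practice): a variant is dropped when its squared
Pearson dosage correlation with an earlier retained in-window variant
exceeds the ceiling; r² uses pairwise-complete observations, with a
single-matrix fast path when the window has no missing data. PCA
mean-centres each variant at twice the allele frequency, scales by
`sqrt(p(1−p))`, mean-imputes missing entries, and takes the SVD;
monomorphic variants are excluded with a warning. Fst is the
Weir–Cockerham (1984) two-population variance-components estimator with
a, b, c components combined as a ratio of sums over loci; the estimator
uses observed heterozygote frequencies, handles unequal sample sizes,
and can be slightly negative under no differentiation.

## Two-stage association

Stage 1 is OLS of one ancestry component at a time on categorical
covariates with declared reference levels (missing values become an
explicit "Missing" level). The region factor is always included —
regional expectations are the deliverable and are undefined without
it — while the remaining candidates pass through forward stepwise
selection by partial F-test with entry and stay levels of 0.1. Regional
expectations default to evaluation at the reference level of every other
factor (intercept plus region offset, matching how a table of an
intercept and per-stratum offsets reads); a population-average
evaluation is available by option. Expectations are clipped to [0, 1]
with a warning if OLS strays outside; standard errors come from the
coefficient covariance through the evaluation contrast.

Stage 2 multiplies the yearly directly-standardized rate (per 10⁵
person-years, standard weights renormalized with a warning if needed) by
region-year person-time to form standardized expected deaths, and fits a
Poisson GLM with offset `log(person_years/1e5)` and the expected
regional ancestry in percentage points as the exposure, so `exp(β)` is
the SMR per 1 % increase. Repeated yearly measures within a region are
dependent and the standardized response is not literally Poisson, so
inference uses cluster-robust (by region) standard errors with Wald
intervals on t critical values at G−1 degrees of freedom (G = number of
regions) — the standard small-cluster correction; a region-exchangeable
GEE variant sits behind `model="gee"`. Whether one models rates or
counts-with-offset changes nothing about the meaning of `exp(β)`; the
choice is surfaced rather than hidden. Gender enters stage 2 only when
rates are sex-stratified; the default generator does not stratify by
sex, so gender is dropped with a warning, and extra region-level
covariates can be added (a constant one is aliased with the intercept
and dropped with a warning). The report flags p-values strictly below
0.05 divided by the number of tested categories.

## Sensitivity procedures

*Leave-one-out influence* recomputes each region's mean ancestry without
each individual in turn (vectorised as `(total − x_i)/(n−1)`) and flags
|shift| > 2/n; regions of size one are skipped with a warning. The
influence is computed on regional means of estimated ancestry — the
quantity the flag rule is defined on — not on regression coefficients.

*Resampling* draws regional expectations from
`Normal(expected, (scale·SE)²)` and refits stage 2 per draw, summarising
the SMR by the median and 2.5th/97.5th percentiles. The proportionality
constant between the resampling standard deviation and the stage-1
standard error is not recoverable from any fixed convention, so
`scale` defaults to 1 and is exposed in configuration; `scale → 0`
degenerates to the plug-in estimate. Draws whose refit fails are dropped
and counted, never retried. The default draw count is 50 000; tests and
the pipeline preset use desk-scaled counts (≤ 2000), which is ample for
median and tail percentiles at the precision reported.

*Marker filtering* computes, per variant and per reference group, a
binomial confidence interval (Wilson score by default, Wald by option)
at the 80 % level for the folded minor-allele frequency, folding within
each group independently (the folding convention changes overlap
outcomes and is therefore fixed and documented). A variant is excluded
when the European CI overlaps the pooled-Native CI *and* the European CI
overlaps the Mapuche-like CI; the conjunction is implemented as written
in the source procedure, with a disjunction available behind a flag.
Variants where any group has no called genotype are skipped (not
retained) with a warning.

## Survival validation

The individual-level stage fits Cox proportional hazards by partial
likelihood with Breslow tie handling by default (ties are expected with
age-in-years survival times); Efron is available by option. Categorical
covariates are dummy-coded against the most frequent level unless a
reference is declared. Records are assumed independent — family
structure is explicitly out of scope — and matching factors included as
covariates carry the usual caveat that their hazard ratios reflect the
matching design. Complete separation is detected by diverging
coefficients or exploding standard errors and raised as an error rather
than reported as an estimate. The synthetic survival cohort draws
exponential event times with rate proportional to
`HR^(ancestry percentage)` and uniform interview (censoring) ages;
about a quarter of records are events under the defaults.

## Numerical conventions and edge cases

- Coordinates are 1-based; variant identity is (chrom, pos, ref, alt);
  strand flips are never auto-resolved — non-matching variants simply do
  not harmonize, and an empty intersection is an error.
- PLINK `.bed` is read and written in SNP-major 2-bit encoding with the
  alternate allele stored as A1; the codec is part of this package.
- Dosages are floats with NaN for missing; QC, r², PCA and the
  likelihood each state their own missing-data rule (drop, pairwise
  complete, mean-impute, drop).
- Greedy tie-breaks (LD pruning keep-first, stepwise candidate order)
  are deterministic given input order.
- All thresholds phrased as strict inequalities ("over", "under",
  "at least") are implemented with the matching strict or inclusive
  comparison and covered by boundary tests.

## What the generator does not emulate

No linkage disequilibrium beyond optionally duplicated markers, no
genotyping error, no sex chromosomes, no pedigrees, no overdispersion in
mortality, no cause-of-death miscoding, and covariate–ancestry coupling
only through the specified multinomial-logit forms. Passing tests
therefore demonstrate correctness of the estimators and procedures under
the stated model, and the qualitative phenomena (masking, pooled-panel
underestimation, filter behaviour with contaminated references) under
conditions engineered to contain them — not robustness of any real-world
epidemiological conclusion. Ecological associations estimated by this
design remain subject to regional confounding; the sensitivity tools
quantify, but cannot eliminate, that limitation.
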