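"""Synthetic study generator with known ground truth.

Emulates the structure of an admixed-population mortality study in a
country settled by four ancestral groups: a far-diverged African-like
component, an intermediate European-like component, and two closely
related Native subcomponents ("MAP" Mapuche-like and "AYM" Aymara-like)
at a pairwise Fst of about 0.038.  Downstream stages (QC, ancestry
estimation, the two-stage ecological regression, sensitivity procedures)
are exercised end-to-end against the recorded truth.

Three generators, run in order:

1. ``simulate_reference_panels`` — per-population allele frequencies under
   a hierarchical Balding–Nichols scheme (population frequencies are
   Beta-distributed around their parent node's frequency, with the drift
   parameter equal to the expected Fst accrued along that edge), plus
   binomially sampled reference genotypes.
2. ``simulate_admixed_cohort`` — individual admixture proportions drawn
   from region-specific Dirichlet distributions, genotypes binomial at the
   individual's mixed frequency, and categorical covariates whose
   log-odds are linear in the ancestry vector.
3. ``simulate_mortality`` — regional death counts Poisson-distributed
   around a log-linear rate in the regional mean ancestry (in percentage
   points), with multiplicative age-band effects.  The ground-truth
   mortality ratio per 1% ancestry is ``exp(effect)``.

All generators are bit-reproducible for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ancestry import ReferencePanel
from .genotypes import GenotypeMatrix

_FREQ_EPS = 1e-6


# ---------------------------------------------------------------------------
# ancestral divergence model
# ---------------------------------------------------------------------------

@dataclass
class AncestralModel:
    """Hierarchical Balding–Nichols divergence model.

    ``tree`` maps every node name to ``(parent, F)`` where ``parent`` is
    another node name or ``None`` for the ancestral root and ``F`` in
    (0, 1) is the drift accrued along that edge.  ``populations`` names
    the leaves that receive genotyped samples; internal nodes (e.g. a
    proto-Native node) only shape the frequency hierarchy.
    """

    populations: list[str]
    M: int
    tree: dict[str, tuple[str | None, float]]
    ancestral_maf_range: tuple[float, float] = (0.05, 0.95)
    pairwise_targets: dict[tuple[str, str], float] | None = None

    def __post_init__(self) -> None:
        if len(self.populations) < 2:
            raise ValueError("need K >= 2 populations")
        lo, hi = self.ancestral_maf_range
        if not (0.0 < lo < hi < 1.0):
            raise ValueError("ancestral_maf_range must be inside (0, 1)")
        for node, (parent, f) in self.tree.items():
            if not (0.0 <= f < 1.0):
                raise ValueError(f"drift parameter for {node!r} must be in [0, 1)")
            if parent is not None and parent not in self.tree:
                raise ValueError(f"unknown parent {parent!r} for node {node!r}")
        for pop in self.populations:
            if pop not in self.tree:
                raise ValueError(f"population {pop!r} missing from the tree")

    def accumulated_drift(self, pop: str) -> float:
        """Total drift from the root: 1 - prod(1 - F_edge) along the path."""
        keep = 1.0
        node: str | None = pop
        while node is not None:
            parent, f = self.tree[node]
            keep *= 1.0 - f
            node = parent
        return 1.0 - keep

    def expected_pairwise_fst(self, a: str, b: str) -> float:
        """First-order expected Weir–Cockerham Fst between two leaves.

        Drift below the most recent common ancestor of the pair averages
        into the between-population variance; approximately
        ``(F_a + F_b) / 2`` with ``F`` the drift accumulated since the MRCA.
        """
        path = {}
        node: str | None = a
        keep = 1.0
        while node is not None:
            path[node] = keep
            keep *= 1.0 - self.tree[node][1]
            node = self.tree[node][0]
        path[None] = keep
        node = b
        keep = 1.0
        while node not in path:
            keep *= 1.0 - self.tree[node][1]
            node = self.tree[node][0]
        fa = 1.0 - path[node]  # drift of a below the MRCA
        fb = 1.0 - keep
        return 0.5 * (fa + fb)


def _bn_draw(rng: np.random.Generator, parent_freq: np.ndarray, f: float) -> np.ndarray:
    """Balding–Nichols: Beta(p(1-F)/F, (1-p)(1-F)/F) around the parent."""
    if f < 1e-12:  # no-drift limit: child equals parent
        return parent_freq.copy()
    ratio = (1.0 - f) / f
    out = rng.beta(parent_freq * ratio, (1.0 - parent_freq) * ratio)
    return np.clip(out, _FREQ_EPS, 1.0 - _FREQ_EPS)


def _variants_frame(M: int) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": ["1"] * M,
            "pos": np.arange(1, M + 1) * 1000,
            "id": [f"snp{j}" for j in range(M)],
            "ref": ["A"] * M,
            "alt": ["G"] * M,
        }
    )


def simulate_reference_panels(
    model: AncestralModel,
    n_per_pop: int,
    seed: int,
    contamination: dict[str, tuple[str, float]] | None = None,
) -> tuple[ReferencePanel, dict[str, GenotypeMatrix]]:
    """True per-population frequencies plus sampled reference genotypes.

    The returned panel stores the *true* simulated frequencies; the
    genotype matrices hold ``Binomial(2, freq)`` draws for ``n_per_pop``
    individuals per population.

    ``contamination`` optionally makes a population's sampled individuals
    two-way admixed: ``{"MAP": ("EUR", 0.74)}`` draws each MAP-like
    reference individual's own-population proportion uniformly from
    [0.74, 1] with the remainder from EUR — mimicking reference
    individuals whose Native proportion is only guaranteed to reach 74%.
    The truth panel is unaffected; only genotypes are contaminated.
    """
    if n_per_pop < 2:
        raise ValueError("need n_per_pop >= 2")
    rng = np.random.default_rng(seed)
    lo, hi = model.ancestral_maf_range
    ancestral = rng.uniform(lo, hi, size=model.M)

    # resolve node frequencies parent-first
    freqs: dict[str, np.ndarray] = {}

    def _freq(node: str) -> np.ndarray:
        if node not in freqs:
            parent, f = model.tree[node]
            base = ancestral if parent is None else _freq(parent)
            freqs[node] = _bn_draw(rng, base, f)
        return freqs[node]

    for node in model.tree:  # deterministic draw order: tree insertion order
        _freq(node)

    variants = _variants_frame(model.M)
    panel = ReferencePanel(
        populations=list(model.populations),
        freqs=np.vstack([freqs[p] for p in model.populations]),
        n_samples={p: n_per_pop for p in model.populations},
        variants=variants,
    )

    genotypes: dict[str, GenotypeMatrix] = {}
    contamination = contamination or {}
    for pop in model.populations:
        f = freqs[pop]
        if pop in contamination:
            other, min_own = contamination[pop]
            own = rng.uniform(min_own, 1.0, size=n_per_pop)
            p_ind = own[:, None] * f[None, :] + (1.0 - own[:, None]) * freqs[other][None, :]
        else:
            p_ind = np.broadcast_to(f, (n_per_pop, model.M))
        dosage = rng.binomial(2, p_ind).astype(float)
        genotypes[pop] = GenotypeMatrix(
            samples=[f"{pop}_{i}" for i in range(n_per_pop)],
            variants=variants.copy(),
            dosage=dosage,
        )
    return panel, genotypes


# ---------------------------------------------------------------------------
# admixed cohort
# ---------------------------------------------------------------------------

@dataclass
class CovariateModel:
    """Categorical covariate whose log-odds are linear in the ancestry vector.

    ``P(cat = c | q) = softmax_c(base_logits[c] + loadings[c] . q)``.
    """

    categories: list[str]
    base_logits: np.ndarray
    loadings: np.ndarray  # (n_categories, K)

    def sample(self, rng: np.random.Generator, Q: np.ndarray) -> np.ndarray:
        logits = self.base_logits[None, :] + Q @ np.asarray(self.loadings).T
        logits -= logits.max(axis=1, keepdims=True)
        probs = np.exp(logits)
        probs /= probs.sum(axis=1, keepdims=True)
        u = rng.random(Q.shape[0])
        idx = (probs.cumsum(axis=1) < u[:, None]).sum(axis=1)
        return np.asarray(self.categories)[idx]


@dataclass
class RegionConfig:
    name: str
    concentration: np.ndarray  # Dirichlet concentration over the K components
    n: int

    def __post_init__(self) -> None:
        self.concentration = np.asarray(self.concentration, dtype=float)
        if np.any(self.concentration <= 0):
            raise ValueError(f"region {self.name!r}: Dirichlet concentrations must be > 0")


@dataclass
class CohortConfig:
    regions: list[RegionConfig]
    covariate_model: dict[str, CovariateModel]
    seed: int

    def __post_init__(self) -> None:
        names = [r.name for r in self.regions]
        if len(set(names)) != len(names):
            raise ValueError("region labels must be unique")

    @property
    def n_individuals(self) -> int:
        return sum(r.n for r in self.regions)


def simulate_admixed_cohort(
    panel: ReferencePanel, cfg: CohortConfig
) -> tuple[GenotypeMatrix, pd.DataFrame, pd.DataFrame]:
    """Admixed genotypes, covariate table and the true Q matrix.

    Per individual in region r: ``q ~ Dirichlet(concentration_r)``;
    dosage at marker m ``~ Binomial(2, sum_k q_k f_km)``; covariates from
    the configured categorical models.  Returns ``(genotypes, covariates,
    true_Q)`` with ``true_Q`` indexed like the covariate table and one
    column per panel population.
    """
    K = panel.K
    for r in cfg.regions:
        if r.concentration.shape != (K,):
            raise ValueError(
                f"region {r.name!r}: concentration length {r.concentration.shape[0]} != K={K}"
            )
    rng = np.random.default_rng(cfg.seed)
    rows_q, regions_col, ids = [], [], []
    for r in cfg.regions:
        rows_q.append(rng.dirichlet(r.concentration, size=r.n))
        regions_col += [r.name] * r.n
        ids += [f"{r.name}_ind{i}" for i in range(r.n)]
    Q = np.vstack(rows_q)

    p_ind = np.clip(Q @ panel.freqs, _FREQ_EPS, 1.0 - _FREQ_EPS)
    dosage = rng.binomial(2, p_ind).astype(float)
    genotypes = GenotypeMatrix(samples=ids, variants=panel.variants.copy(), dosage=dosage)

    cov = pd.DataFrame({"sample_id": ids, "region": regions_col})
    for name, cm in cfg.covariate_model.items():
        cov[name] = cm.sample(rng, Q)
    true_q = pd.DataFrame(Q, columns=panel.populations)
    true_q.insert(0, "sample_id", ids)
    return genotypes, cov, true_q


# ---------------------------------------------------------------------------
# regional mortality
# ---------------------------------------------------------------------------

@dataclass
class MortalityModel:
    """Poisson mortality whose log-rate is linear in regional mean ancestry.

    ``effects[icd]`` is a length-K vector of log-rate change per 1
    percentage point of each ancestry component; the ground-truth
    mortality ratio per 1% is ``exp(effect)``.  ``baseline_per1e5`` is the
    rate (per 10^5 person-years) at 0% of every component and age-band
    multiplier 1.  ``person_years`` is a region x age-band table of
    person-years per calendar year.
    """

    icd_categories: list[str]
    baseline_per1e5: dict[str, float]
    effects: dict[str, np.ndarray]
    years: list[int]
    age_bands: list[str]
    age_log_multipliers: dict[str, float]
    person_years: pd.DataFrame  # index: region, columns: age bands
    standard_weights: pd.Series | None = None  # standard-population age weights

    def __post_init__(self) -> None:
        for icd in self.icd_categories:
            if self.baseline_per1e5[icd] <= 0:
                raise ValueError(f"{icd}: baseline rate must be > 0")
        if (self.person_years.to_numpy() <= 0).any():
            raise ValueError("person-years must be > 0")

    def truth_smr(self) -> dict[str, dict[int, float]]:
        """Ground-truth per-1% mortality ratio, per category per component."""
        return {
            icd: {k: float(np.exp(e)) for k, e in enumerate(np.asarray(eff))}
            for icd, eff in self.effects.items()
        }


def simulate_mortality(
    model: MortalityModel, regional_ancestry: pd.DataFrame, seed: int
) -> pd.DataFrame:
    """Long-format mortality table with Poisson death counts.

    ``regional_ancestry`` is indexed by region with one column per
    ancestry component; rows must lie on the simplex.  Expected deaths in
    cell (region, year, icd, band) are

        person_years * baseline/1e5 * exp(sum_k effect_k * 100 * meanQ_k)
                     * exp(age_log_multiplier_band)

    Returns columns ``region, year, icd10, age_band, deaths, person_years``.
    """
    q = regional_ancestry.to_numpy(dtype=float)
    if np.any(np.abs(q.sum(axis=1) - 1.0) > 1e-6):
        raise ValueError("regional ancestry rows must sum to 1")
    missing = set(regional_ancestry.index) - set(model.person_years.index)
    if missing:
        raise ValueError(f"person-years missing for regions: {sorted(missing)}")
    rng = np.random.default_rng(seed)
    rows = []
    for icd in model.icd_categories:
        eff = np.asarray(model.effects[icd], dtype=float)
        lin = 100.0 * q @ eff  # per-region log-rate contribution
        base = model.baseline_per1e5[icd] / 1e5
        for ri, region in enumerate(regional_ancestry.index):
            for band in model.age_bands:
                py = float(model.person_years.loc[region, band])
                mu = py * base * np.exp(lin[ri] + model.age_log_multipliers[band])
                deaths = rng.poisson(mu, size=len(model.years))
                for year, d in zip(model.years, deaths):
                    rows.append((region, year, icd, band, int(d), py))
    return pd.DataFrame(
        rows, columns=["region", "year", "icd10", "age_band", "deaths", "person_years"]
    )


# ---------------------------------------------------------------------------
# default presets (the study conditions)
# ---------------------------------------------------------------------------

POPULATIONS = ["AFR", "EUR", "MAP", "AYM"]
AGE_BANDS = ["0-39", "40-59", "60-79", "80+"]
AGE_LOG_MULT = {"0-39": -2.5, "40-59": -0.5, "60-79": 1.0, "80+": 1.8}
AGE_SHARES = np.array([0.55, 0.25, 0.15, 0.05])  # census-like age structure
YEARS = list(range(2005, 2012))
N_REGIONS = 15


def default_ancestral_model(M: int = 2000) -> AncestralModel:
    """Four-population hierarchy: AFR far, EUR intermediate, MAP/AYM at
    pairwise Fst 0.038 below a shared proto-Native node.

    The drift below the proto-Native node is split unevenly (0.016 on the
    Mapuche-like edge, 0.060 on the Aymara-like edge; the pairwise
    expectation is their mean, 0.038): the Aymara-like component models a
    smaller, more isolated population carrying more private drift.  The
    asymmetry is what makes a merged Native reference a poor surrogate
    for Mapuche-dominant genomes — the merged frequencies carry Aymara
    drift those genomes do not share."""
    return AncestralModel(
        populations=POPULATIONS,
        M=M,
        tree={
            "AFR": (None, 0.20),
            "EUR": (None, 0.08),
            "NAT": (None, 0.12),
            "MAP": ("NAT", 0.016),
            "AYM": ("NAT", 0.060),
        },
        pairwise_targets={("MAP", "AYM"): 0.038},
    )


def default_covariate_models() -> dict[str, CovariateModel]:
    """Covariates qualitatively coupled to ancestry: higher Native
    components go with lower socioeconomic status and education; a mild
    male excess in the Mapuche-like component.  Order of loading columns
    matches ``POPULATIONS``."""
    z = 0.0
    return {
        "gender": CovariateModel(
            ["male", "female"],
            base_logits=np.array([0.4, 0.0]),  # soldier-heavy cohort: more men
            loadings=np.array([[z, z, 0.5, -0.5], [z, z, z, z]]),
        ),
        "age_class": CovariateModel(
            ["<25", "25-39", "40+"],
            base_logits=np.array([0.3, 0.5, 0.0]),
            loadings=np.zeros((3, 4)),
        ),
        "education": CovariateModel(
            ["basic", "secondary", "higher"],
            base_logits=np.array([0.0, 0.8, 0.2]),
            loadings=np.array([[z, z, 0.8, 0.3], [z, z, z, z], [z, z, -0.8, -0.3]]),
        ),
        "ses": CovariateModel(
            ["ABC1", "C2", "C3", "D/E"],
            base_logits=np.array([-1.5, 0.3, 0.6, 0.3]),
            loadings=np.array(
                [[z, z, -1.2, -0.6], [z, z, z, z], [z, z, z, z], [z, z, 0.8, 0.4]]
            ),
        ),
        "salary": CovariateModel(
            ["low", "mid", "high"],
            base_logits=np.array([0.2, 0.8, -0.4]),
            loadings=np.array([[z, z, 0.6, 0.3], [z, z, z, z], [z, z, -0.6, -0.3]]),
        ),
    }


def _region_names() -> list[str]:
    return [f"R{i:02d}" for i in range(1, N_REGIONS + 1)]


def default_cohort_config(
    n_individuals: int = 1800, seed: int = 0, alpha0: float = 30.0
) -> CohortConfig:
    """North-to-south gradient: the Aymara-like component peaks in the
    first (northern) regions and the Mapuche-like component in the last
    (southern) ones, spanning roughly 30-54% Mapuche-like and 6-28%
    Aymara-like regional means, with small AFR and the balance EUR."""
    names = _region_names()
    t = np.linspace(0.0, 1.0, N_REGIONS)
    m = 0.30 + 0.24 * t
    a = 0.28 - 0.22 * t
    afr = np.full(N_REGIONS, 0.03)
    eur = 1.0 - m - a - afr
    n_per = np.full(N_REGIONS, n_individuals // N_REGIONS)
    n_per[: n_individuals % N_REGIONS] += 1
    regions = [
        RegionConfig(nm, alpha0 * np.array([afr[i], eur[i], m[i], a[i]]), int(n_per[i]))
        for i, nm in enumerate(names)
    ]
    return CohortConfig(regions=regions, covariate_model=default_covariate_models(), seed=seed)


def masking_cohort_config(
    n_individuals: int = 1800, seed: int = 0, alpha0: float = 30.0
) -> CohortConfig:
    """Positively correlated Native subcomponent gradients.

    Both Native means rise with a shared regional trend while an
    alternating orthogonal contrast moves them apart; the two components
    then have similar variances and positive correlation, the setting in
    which opposite-signed effects cancel in their pooled sum."""
    names = _region_names()
    t = np.linspace(-1.0, 1.0, N_REGIONS)
    u = np.array([1.0 if i % 2 == 0 else -1.0 for i in range(N_REGIONS)])
    m = 0.35 + 0.08 * t + 0.04 * u
    a = 0.15 + 0.08 * t - 0.04 * u
    afr = np.full(N_REGIONS, 0.03)
    eur = 1.0 - m - a - afr
    n_per = np.full(N_REGIONS, n_individuals // N_REGIONS)
    n_per[: n_individuals % N_REGIONS] += 1
    regions = [
        RegionConfig(nm, alpha0 * np.array([afr[i], eur[i], m[i], a[i]]), int(n_per[i]))
        for i, nm in enumerate(names)
    ]
    return CohortConfig(regions=regions, covariate_model=default_covariate_models(), seed=seed)


def default_person_years() -> pd.DataFrame:
    """Region x age-band person-years per calendar year (regions differ in
    size, roughly 0.4 to 2.0 million person-years)."""
    totals = np.linspace(0.4e6, 2.0e6, N_REGIONS)
    return pd.DataFrame(
        np.outer(totals, AGE_SHARES), index=_region_names(), columns=AGE_BANDS
    )


def default_standard_weights() -> pd.Series:
    """Standard-population age weights (sum to 1)."""
    return pd.Series(AGE_SHARES, index=AGE_BANDS)


# component order AFR, EUR, MAP, AYM; effects are log-rate per 1 point
def default_mortality_model(
    focal_effect: float = float(np.log(1.037)),
    focal_aym_effect: float = 0.0,
) -> MortalityModel:
    """Default disease presets.

    * ``C23`` — focal category (~10^4 expected deaths): +3.7% per 1%
      Mapuche-like and no structural Aymara-like effect.  The marginal
      per-component fits are what the method estimates, so the focal
      generative effect is placed on a single component; the fitted
      Aymara-like association then comes out protective purely through
      the anti-correlated north-south gradients, as in the real data.
    * ``J45`` — opposite subcomponent effects of equal size (masking).
    * ``E11`` — protective Mapuche-like effect.
    * ``NULL`` — no ancestry effect.
    * ``C99`` — tiny category (expected < 100 national deaths) exercising
      the minimum-deaths filter.
    """
    zeros = np.zeros(4)
    eff = {
        "C23": np.array([0.0, 0.0, focal_effect, focal_aym_effect]),
        "J45": np.array([0.0, 0.0, np.log(1.03), -np.log(1.03)]),
        "E11": np.array([0.0, 0.0, np.log(0.98), 0.0]),
        "NULL": zeros,
        "C99": zeros,
    }
    base = {"C23": 1.9, "J45": 5.0, "E11": 20.0, "NULL": 8.0, "C99": 0.05}
    return MortalityModel(
        icd_categories=list(eff),
        baseline_per1e5=base,
        effects=eff,
        years=list(YEARS),
        age_bands=list(AGE_BANDS),
        age_log_multipliers=dict(AGE_LOG_MULT),
        person_years=default_person_years(),
        standard_weights=default_standard_weights(),
    )
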