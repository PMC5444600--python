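"""Two-stage ecological ancestry-mortality association.

Stage 1 regresses individual ancestry proportions on individual-level
categorical covariates (age class, gender, education, socioeconomic
status, salary, region) by ordinary least squares, ``E[X|Z] = Z'd``, and
evaluates the fitted expectation per region.  Stage 2 relates yearly
age-standardized disease-specific mortality rates to the expected
regional ancestry (in percentage points) through a log-linear Poisson
model with a person-time offset,

    log(mu) = beta * E[X|Z] + Z~ * alpha,

so that ``exp(beta)`` is the standardized mortality ratio per 1%
increase in the ancestry component.  Repeated yearly measures within a
region are handled by cluster-robust (by region) standard errors, with a
region-exchangeable GEE variant behind a flag; Wald intervals use t
critical values with (number of regions - 1) degrees of freedom.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats


# ---------------------------------------------------------------------------
# direct age standardization
# ---------------------------------------------------------------------------

def direct_standardize(age_table: pd.DataFrame, weights: pd.Series) -> float:
    """Directly age-standardized rate per 10^5 person-years.

    ``age_table`` needs columns ``age_band, deaths, person_years`` (one
    row per band); ``weights`` is the standard population's age
    distribution indexed by band.  Weights not summing to one are
    renormalized with a warning.
    """
    w = weights.astype(float)
    if abs(w.sum() - 1.0) > 1e-9:
        warnings.warn("standard weights do not sum to 1; renormalizing")
        w = w / w.sum()
    t = age_table.set_index("age_band")
    missing = set(w.index) - set(t.index)
    if missing:
        raise ValueError(f"age bands missing from the table: {sorted(missing)}")
    t = t.loc[w.index]
    py = t["person_years"].to_numpy(dtype=float)
    d = t["deaths"].to_numpy(dtype=float)
    if np.any((py <= 0) & (d > 0)):
        raise ValueError("zero person-years in a band with nonzero deaths")
    rates = np.divide(d, py, out=np.zeros_like(d), where=py > 0)
    return float(np.sum(w.to_numpy() * rates) * 1e5)


def standardized_rates(
    mortality: pd.DataFrame, weights: pd.Series, icd: str
) -> pd.DataFrame:
    """Yearly standardized rates per region for one ICD category.

    Returns columns ``region, year, rate, person_years`` where ``rate``
    is per 10^5 person-years and ``person_years`` the region-year total.
    """
    sub = mortality[mortality["icd10"] == icd]
    if sub.empty:
        raise ValueError(f"no rows for category {icd!r}")
    rows = []
    for (region, year), grp in sub.groupby(["region", "year"], sort=True):
        rows.append(
            (region, year, direct_standardize(grp, weights), float(grp["person_years"].sum()))
        )
    return pd.DataFrame(rows, columns=["region", "year", "rate", "person_years"])


def filter_categories(
    mortality: pd.DataFrame, min_deaths: int = 100
) -> tuple[list[str], pd.Series]:
    """ICD categories with a national death total of at least ``min_deaths``.

    Returns the retained category list (sorted) and the full per-category
    totals for reporting; the boundary is inclusive.
    """
    totals = mortality.groupby("icd10")["deaths"].sum().sort_index()
    retained = sorted(totals.index[totals >= min_deaths])
    return retained, totals


# ---------------------------------------------------------------------------
# stage 1: individual-level linear model for expected regional ancestry
# ---------------------------------------------------------------------------

@dataclass
class Stage1Model:
    """OLS fit of one ancestry component on individual covariates."""

    ancestry_column: str
    factors: list[str]
    result: object = field(repr=False)
    regional: pd.DataFrame  # index region; columns: expected, se (proportion scale)
    evaluation: str

    def expectations_pct(self) -> pd.Series:
        """Expected regional ancestry in percentage points."""
        return self.regional["expected"] * 100.0

    def se_pct(self) -> pd.Series:
        return self.regional["se"] * 100.0


def _formula(response: str, factors: list[str], references: dict[str, str]) -> str:
    terms = []
    for f in factors:
        ref = references.get(f)
        if ref is None:
            terms.append(f"C({f})")
        else:
            terms.append(f"C({f}, Treatment(reference={ref!r}))")
    rhs = " + ".join(terms) if terms else "1"
    return f"{response} ~ {rhs}"


def fit_stage1(
    covariates: pd.DataFrame,
    ancestry: pd.Series,
    factors: list[str],
    region_col: str = "region",
    references: dict[str, str] | None = None,
    evaluation: str = "reference",
) -> Stage1Model:
    """Individual-level OLS and per-region expected ancestry with SEs.

    ``factors`` are categorical covariate columns to include besides the
    region factor (always included).  ``references`` optionally pins the
    reference level per factor (default: the most frequent level; for the
    region factor, the first region in sorted order).  Missing covariate
    values become an explicit "Missing" category.

    ``evaluation="reference"`` evaluates the regional expectation at the
    reference level of every other factor (intercept plus region offset);
    ``"mean"`` averages predictions over the observed covariate
    distribution with the region forced to each level in turn.
    """
    if evaluation not in ("reference", "mean"):
        raise ValueError("evaluation must be 'reference' or 'mean'")
    data = covariates.copy()
    data["_x"] = np.asarray(ancestry, dtype=float)
    all_factors = [region_col] + [f for f in factors if f != region_col]
    refs = dict(references or {})
    for f in all_factors:
        data[f] = data[f].astype(object).where(pd.notna(data[f]), "Missing").astype(str)
        if f not in refs:
            refs[f] = (
                sorted(data[f].unique())[0] if f == region_col else data[f].mode().iloc[0]
            )
    res = smf.ols(_formula("_x", all_factors, refs), data=data).fit()
    if np.linalg.matrix_rank(res.model.exog) < res.model.exog.shape[1]:
        warnings.warn("rank-deficient stage-1 design; aliased columns dropped by pinv")

    regions = sorted(data[region_col].unique())
    design_info = res.model.data.design_info
    from patsy import dmatrix

    rows = []
    for r in regions:
        if evaluation == "reference":
            new = pd.DataFrame(
                {f: [refs[f]] for f in all_factors} | {region_col: [r]}
            )
            X = np.asarray(dmatrix(design_info, new))
            c = X[0]
        else:
            forced = data[all_factors].copy()
            forced[region_col] = r
            X = np.asarray(dmatrix(design_info, forced))
            c = X.mean(axis=0)
        expected = float(c @ res.params)
        se = float(np.sqrt(c @ res.cov_params() @ c))
        rows.append((r, expected, se))
    regional = pd.DataFrame(rows, columns=["region", "expected", "se"]).set_index("region")
    out_of_range = (regional["expected"] < 0) | (regional["expected"] > 1)
    if out_of_range.any():
        warnings.warn(
            f"{int(out_of_range.sum())} regional expectation(s) outside [0, 1]; clipped"
        )
        regional["expected"] = regional["expected"].clip(0.0, 1.0)
    return Stage1Model(
        ancestry_column=ancestry.name or "_x",
        factors=all_factors,
        result=res,
        regional=regional,
        evaluation=evaluation,
    )


def stepwise_forward(
    data: pd.DataFrame,
    response: str,
    candidates: list[str],
    alpha_enter: float = 0.1,
    alpha_stay: float = 0.1,
    forced: tuple[str, ...] = (),
    references: dict[str, str] | None = None,
) -> list[str]:
    """Forward stepwise selection of categorical factors by partial F-test.

    Repeatedly adds the candidate with the smallest partial-F p-value
    below ``alpha_enter``; after each addition removes any non-forced
    selected factor whose p-value rose above ``alpha_stay``.  Terminates
    when no addition or removal changes the model.  Deterministic given
    the data (ties broken by candidate order).
    """
    refs = dict(references or {})
    work = data.copy()
    for f in list(candidates) + list(forced):
        work[f] = work[f].astype(object).where(pd.notna(work[f]), "Missing").astype(str)

    def _ssr(factors: list[str]):
        res = smf.ols(_formula(response, factors, refs), data=work).fit()
        return res.ssr, res.df_resid

    def _partial_p(base: list[str], factor: str) -> float:
        ssr_r, _ = _ssr(base)
        ssr_f, df_f = _ssr(base + [factor])
        df_diff = (_ssr(base)[1]) - df_f
        if df_diff <= 0 or df_f <= 0 or ssr_f <= 0:
            return 1.0
        F = (ssr_r - ssr_f) / df_diff / (ssr_f / df_f)
        return float(stats.f.sf(max(F, 0.0), df_diff, df_f))

    selected: list[str] = []
    remaining = [c for c in candidates if c not in forced]
    while True:
        changed = False
        # forward step
        best, best_p = None, 1.0
        for c in remaining:
            p = _partial_p(list(forced) + selected, c)
            if p < best_p:
                best, best_p = c, p
        if best is not None and best_p < alpha_enter:
            selected.append(best)
            remaining.remove(best)
            changed = True
        # backward sweep
        for c in list(selected):
            others = list(forced) + [s for s in selected if s != c]
            p = _partial_p(others, c)
            if p > alpha_stay:
                selected.remove(c)
                remaining.append(c)
                changed = True
        if not changed:
            break
    return list(forced) + selected


# ---------------------------------------------------------------------------
# stage 2: Poisson model for the SMR per 1% ancestry
# ---------------------------------------------------------------------------

@dataclass
class Stage2Model:
    """Log-linear fit of standardized rates on expected regional ancestry."""

    smr: float
    ci_low: float
    ci_high: float
    p_value: float
    beta: float
    se: float
    n_obs: int
    n_clusters: int
    converged: bool
    model: str
    result: object = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.smr <= 0:
            raise ValueError("SMR must be positive")
        if not (self.ci_low <= self.smr <= self.ci_high):
            raise ValueError("CI must contain the point estimate")


def fit_stage2(
    std_rates: pd.DataFrame,
    expectations_pct: pd.Series,
    region_covariates: pd.DataFrame | None = None,
    model: str = "poisson",
) -> Stage2Model:
    """Poisson regression of standardized deaths on expected ancestry.

    ``std_rates`` holds one row per region-year (columns ``region, year,
    rate, person_years``; rate per 10^5 person-years).  The response is
    the standardized expected death count ``rate * person_years / 1e5``
    with offset ``log(person_years / 1e5)``; ``expectations_pct`` gives
    the expected ancestry per region in percentage points, so
    ``exp(beta)`` is the mortality ratio per 1% increase.  Optional
    ``region_covariates`` (indexed by region) enter as additional
    region-level fixed effects.

    ``model="poisson"`` uses a GLM with cluster-robust (by region)
    standard errors and t(G-1) Wald intervals; ``model="gee"`` fits a
    region-exchangeable GEE instead.
    """
    if std_rates["region"].nunique() < 2:
        raise ValueError("need at least two regions")
    if model not in ("poisson", "gee"):
        raise ValueError("model must be 'poisson' or 'gee'")
    df = std_rates.copy()
    missing = set(df["region"]) - set(expectations_pct.index)
    if missing:
        raise ValueError(f"expected ancestry missing for regions: {sorted(missing)}")
    df["x"] = df["region"].map(expectations_pct).astype(float)
    exog_cols = ["x"]
    if region_covariates is not None:
        for col in region_covariates.columns:
            vals = df["region"].map(region_covariates[col]).astype(float)
            if vals.std() < 1e-12:
                warnings.warn(f"region covariate {col!r} is constant: aliased, dropped")
                continue
            df[col] = vals
            exog_cols.append(col)
    endog = df["rate"].to_numpy() * df["person_years"].to_numpy() / 1e5
    exog = sm.add_constant(df[exog_cols].to_numpy())
    offset = np.log(df["person_years"].to_numpy() / 1e5)
    groups = df["region"].to_numpy()
    n_clusters = df["region"].nunique()

    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*non-integer.*")
        if model == "poisson":
            glm = sm.GLM(endog, exog, family=sm.families.Poisson(), offset=offset)
            res = glm.fit(cov_type="cluster", cov_kwds={"groups": groups})
        else:
            res = sm.GEE(
                endog,
                exog,
                groups=groups,
                family=sm.families.Poisson(),
                cov_struct=sm.cov_struct.Exchangeable(),
                offset=offset,
            ).fit()
    converged = bool(getattr(res, "converged", True))
    if not converged:
        warnings.warn("stage-2 fit did not converge; estimates are the last iterate")
    beta = float(res.params[1])
    se = float(res.bse[1])
    tcrit = stats.t.ppf(0.975, df=max(n_clusters - 1, 1))
    tstat = beta / se if se > 0 else np.inf
    p = float(2.0 * stats.t.sf(abs(tstat), df=max(n_clusters - 1, 1)))
    return Stage2Model(
        smr=float(np.exp(beta)),
        ci_low=float(np.exp(beta - tcrit * se)),
        ci_high=float(np.exp(beta + tcrit * se)),
        p_value=p,
        beta=beta,
        se=se,
        n_obs=len(df),
        n_clusters=n_clusters,
        converged=converged,
        model=model,
        result=res,
    )


# ---------------------------------------------------------------------------
# reporting
# ---------------------------------------------------------------------------

def highlight_threshold(n_categories: int, alpha: float = 0.05) -> float:
    """Bonferroni-style highlight threshold alpha / n_categories."""
    if n_categories < 1:
        raise ValueError("need at least one tested category")
    return alpha / n_categories


def smr_report(
    fits: list[dict], n_categories: int | None = None, alpha: float = 0.05
) -> pd.DataFrame:
    """Association table with the multiplicity highlight flag.

    ``fits`` is a list of dicts with keys ``icd, component, deaths, smr,
    ci_low, ci_high, p_value``.  The highlight threshold is
    ``alpha / n_categories`` where ``n_categories`` defaults to the
    number of distinct ICD categories present; a p-value exactly at the
    threshold is NOT highlighted (strictly below).  Sorted by ICD code
    then component.
    """
    table = pd.DataFrame(fits)
    if table.empty:
        return table.assign(highlight=pd.Series(dtype=bool))
    if n_categories is None:
        n_categories = table["icd"].nunique()
    thr = highlight_threshold(n_categories, alpha)
    table = table.sort_values(["icd", "component"]).reset_index(drop=True)
    table["highlight"] = table["p_value"] < thr
    table.attrs["threshold"] = thr
    table.attrs["n_categories"] = n_categories
    return table


def percent_excess(smr: float) -> float:
    """Percent excess mortality per 1% ancestry: 100 * (SMR - 1)."""
    return 100.0 * (smr - 1.0)


def projected_excess(smr: float, points: float) -> float:
    """Linear projection of the per-1% excess over an ancestry difference.

    A difference of ``points`` percentage points projects to
    ``points * 100 * (SMR - 1)`` percent excess mortality (e.g. a 24-point
    difference at SMR 1.037 projects to 24 x 3.7 = 88.8%).
    """
    return points * percent_excess(smr)
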