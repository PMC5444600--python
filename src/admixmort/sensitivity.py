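"""Sensitivity procedures for the ecological association.

Three checks of the aggregate-data result:

* leave-one-out influence of single individuals on regional ancestry
  means, flagged against a 2/n cutoff (n = region size);
* propagation of stage-1 uncertainty into the SMR by resampling the
  regional expectations from normal distributions and refitting stage 2;
* refitting stage 2 with an additional region-level covariate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .association import Stage2Model, fit_stage2


def loo_influence(ancestry: pd.Series, regions: pd.Series) -> pd.DataFrame:
    """Leave-one-out influence of each individual on their regional mean.

    For individual i in a region of size n with regional mean ``beta``,
    the mean without i is ``beta_loo``; the record is flagged when
    ``|beta_loo - beta| > 2/n``.  Regions of size 1 are skipped with a
    warning (no leave-one-out mean exists).  Only same-region individuals
    affect a region's estimate.
    """
    x = np.asarray(ancestry, dtype=float)
    r = pd.Series(np.asarray(regions, dtype=object))
    frames = []
    for region, idx in r.groupby(r).groups.items():
        n = len(idx)
        if n < 2:
            warnings.warn(f"region {region!r} has a single individual; skipped")
            continue
        vals = x[np.asarray(idx)]
        total = vals.sum()
        beta = total / n
        beta_loo = (total - vals) / (n - 1)
        cutoff = 2.0 / n
        frames.append(
            pd.DataFrame(
                {
                    "individual": np.asarray(ancestry.index)[np.asarray(idx)],
                    "region": region,
                    "beta": beta,
                    "beta_loo": beta_loo,
                    "n": n,
                    "influence": beta_loo - beta,
                    "flagged": np.abs(beta_loo - beta) > cutoff,
                }
            )
        )
    if not frames:
        raise ValueError("no region with at least two individuals")
    return pd.concat(frames, ignore_index=True)


@dataclass
class ResampleSummary:
    """Distribution of the SMR over resampled regional expectations."""

    draws: np.ndarray = field(repr=False)
    median: float
    q025: float
    q975: float
    n_requested: int
    n_failed: int

    def __post_init__(self) -> None:
        if not (self.q025 <= self.median <= self.q975):
            raise ValueError("percentiles must be ordered")
        if len(self.draws) + self.n_failed != self.n_requested:
            raise ValueError("draw count does not reconcile with failures")


def resample_smr(
    expectations_pct: pd.Series,
    se_pct: pd.Series,
    std_rates: pd.DataFrame,
    S: int = 50_000,
    seed: int = 0,
    scale: float = 1.0,
    region_covariates: pd.DataFrame | None = None,
    model: str = "poisson",
) -> ResampleSummary:
    """Propagate stage-1 uncertainty into the SMR by normal resampling.

    Each draw samples the regional expectations from
    ``Normal(expected, (scale * SE)^2)`` (percentage-point scale), refits
    stage 2 and records the SMR; the summary is the median with the 2.5th
    and 97.5th percentiles.  Draws whose refit fails are dropped and
    counted.  ``scale -> 0`` degenerates to the plug-in estimate.
    """
    se_pct = se_pct.reindex(expectations_pct.index)
    if se_pct.isna().any():
        raise ValueError("standard errors missing for some regions")
    rng = np.random.default_rng(seed)
    mu = expectations_pct.to_numpy(dtype=float)
    sd = scale * se_pct.to_numpy(dtype=float)
    draws = []
    n_failed = 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for _ in range(S):
            sampled = pd.Series(rng.normal(mu, sd), index=expectations_pct.index)
            try:
                fit = fit_stage2(
                    std_rates, sampled, region_covariates=region_covariates, model=model
                )
                if not fit.converged or not np.isfinite(fit.smr):
                    raise ValueError("non-converged draw")
                draws.append(fit.smr)
            except Exception:
                n_failed += 1
    if n_failed:
        warnings.warn(f"{n_failed} of {S} resampling refits failed and were dropped")
    if not draws:
        raise ValueError("all resampling refits failed")
    arr = np.asarray(draws)
    return ResampleSummary(
        draws=arr,
        median=float(np.median(arr)),
        q025=float(np.percentile(arr, 2.5)),
        q975=float(np.percentile(arr, 97.5)),
        n_requested=S,
        n_failed=n_failed,
    )


def adjust_regional_covariate(
    std_rates: pd.DataFrame,
    expectations_pct: pd.Series,
    extra: pd.Series,
    region_covariates: pd.DataFrame | None = None,
    model: str = "poisson",
) -> tuple[Stage2Model, Stage2Model]:
    """Stage 2 with and without an additional region-level covariate.

    ``extra`` must be defined for every region in ``std_rates``; a
    covariate constant across regions is aliased with the intercept and
    dropped with a warning, making the adjusted fit equal the unadjusted
    one.  Returns ``(unadjusted, adjusted)``.
    """
    missing = set(std_rates["region"]) - set(extra.index)
    if missing:
        raise ValueError(f"extra covariate undefined for regions: {sorted(missing)}")
    unadjusted = fit_stage2(
        std_rates, expectations_pct, region_covariates=region_covariates, model=model
    )
    extra_frame = pd.DataFrame({extra.name or "extra": extra})
    combined = (
        extra_frame
        if region_covariates is None
        else region_covariates.join(extra_frame, how="outer")
    )
    adjusted = fit_stage2(
        std_rates, expectations_pct, region_covariates=combined, model=model
    )
    return unadjusted, adjusted
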