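"""Supervised ancestry-proportion estimation.

Given fixed per-population alternate-allele frequencies (a reference
panel), the admixture proportion vector ``q`` of an individual is the
maximiser over the K-simplex of the independent-locus binomial
log-likelihood

    l(q) = sum_m [ g_m * ln(sum_k q_k f_km) + (2 - g_m) * ln(sum_k q_k (1 - f_km)) ]

where ``g_m`` is the alt-allele dosage and ``f_km`` the reference
frequency of population ``k`` at marker ``m``.  Missing dosages drop out
of the sum.  The maximiser is found by expectation-maximisation on the
complete-data formulation (allele-origin indicators as latent variables),
which is monotone in the log-likelihood and respects the simplex without
any projection step.

The module also houses the ancestry-informative-marker filter: variants
whose minor-allele-frequency confidence intervals overlap between a
European-like group and each of two Native-like groups are discarded, so
that only markers separating the continental components survive.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from .genotypes import GenotypeMatrix

_FREQ_EPS = 1e-12  # guards the logs; panel frequencies should already be interior
_BOUNDARY_SNAP = 1e-8  # components below this are reported as exact zeros


@dataclass
class ReferencePanel:
    """Per-population alternate-allele frequencies over a shared variant set."""

    populations: list[str]
    freqs: np.ndarray = field(repr=False)  # (K, M), strictly inside (0, 1)
    n_samples: dict[str, int]
    variants: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        if self.freqs.shape[0] != len(self.populations):
            raise ValueError("freqs rows must match the population list")
        if np.any(self.freqs <= 0.0) or np.any(self.freqs >= 1.0):
            raise ValueError("panel frequencies must lie strictly inside (0, 1)")

    @property
    def K(self) -> int:
        return len(self.populations)

    @property
    def M(self) -> int:
        return self.freqs.shape[1]

    def take_variants(self, index: np.ndarray) -> "ReferencePanel":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return ReferencePanel(
            populations=list(self.populations),
            freqs=self.freqs[:, index],
            n_samples=dict(self.n_samples),
            variants=None
            if self.variants is None
            else self.variants.iloc[index].reset_index(drop=True),
        )

    def pool(self, members: list[str], name: str) -> "ReferencePanel":
        """Merge populations into one, weighting frequencies by sample count."""
        idx = [self.populations.index(p) for p in members]
        w = np.array([self.n_samples[p] for p in members], dtype=float)
        pooled = (w[:, None] * self.freqs[idx]).sum(axis=0) / w.sum()
        keep = [i for i, p in enumerate(self.populations) if p not in members]
        return ReferencePanel(
            populations=[self.populations[i] for i in keep] + [name],
            freqs=np.vstack([self.freqs[keep], pooled[None, :]]),
            n_samples={
                **{self.populations[i]: self.n_samples[self.populations[i]] for i in keep},
                name: int(w.sum()),
            },
            variants=self.variants,
        )


@dataclass
class AncestryEstimate:
    """Result of a supervised fit for one individual."""

    q: np.ndarray
    loglik: float
    converged: bool
    iterations: int

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        if np.any(self.q < 0) or abs(self.q.sum() - 1.0) > 1e-8:
            raise ValueError("q must lie on the simplex")
        if not np.isfinite(self.loglik):
            raise ValueError("log-likelihood must be finite")


def estimate_reference_freqs(
    genotypes: GenotypeMatrix, labels: pd.Series | dict, pseudocount: float = 0.5
) -> ReferencePanel:
    """Per-population alt-allele frequencies with a symmetric pseudocount.

    ``freq = (alt_count + pseudocount) / (2 * n_called + 2 * pseudocount)``,
    which keeps frequencies strictly inside (0, 1) for any positive
    pseudocount.  ``labels`` maps sample id -> population name.  A
    population with zero called genotypes at some variant receives the
    pseudocount-only frequency 0.5 with a warning.
    """
    labels = pd.Series(labels)
    pops = sorted(labels.unique())
    freqs = np.empty((len(pops), genotypes.n_variants))
    n_samples = {}
    for i, pop in enumerate(pops):
        members = [s for s in genotypes.samples if labels.get(s) == pop]
        if not members:
            raise ValueError(f"population {pop!r} has no genotyped sample")
        sub = genotypes.take_samples(np.array([genotypes.samples.index(s) for s in members]))
        called = sub.called.sum(axis=0)
        alt = np.nansum(sub.dosage, axis=0)
        if pseudocount <= 0 and (np.any(alt == 0) or np.any(alt == 2 * called)):
            raise ValueError("pseudocount must be positive when alleles are fixed")
        uncalled = called == 0
        if uncalled.any():
            warnings.warn(
                f"population {pop!r}: {int(uncalled.sum())} variant(s) with no called "
                "genotype; pseudocount-only frequency used"
            )
        freqs[i] = (alt + pseudocount) / (2.0 * called + 2.0 * pseudocount)
        n_samples[pop] = len(members)
    freqs = np.clip(freqs, _FREQ_EPS, 1.0 - _FREQ_EPS)
    return ReferencePanel(pops, freqs, n_samples, variants=genotypes.variants.copy())


def _loglik(dosage: np.ndarray, called: np.ndarray, Q: np.ndarray, F: np.ndarray) -> np.ndarray:
    """Row-wise log-likelihood for a batch. dosage NaN-filled with 0 where uncalled."""
    P = Q @ F
    P = np.clip(P, _FREQ_EPS, 1.0 - _FREQ_EPS)
    g = np.where(called, dosage, 0.0)
    h = np.where(called, 2.0 - dosage, 0.0)
    return (g * np.log(P) + h * np.log1p(-P)).sum(axis=1)


def estimate_ancestry_matrix(
    g: GenotypeMatrix,
    panel: ReferencePanel,
    tol: float = 1e-7,
    max_iter: int = 2000,
) -> tuple[pd.DataFrame, list[AncestryEstimate]]:
    """Supervised EM fit for every sample of ``g`` against ``panel``.

    Vectorised over individuals; each row converges when its successive
    log-likelihood gain drops below ``tol``.  Returns a tidy frame
    (sample_id, one column per component, loglik, converged) plus the raw
    per-individual estimates in sample order.
    """
    if g.n_variants != panel.M:
        raise ValueError("genotypes and panel must be variant-harmonized")
    F = panel.freqs
    if np.ptp(F, axis=0).max() < 1e-12:
        warnings.warn("all populations share identical frequencies: q is not identifiable")
    K = panel.K
    N = g.n_samples
    dosage = g.dosage
    called = g.called
    g_filled = np.where(called, dosage, 0.0)
    h_filled = np.where(called, 2.0 - dosage, 0.0)
    two_m = 2.0 * called.sum(axis=1)
    if np.any(two_m == 0):
        raise ValueError("individual with no called genotype")

    Q = np.full((N, K), 1.0 / K)
    ll = _loglik(dosage, called, Q, F)
    iters = np.zeros(N, dtype=int)
    converged = np.zeros(N, dtype=bool)
    active = np.ones(N, dtype=bool)
    Ft = F.T
    Gt = (1.0 - F).T

    def _em_step(Qa: np.ndarray, rows: np.ndarray) -> np.ndarray:
        P = np.clip(Qa @ F, _FREQ_EPS, 1.0 - _FREQ_EPS)
        # E-step responsibilities folded into the M-step update
        num = Qa * ((g_filled[rows] / P) @ Ft + (h_filled[rows] / (1.0 - P)) @ Gt)
        return num / num.sum(axis=1, keepdims=True)

    def _project(Qa: np.ndarray) -> np.ndarray:
        # floor away from the boundary: a multiplicative EM update cannot
        # revive a component once it collapses to ~0, so extrapolated
        # points keep a small interior margin; genuine boundary optima are
        # still reached by the plain EM steps shrinking geometrically
        Qa = np.clip(Qa, 1e-4, None)
        return Qa / Qa.sum(axis=1, keepdims=True)

    # safeguarded SQUAREM acceleration: two EM steps per cycle plus a
    # per-row extrapolation, falling back to the plain EM iterate whenever
    # the extrapolated point does not improve the log-likelihood
    cycle_cost = 3
    for _ in range(max(max_iter // cycle_cost, 1)):
        idx = np.flatnonzero(active)
        if idx.size == 0:
            break
        Q0 = Q[idx]
        Q1 = _em_step(Q0, idx)
        Q2 = _em_step(Q1, idx)
        r = Q1 - Q0
        v = (Q2 - Q1) - r
        vnorm = np.linalg.norm(v, axis=1)
        alpha = np.where(vnorm > 0, -np.linalg.norm(r, axis=1) / np.maximum(vnorm, 1e-300), -1.0)
        # never shorter than a plain double step, never a wild extrapolation
        alpha = np.clip(alpha, -16.0, -1.0)
        Qacc = _project(Q0 - 2.0 * alpha[:, None] * r + (alpha**2)[:, None] * v)
        ll2 = _loglik(dosage[idx], called[idx], Q2, F)
        ll_acc = _loglik(dosage[idx], called[idx], Qacc, F)
        take_acc = ll_acc >= ll2
        Qnew = np.where(take_acc[:, None], Qacc, Q2)
        new_ll = np.where(take_acc, ll_acc, ll2)
        gain = new_ll - ll[idx]
        Q[idx] = Qnew
        ll[idx] = new_ll
        iters[idx] += cycle_cost
        done = gain < tol * cycle_cost
        converged[idx[done]] = True
        active[idx[done]] = False

    # snap numerically-vanished components to exact boundary zeros
    Q[Q < _BOUNDARY_SNAP] = 0.0
    Q /= Q.sum(axis=1, keepdims=True)
    ll = _loglik(dosage, called, Q, F)

    estimates = [
        AncestryEstimate(q=Q[i], loglik=float(ll[i]), converged=bool(converged[i]),
                         iterations=int(iters[i]))
        for i in range(N)
    ]
    frame = pd.DataFrame(Q, columns=panel.populations)
    frame.insert(0, "sample_id", g.samples)
    frame["loglik"] = ll
    frame["converged"] = converged
    if not converged.all():
        warnings.warn(
            f"{int((~converged).sum())} individual(s) did not converge in "
            f"{max_iter} iterations; best iterate returned"
        )
    return frame, estimates


def estimate_ancestry(
    g_i: np.ndarray,
    panel: ReferencePanel,
    tol: float = 1e-7,
    max_iter: int = 2000,
) -> AncestryEstimate:
    """Supervised fit for a single dosage vector (NaN = missing call)."""
    g_i = np.asarray(g_i, dtype=float)
    gm = GenotypeMatrix(
        samples=["_single"],
        variants=panel.variants
        if panel.variants is not None
        else pd.DataFrame(
            {
                "chrom": ["1"] * panel.M,
                "pos": np.arange(1, panel.M + 1),
                "id": [f"m{j}" for j in range(panel.M)],
                "ref": ["A"] * panel.M,
                "alt": ["G"] * panel.M,
            }
        ),
        dosage=g_i[None, :],
    )
    _, ests = estimate_ancestry_matrix(gm, panel, tol=tol, max_iter=max_iter)
    return ests[0]


def _simplex_lattice(K: int, steps: int) -> np.ndarray:
    """All points q with q_k = j/steps, sum q = 1."""
    pts = []
    for combo in itertools.combinations(range(steps + K - 1), K - 1):
        prev = -1
        parts = []
        for c in combo:
            parts.append(c - prev - 1)
            prev = c
        parts.append(steps + K - 2 - prev)
        pts.append(parts)
    return np.asarray(pts, dtype=float) / steps


def grid_oracle(
    g_i: np.ndarray, panel: ReferencePanel, resolution: float = 0.01
) -> tuple[np.ndarray, float]:
    """Exhaustive simplex-lattice maximiser of the supervised likelihood.

    Brute-force test oracle: evaluates the log-likelihood at every lattice
    point ``{q : q_k = j * resolution, sum q = 1}`` and returns the argmax
    with its value.  Refuses combinatorially large lattices (K > 4, or more
    than ~5e5 points).
    """
    if panel.K > 4:
        raise ValueError("grid oracle limited to K <= 4")
    steps = int(round(1.0 / resolution))
    if abs(steps * resolution - 1.0) > 1e-9:
        raise ValueError("resolution must divide 1 evenly")
    from math import comb

    if comb(steps + panel.K - 1, panel.K - 1) > 500_000:
        raise ValueError("lattice too large at this resolution")
    lattice = _simplex_lattice(panel.K, steps)
    g_i = np.asarray(g_i, dtype=float)
    called = ~np.isnan(g_i)
    ll = _loglik(g_i[None, :].repeat(1, axis=0), called[None, :], lattice, panel.freqs)
    best = int(np.argmax(ll))
    return lattice[best], float(ll[best])


def _group_minor_counts(g: GenotypeMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Folded minor-allele count and total allele count per variant."""
    called = g.called.sum(axis=0)
    alt = np.nansum(g.dosage, axis=0)
    total = 2.0 * called
    minor = np.minimum(alt, total - alt)
    return minor, total


def maf_ci_filter(
    panel_eur: GenotypeMatrix,
    panel_pooled_native: GenotypeMatrix,
    panel_mapuche_like: GenotypeMatrix,
    level: float = 0.80,
    method: str = "wilson",
    rule: str = "and",
) -> np.ndarray:
    """Ancestry-informative-marker filter on MAF confidence intervals.

    For each variant a binomial confidence interval of the minor allele
    frequency (folded within each group independently) is computed at the
    given level in the European-like, pooled-Native and Mapuche-like
    groups.  With ``rule="and"`` (default, matching the published
    procedure) a variant is EXCLUDED when the European CI overlaps the
    pooled-Native CI *and* the European CI overlaps the Mapuche-like CI;
    ``rule="or"`` excludes on either overlap.  Variants with an
    uncallable group are skipped (not retained) with a warning.

    Returns a boolean mask over the (shared, harmonized) variant set:
    True = retained.
    """
    if not (panel_eur.n_variants == panel_pooled_native.n_variants == panel_mapuche_like.n_variants):
        raise ValueError("the three groups must share a harmonized variant set")
    if method not in ("wilson", "wald"):
        raise ValueError("method must be 'wilson' or 'wald'")
    if rule not in ("and", "or"):
        raise ValueError("rule must be 'and' or 'or'")
    alpha = 1.0 - level
    sm_method = {"wilson": "wilson", "wald": "normal"}[method]

    def _ci(g: GenotypeMatrix):
        minor, total = _group_minor_counts(g)
        ok = total > 0
        lo = np.zeros_like(minor)
        hi = np.ones_like(minor)
        if ok.any():
            lo_ok, hi_ok = proportion_confint(minor[ok], total[ok], alpha=alpha, method=sm_method)
            lo[ok], hi[ok] = lo_ok, hi_ok
        return lo, hi, ok

    lo_e, hi_e, ok_e = _ci(panel_eur)
    lo_n, hi_n, ok_n = _ci(panel_pooled_native)
    lo_m, hi_m, ok_m = _ci(panel_mapuche_like)
    usable = ok_e & ok_n & ok_m
    if not usable.all():
        warnings.warn(
            f"{int((~usable).sum())} variant(s) skipped: a group had no called genotype"
        )

    overlap_en = (lo_e <= hi_n) & (lo_n <= hi_e)
    overlap_em = (lo_e <= hi_m) & (lo_m <= hi_e)
    if rule == "and":
        excluded = overlap_en & overlap_em
    else:
        excluded = overlap_en | overlap_em
    return usable & ~excluded
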