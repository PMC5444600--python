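"""Population-structure toolkit: genotype QC, LD pruning, PCA and Fst.

QC thresholds follow the conventional strict phrasing: variants are removed
when the missing call rate is *over* ``max_missing`` or the minor allele
frequency is *under* ``min_maf``; values exactly at a threshold survive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict

import numpy as np

from .genotypes import GenotypeMatrix, is_autosomal


@dataclass
class QCReport:
    """Book-keeping of a QC pass; removals are sequential and disjoint."""

    variants_in: int
    removed_nonautosomal: int
    removed_missingness: int
    removed_maf: int
    removed_ld: int
    variants_out: int

    def __post_init__(self) -> None:
        removed = (
            self.removed_nonautosomal
            + self.removed_missingness
            + self.removed_maf
            + self.removed_ld
        )
        if self.variants_out != self.variants_in - removed:
            raise ValueError("QC report totals do not reconcile")
        if min(asdict(self).values()) < 0:
            raise ValueError("QC report counts must be non-negative")

    def to_dict(self) -> dict:
        return asdict(self)


def qc_filter(
    g: GenotypeMatrix, max_missing: float = 0.05, min_maf: float = 0.05
) -> tuple[GenotypeMatrix, QCReport]:
    """Remove non-autosomal variants, then high-missingness, then low-MAF.

    A variant is dropped when its missing fraction exceeds ``max_missing``
    (strictly) or its folded MAF is strictly below ``min_maf``, both
    evaluated on the input matrix.  Raises ``ValueError`` when nothing
    survives.
    """
    auto = is_autosomal(g.variants["chrom"])
    n_nonauto = int((~auto).sum())

    miss = g.missing_fraction()
    miss_fail = auto & (miss > max_missing)
    n_miss = int(miss_fail.sum())

    with np.errstate(invalid="ignore"):
        maf = g.maf()
    maf_fail = auto & ~miss_fail & (np.isnan(maf) | (maf < min_maf))
    n_maf = int(maf_fail.sum())

    keep = auto & ~miss_fail & ~maf_fail
    if not keep.any():
        raise ValueError("QC removed every variant: nothing left to analyze")

    report = QCReport(
        variants_in=g.n_variants,
        removed_nonautosomal=n_nonauto,
        removed_missingness=n_miss,
        removed_maf=n_maf,
        removed_ld=0,
        variants_out=int(keep.sum()),
    )
    return g.take_variants(keep), report


def _pairwise_r2(x: np.ndarray, y: np.ndarray) -> float:
    """Squared Pearson correlation of two dosage vectors, pairwise-complete."""
    ok = ~np.isnan(x) & ~np.isnan(y)
    if ok.sum() < 2:
        return 0.0
    xv, yv = x[ok], y[ok]
    sx, sy = xv.std(), yv.std()
    if sx == 0.0 or sy == 0.0:
        return 0.0
    r = np.mean((xv - xv.mean()) * (yv - yv.mean())) / (sx * sy)
    return float(r * r)


def ld_prune(
    g: GenotypeMatrix, r2_max: float = 0.1, window: int = 50, step: int = 5
) -> GenotypeMatrix:
    """Greedy left-to-right LD pruning within a sliding variant window.

    Within each window of ``window`` variants (advanced by ``step``), a
    variant is dropped as soon as its squared dosage correlation with an
    earlier *retained* in-window variant exceeds ``r2_max``.  Deterministic
    given the input order: the leftmost variant of a correlated set wins.
    """
    if window < step:
        raise ValueError(f"window ({window}) must be >= step ({step})")
    m = g.n_variants
    keep = np.ones(m, dtype=bool)
    d = g.dosage
    any_missing = np.isnan(d).any(axis=0)
    for start in range(0, max(m - 1, 1), step):
        idx = [j for j in range(start, min(start + window, m)) if keep[j]]
        if len(idx) > 1:
            block_missing = any_missing[idx].any()
            r2 = None
            if not block_missing:
                # complete data: one correlation matrix for the window
                with np.errstate(invalid="ignore"):
                    r2 = np.corrcoef(d[:, idx], rowvar=False) ** 2
                r2 = np.nan_to_num(r2, nan=0.0)
            for a_pos, j in enumerate(idx):
                if not keep[j]:
                    continue
                for b_pos, i in enumerate(idx[:a_pos]):
                    if not keep[i]:
                        continue
                    val = (
                        r2[b_pos, a_pos]
                        if r2 is not None
                        else _pairwise_r2(d[:, i], d[:, j])
                    )
                    if val > r2_max:
                        keep[j] = False
                        break
        if start + window >= m:
            break
    return g.take_variants(keep)


def pca(g: GenotypeMatrix, n_components: int = 10) -> tuple[np.ndarray, np.ndarray]:
    """Genetic PCA with allele-frequency standardisation.

    Each variant is mean-centred and scaled by ``sqrt(p(1-p))`` where ``p``
    is the observed alt-allele frequency; missing dosages are mean-imputed.
    Monomorphic variants are excluded with a warning.  Returns
    ``(scores, explained)`` where ``scores`` is ``(n, n_components)``
    (columns are principal-component projections, i.e. left singular
    vectors scaled by singular values) and ``explained`` the fractions of
    total variance, non-increasing.
    """
    p = g.allele_freq()
    poly = (p > 0) & (p < 1) & ~np.isnan(p)
    if not poly.all():
        warnings.warn(f"excluding {int((~poly).sum())} monomorphic variant(s) from PCA")
    d = g.dosage[:, poly]
    p = p[poly]
    if n_components >= min(d.shape):
        raise ValueError("n_components must be < min(n_samples, n_variants)")
    x = d - 2.0 * p  # centre at twice the allele frequency
    x[np.isnan(x)] = 0.0  # mean imputation after centring
    x /= np.sqrt(p * (1.0 - p))
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    scores = u[:, :n_components] * s[:n_components]
    explained = (s**2) / np.sum(s**2)
    return scores, explained[:n_components]


def fst_wc(gA: GenotypeMatrix, gB: GenotypeMatrix) -> float:
    """Weir & Cockerham (1984) two-population multi-locus Fst.

    Uses the variance-components estimator with the a, b, c locus
    components combined as a ratio of sums over loci.  The two matrices
    must share their variant set (harmonize first if needed); loci where
    either side has fewer than two called genotypes are skipped.
    """
    if gA.n_variants != gB.n_variants:
        raise ValueError("matrices must share a common variant set; harmonize first")
    if gA.n_samples < 2 or gB.n_samples < 2:
        raise ValueError("need at least two samples per population")
    if gA.n_variants == 0:
        raise ValueError("no overlapping variants")

    def _counts(g: GenotypeMatrix):
        called = g.called
        n = called.sum(axis=0).astype(float)  # called individuals per locus
        with np.errstate(invalid="ignore"):
            p = np.nansum(g.dosage, axis=0) / (2.0 * n)
        het = np.nansum(g.dosage == 1.0, axis=0) / np.maximum(n, 1.0)
        return n, p, het

    n1, p1, h1 = _counts(gA)
    n2, p2, h2 = _counts(gB)
    ok = (n1 >= 2) & (n2 >= 2)
    if not ok.any():
        raise ValueError("no locus with >=2 called genotypes on both sides")
    n1, p1, h1 = n1[ok], p1[ok], h1[ok]
    n2, p2, h2 = n2[ok], p2[ok], h2[ok]

    r = 2.0
    nbar = (n1 + n2) / r
    nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1.0)
    pbar = (n1 * p1 + n2 * p2) / (r * nbar)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1.0) * nbar)
    hbar = (n1 * h1 + n2 * h2) / (r * nbar)

    a = (nbar / nc) * (
        s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4.0) / (nbar - 1.0)
    )
    b = (nbar / (nbar - 1.0)) * (
        pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
    )
    c = hbar / 2.0

    denom = np.sum(a + b + c)
    if denom == 0.0:
        raise ValueError("zero total variance: no polymorphic locus")
    return float(np.sum(a) / denom)
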