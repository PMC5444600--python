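"""Shared genotype container.

Genotypes are stored as alternate-allele dosages (0, 1, 2) in a dense
``float64`` matrix with ``NaN`` marking missing calls.  Variants are
identified by (chrom, pos, ref, alt); coordinates are 1-based as in VCF.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

VARIANT_COLUMNS = ["chrom", "pos", "id", "ref", "alt"]

#: chromosome labels accepted as autosomal (with or without a "chr" prefix)
AUTOSOMES = frozenset(str(i) for i in range(1, 23))


def is_autosomal(chrom: pd.Series) -> np.ndarray:
    """Boolean mask of autosomal chromosome labels ("chr" prefix tolerated)."""
    stripped = chrom.astype(str).str.replace("^chr", "", regex=True)
    return stripped.isin(AUTOSOMES).to_numpy()


@dataclass
class GenotypeMatrix:
    """Individuals x biallelic SNPs, alt-allele dosage with missingness.

    Parameters
    ----------
    samples : list of str
        Ordered sample identifiers (rows of ``dosage``).
    variants : pandas.DataFrame
        One row per variant with columns ``chrom, pos, id, ref, alt``
        (columns of ``dosage``), in matrix order.
    dosage : numpy.ndarray
        ``(n_samples, n_variants)`` float array with values in
        ``{0, 1, 2, NaN}``; ``NaN`` is a missing call.
    """

    samples: list[str]
    variants: pd.DataFrame
    dosage: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=float)
        if self.dosage.shape != (len(self.samples), len(self.variants)):
            raise ValueError(
                f"dosage shape {self.dosage.shape} inconsistent with "
                f"{len(self.samples)} samples x {len(self.variants)} variants"
            )
        missing = set(VARIANT_COLUMNS) - set(self.variants.columns)
        if missing:
            raise ValueError(f"variants table lacks columns: {sorted(missing)}")
        valid = np.isnan(self.dosage) | np.isin(self.dosage, (0.0, 1.0, 2.0))
        if not valid.all():
            raise ValueError("dosages must be 0, 1, 2 or NaN")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def called(self) -> np.ndarray:
        """Boolean mask of non-missing calls."""
        return ~np.isnan(self.dosage)

    def variant_keys(self) -> pd.Index:
        """Identity of each variant as a (chrom, pos, ref, alt) MultiIndex."""
        v = self.variants
        return pd.MultiIndex.from_arrays(
            [v["chrom"].astype(str), v["pos"].astype(int), v["ref"], v["alt"]],
            names=["chrom", "pos", "ref", "alt"],
        )

    def allele_freq(self) -> np.ndarray:
        """Observed alt-allele frequency per variant (missing calls ignored)."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosage, axis=0) / 2.0

    def maf(self) -> np.ndarray:
        """Folded minor-allele frequency per variant."""
        p = self.allele_freq()
        return np.minimum(p, 1.0 - p)

    def missing_fraction(self) -> np.ndarray:
        return np.isnan(self.dosage).mean(axis=0)

    def take_variants(self, index: np.ndarray) -> "GenotypeMatrix":
        """Subset to the given variant positions (boolean mask or indices)."""
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return GenotypeMatrix(
            samples=list(self.samples),
            variants=self.variants.iloc[index].reset_index(drop=True),
            dosage=self.dosage[:, index],
        )

    def take_samples(self, index: np.ndarray) -> "GenotypeMatrix":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return GenotypeMatrix(
            samples=[self.samples[i] for i in index],
            variants=self.variants.copy(),
            dosage=self.dosage[index, :],
        )


def harmonize(a: GenotypeMatrix, b: GenotypeMatrix) -> tuple[GenotypeMatrix, GenotypeMatrix]:
    """Restrict two matrices to their shared (chrom, pos, ref, alt) variants.

    Variant order follows ``a``.  Strand flips are not resolved: a variant
    present at the same site with swapped or different alleles simply does
    not match.  Raises ``ValueError`` when no variant is shared.
    """
    ka, kb = a.variant_keys(), b.variant_keys()
    common = ka.intersection(kb)
    if len(common) == 0:
        raise ValueError("no overlapping variants between the two matrices")
    mask_a = ka.isin(common)
    a2 = a.take_variants(mask_a)
    pos_b = pd.Series(np.arange(len(kb)), index=kb)
    b2 = b.take_variants(pos_b.loc[a2.variant_keys()].to_numpy())
    return a2, b2
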