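"""Readers and writers for the standard exchange formats.

Genotypes travel as VCF (GT field) or PLINK bed/bim/fam; tables as CSV;
ground truth and result bundles as JSON; configuration as YAML.
Coordinates are 1-based as in VCF and variant identity is
(chrom, pos, ref, alt).  Multi-allelic VCF records are skipped with a
warning; strand flips are never auto-resolved.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .genotypes import GenotypeMatrix

# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

_GT_STRINGS = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}


def write_vcf(g: GenotypeMatrix, path: str | Path) -> None:
    """Write dosages as an uncompressed VCF with a GT field."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in pd.unique(g.variants["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(g.samples)
            + "\n"
        )
        for j, var in g.variants.iterrows():
            gts = "\t".join(
                _GT_STRINGS.get(d, "./.") for d in g.dosage[:, j]
            )
            fh.write(
                f"{var.chrom}\t{int(var.pos)}\t{var.id}\t{var.ref}\t{var.alt}"
                f"\t.\t.\t.\tGT\t{gts}\n"
            )


def read_vcf(path: str | Path) -> GenotypeMatrix:
    """Load biallelic records from a VCF (plain or gzipped).

    Multi-allelic records are skipped with a warning carrying the count.
    Sample and variant order are preserved.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows_meta, dosages = [], []
    n_multi = 0
    for variant in vcf:
        if len(variant.ALT) != 1:
            n_multi += 1
            continue
        rows_meta.append(
            (
                str(variant.CHROM),
                int(variant.POS),
                variant.ID or f"{variant.CHROM}:{variant.POS}",
                variant.REF,
                variant.ALT[0],
            )
        )
        row = np.empty(len(samples))
        for i, gt in enumerate(variant.genotypes):
            a = [x for x in gt[:2]]
            row[i] = np.nan if (a[0] < 0 or a[1] < 0) else float(a[0] + a[1])
        dosages.append(row)
    vcf.close()
    if n_multi:
        warnings.warn(f"skipped {n_multi} multi-allelic record(s)")
    if not rows_meta:
        raise ValueError(f"no biallelic variant found in {path}")
    variants = pd.DataFrame(rows_meta, columns=["chrom", "pos", "id", "ref", "alt"])
    return GenotypeMatrix(
        samples=samples, variants=variants, dosage=np.array(dosages).T
    )


# ---------------------------------------------------------------------------
# PLINK bed/bim/fam
# ---------------------------------------------------------------------------
# .bed is SNP-major, 2 bits per genotype: 00 = homozygous A1, 01 = missing,
# 10 = heterozygous, 11 = homozygous A2.  We store the alternate allele as
# A1, so the 2-bit code maps to alt-dosage 2 / missing / 1 / 0.

_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])
_CODE_FOR_DOSAGE = {2.0: 0b00, 1.0: 0b10, 0.0: 0b11}
_DOSAGE_FOR_CODE = {0b00: 2.0, 0b01: np.nan, 0b10: 1.0, 0b11: 0.0}


def write_plink(g: GenotypeMatrix, prefix: str | Path) -> None:
    """Write a bed/bim/fam triple (alt allele stored as A1)."""
    prefix = Path(prefix)
    n = g.n_samples
    with open(f"{prefix}.bed", "wb") as fh:
        fh.write(_BED_MAGIC)
        for j in range(g.n_variants):
            col = g.dosage[:, j]
            byte_row = bytearray((n + 3) // 4)
            for i in range(n):
                d = col[i]
                code = 0b01 if np.isnan(d) else _CODE_FOR_DOSAGE[d]
                byte_row[i // 4] |= code << (2 * (i % 4))
            fh.write(bytes(byte_row))
    bim = g.variants.assign(cm=0)[["chrom", "id", "cm", "pos", "alt", "ref"]]
    bim.to_csv(f"{prefix}.bim", sep="\t", header=False, index=False)
    fam = pd.DataFrame(
        {"fid": g.samples, "iid": g.samples, "pat": 0, "mat": 0, "sex": 0, "phe": -9}
    )
    fam.to_csv(f"{prefix}.fam", sep=" ", header=False, index=False)


def read_plink(prefix: str | Path) -> GenotypeMatrix:
    """Read a bed/bim/fam triple written in SNP-major order."""
    prefix = Path(prefix)
    fam = pd.read_csv(
        f"{prefix}.fam", sep=r"\s+", header=None,
        names=["fid", "iid", "pat", "mat", "sex", "phe"], dtype={"iid": str},
    )
    bim = pd.read_csv(
        f"{prefix}.bim", sep=r"\s+", header=None,
        names=["chrom", "id", "cm", "pos", "a1", "a2"], dtype={"chrom": str},
    )
    n, m = len(fam), len(bim)
    raw = Path(f"{prefix}.bed").read_bytes()
    if raw[:3] != _BED_MAGIC:
        raise ValueError(f"{prefix}.bed: bad magic (not a SNP-major PLINK bed file)")
    stride = (n + 3) // 4
    if len(raw) != 3 + stride * m:
        raise ValueError(f"{prefix}.bed: unexpected size for {n} samples x {m} variants")
    data = np.frombuffer(raw, dtype=np.uint8, offset=3).reshape(m, stride)
    dosage = np.empty((n, m))
    shifts = 2 * (np.arange(n) % 4)
    bytes_idx = np.arange(n) // 4
    for j in range(m):
        codes = (data[j, bytes_idx] >> shifts) & 0b11
        dosage[:, j] = [_DOSAGE_FOR_CODE[c] for c in codes]
    variants = pd.DataFrame(
        {
            "chrom": bim["chrom"].astype(str),
            "pos": bim["pos"].astype(int),
            "id": bim["id"],
            "ref": bim["a2"],
            "alt": bim["a1"],
        }
    )
    return GenotypeMatrix(samples=list(fam["iid"]), variants=variants, dosage=dosage)


# ---------------------------------------------------------------------------
# tables, config, bundles
# ---------------------------------------------------------------------------

def write_labels(labels: dict[str, str] | pd.Series, path: str | Path) -> None:
    pd.Series(labels, name="population").rename_axis("sample_id").reset_index().to_csv(
        path, index=False
    )


def read_labels(path: str | Path) -> pd.Series:
    df = pd.read_csv(path, dtype=str)
    return df.set_index("sample_id")["population"]


def write_json(obj: dict, path: str | Path) -> None:
    """Atomic JSON write (temp file then rename)."""
    path = Path(path)
    tmp = path.with_suffix(path.suffix + ".tmp")
    with tmp.open("w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_json_default)
    tmp.replace(path)


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


def read_yaml(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def write_yaml(obj: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(obj, fh, sort_keys=True)
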