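"""Reading genotype dosages (VCF or TSV matrix) and phenotype tables."""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass
class VariantRecord:
    """One variant's expected minor-allele dosages, aligned to the sample list."""

    id: str
    chrom: str
    pos: int
    dosages: np.ndarray  # float in [0, 2], NaN = missing

    @property
    def missingness(self) -> float:
        return float(np.isnan(self.dosages).mean())


def read_phenotypes(path: str | Path, transform: str = "none") -> pd.DataFrame:
    """Phenotype TSV with columns sample_id, status, trait.

    Returns a frame indexed by sample_id with status (0/1), trait (raw) and
    trait_transformed (after the configured transform; square-root requires
    a non-negative trait).
    """
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    required = {"sample_id", "status", "trait"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"phenotype file lacks columns: {sorted(missing)}")
    if not df["status"].isin([0, 1]).all():
        raise ValueError("status must be binary 0/1")
    df = df.set_index("sample_id")
    if transform == "none":
        df["trait_transformed"] = df["trait"].astype(float)
    elif transform == "sqrt":
        if (df["trait"] < 0).any():
            raise ValueError("square-root transform requires a non-negative trait")
        df["trait_transformed"] = np.sqrt(df["trait"].astype(float))
    else:
        raise ValueError(f"unknown transform: {transform!r}")
    return df


def _align(dosages: np.ndarray, geno_samples: Sequence[str], samples: Sequence[str]) -> np.ndarray:
    idx = {s: i for i, s in enumerate(geno_samples)}
    out = np.full(len(samples), np.nan)
    for j, s in enumerate(samples):
        if s in idx:
            out[j] = dosages[idx[s]]
    return out


def read_genotypes_tsv(
    path: str | Path, samples: Sequence[str]
) -> Iterator[VariantRecord]:
    """Dosage matrix TSV: columns id, chrom, pos, then one column per sample.

    Dosages are aligned to the given sample order; samples absent from the
    file become missing.  Zero sample overlap is fatal.
    """
    df = pd.read_csv(path, sep="\t", dtype={"id": str, "chrom": str})
    meta = ["id", "chrom", "pos"]
    if df.columns[:3].tolist() != meta:
        raise ValueError("genotype TSV must start with columns id, chrom, pos")
    geno_samples = df.columns[3:].tolist()
    overlap = set(geno_samples) & set(samples)
    if not overlap:
        raise ValueError("no overlap between genotype and phenotype samples")
    for row in df.itertuples(index=False):
        vals = np.asarray(row[3:], dtype=float)
        if np.nanmax(vals, initial=0.0) > 2 or np.nanmin(vals, initial=0.0) < 0:
            logger.warning("variant %s has dosages outside [0, 2]; skipped", row.id)
            continue
        yield VariantRecord(
            id=str(row.id),
            chrom=str(row.chrom),
            pos=int(row.pos),
            dosages=_align(vals, geno_samples, samples),
        )


def read_genotypes_vcf(
    path: str | Path, samples: Sequence[str]
) -> Iterator[VariantRecord]:
    """VCF reader: dosage from the DS FORMAT field when present, else the GT
    minor-allele count.  Biallelic records only; others are skipped with a
    warning."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    geno_samples = list(vcf.samples)
    if not set(geno_samples) & set(samples):
        raise ValueError("no overlap between VCF and phenotype samples")
    for var in vcf:
        if len(var.ALT) != 1:
            logger.warning("variant %s is not biallelic; skipped", var.ID)
            continue
        ds = None
        try:
            ds = var.format("DS")
        except KeyError:
            ds = None
        if ds is not None:
            dosages = np.asarray(ds, dtype=float).reshape(-1)
        else:
            # cyvcf2 gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
            gt = var.gt_types.astype(float)
            dosages = np.where(gt == 2, np.nan, np.where(gt == 3, 2.0, gt))
        dosages = np.where((dosages < 0) | (dosages > 2), np.nan, dosages)
        vid = var.ID or f"{var.CHROM}:{var.POS}"
        yield VariantRecord(
            id=vid,
            chrom=str(var.CHROM),
            pos=int(var.POS),
            dosages=_align(dosages, geno_samples, samples),
        )


def read_genotypes(
    path: str | Path, samples: Sequence[str], format: str | None = None
) -> Iterator[VariantRecord]:
    """Dispatch on format ('vcf' or 'tsv'; inferred from the extension)."""
    path = Path(path)
    if format is None:
        format = "vcf" if ".vcf" in path.suffixes else "tsv"
    if format == "vcf":
        return read_genotypes_vcf(path, samples)
    if format == "tsv":
        return read_genotypes_tsv(path, samples)
    raise ValueError(f"unknown genotype format: {format!r}")
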