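"""Per-variant association scan: the four tests applied across a cohort."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .assoc import (
    fisher_combine,
    genomic_inflation,
    ivw_combine,
    linear_assoc_adjusted,
    logistic_assoc,
)
from .io import VariantRecord

RESULT_COLUMNS = [
    "id", "chrom", "pos", "n", "maf", "excluded",
    "beta1", "se1", "z1", "p1",
    "beta2", "se2", "z2", "p2",
    "fisher_chi2", "p_fisher", "ivw_s", "ivw_p",
    "neglog10_p1", "neglog10_p2", "neglog10_p_fisher", "neglog10_p_ivw",
    "promising", "flag",
]

LAMBDA_TESTS = {"logistic": "p1", "linear": "p2", "fisher": "p_fisher", "ivw": "p_ivw"}


@dataclass
class ScanResult:
    """Results table plus per-test genomic-control inflation factors."""

    table: pd.DataFrame
    lambdas: dict[str, float]


def _neglog10(p: float) -> float:
    return float(-np.log10(p)) if np.isfinite(p) and p > 0 else np.nan


def run_assoc(
    variants: Iterable[VariantRecord],
    phenotypes: pd.DataFrame,
    maf_floor: float = 0.01,
    direction: str = "positive",
    threshold: float = 5.0,
) -> ScanResult:
    """Apply the four tests to every variant against one phenotype table.

    Per variant, samples with missing dosage are dropped (complete-case);
    the trait is taken from the ``trait_transformed`` column.  Variants with
    folded MAF below ``maf_floor`` are marked excluded and left out of the
    genomic-control lambdas; ``promising`` flags -log10(p_ivw) above the
    screening threshold (default 5).  Flagged fits yield missing codes in
    the output rather than aborting the scan.
    """
    status = phenotypes["status"].to_numpy(dtype=float)
    trait = phenotypes["trait_transformed"].to_numpy(dtype=float)

    rows = []
    for var in variants:
        keep = np.isfinite(var.dosages) & np.isfinite(trait)
        g = var.dosages[keep]
        d = status[keep]
        y = trait[keep]
        n = int(keep.sum())
        row: dict = {"id": var.id, "chrom": var.chrom, "pos": var.pos, "n": n}
        maf = float(np.mean(g) / 2) if n else np.nan
        maf = min(maf, 1 - maf) if np.isfinite(maf) else np.nan
        row["maf"] = maf
        row["excluded"] = bool(not np.isfinite(maf) or maf < maf_floor)
        r1 = logistic_assoc(d, g)
        r2 = linear_assoc_adjusted(y, g, d)
        row.update(beta1=r1.beta, se1=r1.se, z1=r1.z, p1=r1.p)
        row.update(beta2=r2.beta, se2=r2.se, z2=r2.z, p2=r2.p)
        if r1.ok and r2.ok:
            fisher = fisher_combine(r1.p, r2.p)
            ivw = ivw_combine(r1, r2, direction=direction)
            row.update(fisher_chi2=fisher.statistic, p_fisher=fisher.p,
                       ivw_s=ivw.statistic, ivw_p=ivw.p)
            row["flag"] = ""
        else:
            row.update(fisher_chi2=np.nan, p_fisher=np.nan,
                       ivw_s=np.nan, ivw_p=np.nan)
            row["flag"] = r1.flag or r2.flag or ""
        for src, dst in [("p1", "neglog10_p1"), ("p2", "neglog10_p2"),
                         ("p_fisher", "neglog10_p_fisher"), ("ivw_p", "neglog10_p_ivw")]:
            row[dst] = _neglog10(row[src])
        row["promising"] = bool(
            np.isfinite(row["neglog10_p_ivw"])
            and row["neglog10_p_ivw"] > threshold
            and not row["excluded"]
        )
        rows.append(row)

    table = pd.DataFrame.from_records(rows, columns=RESULT_COLUMNS)
    lambdas = {}
    usable = table[~table["excluded"]]
    for test, col in LAMBDA_TESTS.items():
        pcol = {"ivw": "ivw_p"}.get(test, col)
        p = usable[pcol].to_numpy(dtype=float)
        p = p[np.isfinite(p) & (p > 0)]
        lambdas[test] = genomic_inflation(p) if p.size else np.nan
    return ScanResult(table=table, lambdas=lambdas)


def write_results(result: ScanResult, path: str) -> None:
    """Write the scan table as TSV with 6 significant digits."""
    result.table.to_csv(path, sep="\t", index=False, float_format="%.6g")
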