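"""Synthetic GWAS fixture emulating a lung-cancer/smoking-style dataset.

The generator writes a dosage matrix plus a phenotype table with a binary
disease status and a right-skewed, non-negative count-like trait (so the
square-root transform is exercised).  Most variants are null; a configurable
number are causal under the dual-pathway disease model: each causal locus
raises a latent (square-root scale) trait and contributes a direct log-odds
term, and observed dosages for causal variants are noisy copies of the
causal genotypes, mimicking imputation.  The ground-truth causal variant ids
are written alongside.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit

# latent trait is the square root of the count-like trait; the location and
# scale mimic sqrt(cigarettes-per-day) in smokers (~sqrt(20) +/- 1)
LATENT_MEAN = 4.5
LATENT_SD = 1.0
CAUSAL_MAF = 0.3
#: case fraction mirrors a 1154-case / 1137-control design
CASE_FRACTION = 1154 / (1154 + 1137)


@dataclass
class FixturePaths:
    genotypes: Path
    phenotypes: Path
    causal: Path


def make_fixture(
    n_samples: int = 2291,
    n_variants: int = 1000,
    n_causal: int = 5,
    seed: int = 0,
    out_prefix: str | Path = "fixture",
    or_causal: float = 1.8,
    h2_causal: float = 0.02,
    dosage_noise_sd: float = 0.25,
    incidence: float = 0.05,
    maf_range: tuple[float, float] = (0.05, 0.5),
) -> FixturePaths:
    """Write genotype/phenotype/causal-truth files; byte-identical per seed.

    Cases and controls are ascertained from a simulated population at the
    given incidence, split ~50:50 (1154:1137).  Null variants are
    independent Hardy-Weinberg draws; causal variants act through both a
    latent-trait path (per-locus heritability ``h2_causal`` on the latent
    scale) and a direct path (per-allele odds ratio ``or_causal``).
    """
    if n_causal > n_variants:
        raise ValueError("n_causal cannot exceed n_variants")
    rng = np.random.default_rng(seed)
    n_cases = int(round(n_samples * CASE_FRACTION))
    n_controls = n_samples - n_cases

    beta1 = np.sqrt(h2_causal / (2 * CAUSAL_MAF * (1 - CAUSAL_MAF)))
    resid_var = LATENT_SD**2 - n_causal * h2_causal
    if resid_var <= 0:
        raise ValueError("n_causal * h2_causal exceeds the latent trait variance")
    gamma1 = np.log(or_causal)
    gamma2 = 1.0  # log-odds per latent-trait unit

    # oversample a population, then take the case/control quota
    pop_n = int(np.ceil(max(n_cases / incidence, n_controls / (1 - incidence)) * 1.4))
    g_causal = rng.binomial(2, CAUSAL_MAF, size=(pop_n, n_causal)).astype(float)
    latent = (
        LATENT_MEAN
        + (g_causal - 2 * CAUSAL_MAF) @ np.full(n_causal, beta1)
        + rng.normal(0.0, np.sqrt(resid_var), pop_n)
    )
    eta = g_causal @ np.full(n_causal, gamma1) + gamma2 * (latent - LATENT_MEAN)
    # anchor the intercept so the empirical population incidence is exact
    gamma0 = brentq(
        lambda g0: expit(g0 + eta).mean() - incidence, -30.0, 10.0, xtol=1e-12
    )
    d = (rng.random(pop_n) < expit(gamma0 + eta)).astype(int)
    case_idx = np.flatnonzero(d == 1)[:n_cases]
    control_idx = np.flatnonzero(d == 0)[:n_controls]
    if len(case_idx) < n_cases or len(control_idx) < n_controls:
        raise RuntimeError("population oversample too small for the requested quota")
    keep = np.concatenate([case_idx, control_idx])
    g_causal, latent, d = g_causal[keep], latent[keep], d[keep]

    # non-negative, right-skewed observed trait: square of the latent scale
    trait = np.clip(latent, 0.0, None) ** 2

    causal_slots = rng.choice(n_variants, size=n_causal, replace=False)
    mafs = rng.uniform(*maf_range, size=n_variants)
    order = rng.permutation(n_samples)  # shuffle cases and controls together

    prefix = Path(out_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    paths = FixturePaths(
        genotypes=Path(f"{prefix}.geno.tsv"),
        phenotypes=Path(f"{prefix}.pheno.tsv"),
        causal=Path(f"{prefix}.causal.txt"),
    )

    sample_ids = [f"S{i + 1:05d}" for i in range(n_samples)]
    slot_to_causal = {int(s): j for j, s in enumerate(causal_slots)}
    with open(paths.genotypes, "w") as fh:
        fh.write("id\tchrom\tpos\t" + "\t".join(sample_ids) + "\n")
        for v in range(n_variants):
            vid = f"var{v + 1:05d}"
            if v in slot_to_causal:
                j = slot_to_causal[v]
                dos = np.clip(
                    g_causal[:, j] + rng.normal(0.0, dosage_noise_sd, n_samples),
                    0.0, 2.0,
                )
            else:
                dos = rng.binomial(2, mafs[v], size=n_samples).astype(float)
            dos = dos[order]
            fh.write(
                f"{vid}\t1\t{(v + 1) * 1000}\t"
                + "\t".join(format(x, ".4f") for x in dos)
                + "\n"
            )

    with open(paths.phenotypes, "w") as fh:
        fh.write("sample_id\tstatus\ttrait\n")
        for i, orig in enumerate(order):
            fh.write(f"{sample_ids[i]}\t{d[orig]}\t{format(trait[orig], '.4f')}\n")

    with open(paths.causal, "w") as fh:
        for v in sorted(slot_to_causal):
            fh.write(f"var{v + 1:05d}\n")
    return paths
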