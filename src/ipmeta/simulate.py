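"""Generative model for a biallelic marker in LD with a disease locus.

The population model has three layers:

1. A disease locus A (minor-allele frequency ``q1``) and a SNP marker M
   (minor-allele frequency ``m1``) in linkage disequilibrium quantified by
   the correlation coefficient ``r`` between allele indicators on a
   haplotype.  Individuals are random unions of two haplotypes
   (Hardy-Weinberg, random mating).
2. An intermediate quantitative trait ``Y = beta0 + beta1 * code(G_A) + eps``
   with Gaussian residual ``eps ~ N(0, sigma2_E)``.  The effect ``beta1`` is
   derived from a target locus-specific heritability h2 so that the coded
   genotype explains exactly h2 of the total trait variance.
3. A logistic penetrance
   ``P(D=1 | G_A, Y) = expit(gamma0 + gamma1 * code(G_A) + gamma2 * Y)``.

The generative equations act on the disease-locus genotype; association
tests are applied to the marker, so the marker-disease association decays
with r and vanishes at r = 0 (the null).  Case-control cohorts are drawn by
rejection sampling from the population at the calibrated prevalence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Literal

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit, logit, roots_hermite

Coding = Literal["additive", "dominant", "recessive"]

#: genotype coding schemes: coded value for 0, 1 or 2 copies of the minor allele
CODINGS: dict[str, tuple[float, float, float]] = {
    "additive": (0.0, 1.0, 2.0),
    "dominant": (0.0, 1.0, 1.0),
    "recessive": (0.0, 0.0, 1.0),
}

_GH_NODES = 64


def code_genotypes(g: np.ndarray, coding: Coding) -> np.ndarray:
    """Map minor-allele counts {0,1,2} to coded values under a coding scheme."""
    table = np.asarray(CODINGS[coding], dtype=float)
    return table[np.asarray(g, dtype=np.intp)]


def hwe_genotype_freqs(q: float) -> np.ndarray:
    """Hardy-Weinberg genotype frequencies (0, 1, 2 minor alleles)."""
    return np.array([(1 - q) ** 2, 2 * q * (1 - q), q * q])


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# linkage disequilibrium


@dataclass(frozen=True)
class LDSpec:
    """Two-locus haplotype model: marker MAF, disease-locus MAF, correlation r."""

    m1: float
    q1: float
    r: float

    def __post_init__(self) -> None:
        if not (0 < self.m1 < 1 and 0 < self.q1 < 1):
            raise ValueError("allele frequencies must lie strictly in (0, 1)")
        if not (0 <= self.r <= 1):
            raise ValueError("r must lie in [0, 1]")

    @property
    def d(self) -> float:
        """Disequilibrium coefficient D implied by r."""
        return self.r * np.sqrt(
            self.m1 * (1 - self.m1) * self.q1 * (1 - self.q1)
        )

    @property
    def max_r(self) -> float:
        """Largest r for which all four haplotype frequencies are non-negative."""
        m2, q2 = 1 - self.m1, 1 - self.q1
        d_max = min(self.m1 * q2, m2 * self.q1)
        return d_max / np.sqrt(self.m1 * m2 * self.q1 * q2)


def haplotype_frequencies(ld: LDSpec) -> np.ndarray:
    """Four haplotype frequencies (M1A1, M1A2, M2A1, M2A2).

    M1/A1 denote the minor alleles.  D is parameterized from r via
    ``D = r * sqrt(m1 m2 q1 q2)``; an r implying a negative frequency is
    rejected with the maximum feasible r in the message.
    """
    m1, q1, d = ld.m1, ld.q1, ld.d
    m2, q2 = 1 - m1, 1 - q1
    freqs = np.array([m1 * q1 + d, m1 * q2 - d, m2 * q1 - d, m2 * q2 + d])
    if np.any(freqs < -1e-12):
        raise ValueError(
            f"infeasible LD: r={ld.r} implies a negative haplotype frequency; "
            f"maximum feasible r for (m1={m1}, q1={q1}) is {ld.max_r:.6f}"
        )
    return np.clip(freqs, 0.0, 1.0)


def sample_joint_genotypes(
    ld: LDSpec, n: int, rng
) -> tuple[np.ndarray, np.ndarray]:
    """Draw n individuals as random unions of two haplotypes.

    Returns ``(g_disease, g_marker)`` minor-allele counts in {0, 1, 2}.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    rng = _as_rng(rng)
    cum = np.cumsum(haplotype_frequencies(ld))
    cum[-1] = 1.0
    hap = np.searchsorted(cum, rng.random((n, 2)))
    # haplotype index: 0=M1A1, 1=M1A2, 2=M2A1, 3=M2A2
    marker_allele = hap < 2
    disease_allele = (hap == 0) | (hap == 2)
    return (
        disease_allele.sum(axis=1).astype(np.int8),
        marker_allele.sum(axis=1).astype(np.int8),
    )


# ---------------------------------------------------------------------------
# trait model


@dataclass(frozen=True)
class TraitModel:
    """Linear model for the intermediate phenotype.

    ``beta1`` is tied to the locus-specific heritability ``h2``: the variance
    of ``beta1 * code(G)`` over the genotype distribution equals
    ``h2 * total_variance``.  When ``mediated`` is off the genotype->trait
    path is severed (beta1 = 0) regardless of h2.
    """

    coding: Coding = "additive"
    h2: float = 0.0
    beta0: float = 0.0
    beta1: float = 0.0
    sigma2_E: float = 1.0
    mediated: bool = True

    def __post_init__(self) -> None:
        if not (0 <= self.h2 < 1):
            raise ValueError("h2 must lie in [0, 1)")
        if self.sigma2_E <= 0:
            raise ValueError("sigma2_E must be positive")

    @classmethod
    def from_heritability(
        cls,
        h2: float,
        coding: Coding,
        genotype_freqs: np.ndarray,
        total_variance: float = 1.0,
        beta0: float = 0.0,
        mediated: bool = True,
    ) -> "TraitModel":
        if mediated:
            beta1, sigma2_E = effect_from_heritability(
                h2, coding, genotype_freqs, total_variance
            )
        else:
            beta1, sigma2_E = 0.0, total_variance
        return cls(
            coding=coding,
            h2=h2 if mediated else 0.0,
            beta0=beta0,
            beta1=beta1,
            sigma2_E=sigma2_E,
            mediated=mediated,
        )


def coded_genotype_variance(coding: Coding, genotype_freqs: np.ndarray) -> float:
    """Variance of the coded genotype over a genotype distribution."""
    p = np.asarray(genotype_freqs, dtype=float)
    c = np.asarray(CODINGS[coding], dtype=float)
    mean = float(p @ c)
    return float(p @ c**2) - mean**2


def effect_from_heritability(
    h2: float,
    coding: Coding,
    genotype_freqs: np.ndarray,
    total_variance: float = 1.0,
) -> tuple[float, float]:
    """Solve for (beta1, sigma2_E) so the locus explains h2 of the trait variance.

    ``Var(beta1 * code(G)) = h2 * total_variance`` and
    ``sigma2_E = (1 - h2) * total_variance``.  For additive coding under
    Hardy-Weinberg this is the classical additive variance 2 m1 m2 a^2 with
    no dominance deviation (k = 0).
    """
    if not (0 <= h2 < 1):
        raise ValueError("h2 must lie in [0, 1)")
    if h2 == 0:
        return 0.0, total_variance
    var_code = coded_genotype_variance(coding, genotype_freqs)
    if var_code <= 0:
        raise ValueError("degenerate genotype distribution: coded variance is 0")
    beta1 = float(np.sqrt(h2 * total_variance / var_code))
    return beta1, (1 - h2) * total_variance


def simulate_trait(g: np.ndarray, tm: TraitModel, rng) -> np.ndarray:
    """Quantitative trait: beta0 + beta1 * code(g) + Gaussian noise."""
    rng = _as_rng(rng)
    mean = tm.beta0 + tm.beta1 * code_genotypes(g, tm.coding)
    return mean + rng.normal(0.0, np.sqrt(tm.sigma2_E), size=len(mean))


# ---------------------------------------------------------------------------
# disease model and calibration


@dataclass(frozen=True)
class DiseaseModel:
    """Logistic penetrance on the coded genotype and the quantitative trait."""

    gamma0: float
    gamma1: float
    gamma2: float
    coding: Coding = "additive"

    def odds_ratios(self) -> tuple[float, float]:
        """Direct-path odds ratios (heterozygous, homozygous) implied by gamma1."""
        c = CODINGS[self.coding]
        return float(np.exp(self.gamma1 * c[1])), float(np.exp(self.gamma1 * c[2]))

    def penetrance(self, g: np.ndarray, y: np.ndarray) -> np.ndarray:
        return expit(
            self.gamma0 + self.gamma1 * code_genotypes(g, self.coding) + self.gamma2 * y
        )


def simulate_disease(g_disease: np.ndarray, y: np.ndarray, dm: DiseaseModel, rng) -> np.ndarray:
    """Bernoulli disease status from the logistic penetrance."""
    if len(g_disease) != len(y):
        raise ValueError("genotype and trait arrays must be aligned")
    rng = _as_rng(rng)
    p = dm.penetrance(np.asarray(g_disease), np.asarray(y))
    return (rng.random(len(p)) < p).astype(np.int8)


def expected_incidence(
    dm: DiseaseModel, tm: TraitModel, genotype_freqs: np.ndarray, n_nodes: int = _GH_NODES
) -> float:
    """Marginal disease probability under the genotype mixture and Gaussian trait.

    The trait integral is done with Gauss-Hermite quadrature; the genotype
    sum is exact.
    """
    nodes, weights = roots_hermite(n_nodes)
    sd = np.sqrt(tm.sigma2_E)
    codes = np.asarray(CODINGS[dm.coding], dtype=float)
    trait_codes = np.asarray(CODINGS[tm.coding], dtype=float)
    # trait mean depends on genotype through beta1 * code(g)
    mu = tm.beta0 + tm.beta1 * trait_codes  # (3,)
    y = mu[:, None] + np.sqrt(2.0) * sd * nodes[None, :]  # (3, n_nodes)
    lin = dm.gamma0 + dm.gamma1 * codes[:, None] + dm.gamma2 * y
    per_g = expit(lin) @ weights / np.sqrt(np.pi)
    return float(np.asarray(genotype_freqs) @ per_g)


def calibrate_gamma0(
    dm: DiseaseModel,
    tm: TraitModel,
    genotype_freqs: np.ndarray,
    target_incidence: float,
    tol: float = 1e-10,
) -> float:
    """Find the intercept gamma0 giving the target marginal incidence.

    Incidence is monotone increasing in gamma0, so a bracketed Brent search
    on [-20, 20] converges; the input model's gamma0 is ignored.
    """
    if not (0 < target_incidence < 1):
        raise ValueError("target incidence must lie in (0, 1)")

    def f(g0: float) -> float:
        return (
            expected_incidence(
                DiseaseModel(g0, dm.gamma1, dm.gamma2, dm.coding), tm, genotype_freqs
            )
            - target_incidence
        )

    lo, hi = -20.0, 20.0
    flo, fhi = f(lo), f(hi)
    if flo > 0 or fhi < 0:
        raise RuntimeError(
            f"cannot bracket gamma0 in [-20, 20]: f({lo})={flo:.3g}, f({hi})={fhi:.3g}"
        )
    return float(brentq(f, lo, hi, xtol=tol))


def calibrate_gamma2(
    gamma0: float,
    gamma1: float,
    tm: TraitModel,
    genotype_freqs: np.ndarray,
    target_incidence: float,
    coding: Coding = "additive",
    tol: float = 1e-10,
) -> float:
    """Find gamma2 >= 0 giving the target incidence at a fixed intercept.

    Requires the incidence at gamma2 = 0 to be below the target: spreading
    the linear predictor with a (near) zero-mean trait then raises the
    marginal incidence monotonically up to 1/2, so a unique root exists for
    any target below that.
    """
    if not (0 < target_incidence < 1):
        raise ValueError("target incidence must lie in (0, 1)")

    def f(g2: float) -> float:
        return (
            expected_incidence(
                DiseaseModel(gamma0, gamma1, g2, coding), tm, genotype_freqs
            )
            - target_incidence
        )

    f0 = f(0.0)
    if abs(f0) < tol:
        return 0.0
    if f0 > 0:
        raise ValueError(
            f"incidence at gamma2=0 is {f0 + target_incidence:.4f}, already above "
            f"the target {target_incidence}; gamma2 cannot lower it"
        )
    hi = 1.0
    while f(hi) < 0:
        hi *= 2.0
        if hi > 1e4:
            raise RuntimeError("target incidence unreachable by raising gamma2")
    return float(brentq(f, 0.0, hi, xtol=tol))


# ---------------------------------------------------------------------------
# cohorts and scenarios


@dataclass
class PopulationCohort:
    """Unascertained individuals: genotypes at both loci, trait, status."""

    g_disease: np.ndarray
    g_marker: np.ndarray
    y: np.ndarray
    d: np.ndarray

    def __len__(self) -> int:
        return len(self.d)


@dataclass
class CaseControlCohort(PopulationCohort):
    n_cases: int = 0
    n_controls: int = 0


# Logistic parameters (gamma0, gamma1) for the simulated susceptibility loci,
# by (risk level, genetic model, disease model).  Disease model 1: the trait
# and the locus are independently associated with disease; disease model 3:
# the trait additionally mediates part of the locus effect.
SCENARIO_PARAMS: dict[tuple[str, str, int], tuple[float, float]] = {
    ("medium", "additive", 1): (-3.36, np.log(1.20)),
    ("medium", "additive", 3): (-3.10, np.log(1.15)),
    ("medium", "dominant", 1): (-3.36, np.log(1.14)),
    ("medium", "dominant", 3): (-3.16, np.log(1.07)),
    ("medium", "recessive", 1): (-3.13, np.log(1.14)),
    ("medium", "recessive", 3): (-3.04, np.log(1.07)),
    ("low", "additive", 1): (-3.16, np.log(1.10)),
    ("low", "additive", 3): (-3.05, np.log(1.05)),
    ("low", "dominant", 1): (-3.18, np.log(1.08)),
    ("low", "dominant", 3): (-3.07, np.log(1.04)),
    ("low", "recessive", 1): (-3.05, np.log(1.08)),
    ("low", "recessive", 3): (-3.00, np.log(1.04)),
}

#: default case (= control) counts by (risk, coding)
SAMPLE_SIZES: dict[tuple[str, str], int] = {
    ("medium", "additive"): 2000,
    ("medium", "dominant"): 2000,
    ("medium", "recessive"): 6000,
    ("low", "additive"): 4000,
    ("low", "dominant"): 4000,
    ("low", "recessive"): 8000,
}

DEFAULT_MAF = 0.3
DEFAULT_INCIDENCE = 0.05


@dataclass(frozen=True)
class Scenario:
    """One fully-specified simulation condition."""

    ld: LDSpec
    trait: TraitModel
    disease: DiseaseModel
    n_cases: int
    n_controls: int
    risk: str = "medium"
    disease_model: int = 3
    incidence: float = DEFAULT_INCIDENCE

    @property
    def key(self) -> str:
        """Stable identifier used for order-invariant seeding and caching."""
        return (
            f"{self.risk}-{self.disease.coding}-m{self.disease_model}"
            f"-r{self.ld.r:g}-h2{self.trait.h2:g}"
            f"-n{self.n_cases}+{self.n_controls}"
        )


@lru_cache(maxsize=256)
def _cached_gamma2(
    gamma0: float,
    gamma1: float,
    coding: str,
    h2: float,
    mediated: bool,
    q1: float,
    incidence: float,
) -> tuple[float, TraitModel]:
    freqs = hwe_genotype_freqs(q1)
    tm = TraitModel.from_heritability(h2, coding, freqs, mediated=mediated)
    g2 = calibrate_gamma2(gamma0, gamma1, tm, freqs, incidence, coding=coding)
    return g2, tm


def build_scenario(
    risk: str = "medium",
    coding: Coding = "additive",
    disease_model: int = 3,
    r: float = 0.8,
    h2: float = 0.010,
    m1: float = DEFAULT_MAF,
    q1: float = DEFAULT_MAF,
    incidence: float = DEFAULT_INCIDENCE,
    n_cases: int | None = None,
    n_controls: int | None = None,
    gamma2: float | None = None,
) -> Scenario:
    """Assemble a Scenario from the default parameter table.

    The table fixes (gamma0, gamma1) per risk level, genetic model and
    disease model; gamma2 is calibrated by quadrature so the marginal
    incidence hits the target (or supplied explicitly, in which case gamma0
    is recalibrated instead).  Disease model 1 severs the genotype->trait
    path; model 2 (pure mediation) sets gamma1 = 0 and is available via
    ``disease_model=2`` with the model-3 intercept.
    """
    if disease_model == 2:
        gamma0_t, _ = SCENARIO_PARAMS[(risk, coding, 3)]
        gamma1 = 0.0
    else:
        gamma0_t, gamma1 = SCENARIO_PARAMS[(risk, coding, disease_model)]
    mediated = disease_model in (2, 3)
    freqs = hwe_genotype_freqs(q1)
    if gamma2 is None:
        g2, tm = _cached_gamma2(
            gamma0_t, gamma1, coding, h2, mediated, q1, incidence
        )
        dm = DiseaseModel(gamma0_t, gamma1, g2, coding)
    else:
        tm = TraitModel.from_heritability(h2, coding, freqs, mediated=mediated)
        g0 = calibrate_gamma0(
            DiseaseModel(0.0, gamma1, gamma2, coding), tm, freqs, incidence
        )
        dm = DiseaseModel(g0, gamma1, gamma2, coding)
    n_default = SAMPLE_SIZES[(risk, coding)]
    return Scenario(
        ld=LDSpec(m1, q1, r),
        trait=tm,
        disease=dm,
        n_cases=n_cases if n_cases is not None else n_default,
        n_controls=n_controls if n_controls is not None else n_default,
        risk=risk,
        disease_model=disease_model,
        incidence=incidence,
    )


def simulate_population(scenario: Scenario, n: int, rng) -> PopulationCohort:
    """Draw n unascertained individuals from the scenario's generative model."""
    rng = _as_rng(rng)
    rng_g, rng_y, rng_d = rng.spawn(3)
    g_dis, g_mark = sample_joint_genotypes(scenario.ld, n, rng_g)
    y = simulate_trait(g_dis, scenario.trait, rng_y)
    d = simulate_disease(g_dis, y, scenario.disease, rng_d)
    return PopulationCohort(g_dis, g_mark, y, d)


def ascertain_case_control(
    scenario: Scenario,
    n_cases: int | None = None,
    n_controls: int | None = None,
    rng=None,
    max_draw_factor: float = 1e4,
) -> CaseControlCohort:
    """Rejection-sample a population until the case/control quota is filled.

    Individuals are generated in batches sized from the expected prevalence;
    a safety cap of ``max_draw_factor * (n_cases + n_controls)`` population
    draws guards against miscalibrated scenarios.
    """
    n_cases = n_cases if n_cases is not None else scenario.n_cases
    n_controls = n_controls if n_controls is not None else scenario.n_controls
    if n_cases <= 0 or n_controls <= 0:
        raise ValueError("case and control counts must be positive")
    rng = _as_rng(rng)
    prev = scenario.incidence
    cap = max_draw_factor * (n_cases + n_controls)

    parts: list[PopulationCohort] = []
    got_cases = got_controls = 0
    drawn = 0
    while got_cases < n_cases or got_controls < n_controls:
        need = max(
            (n_cases - got_cases) / prev, (n_controls - got_controls) / (1 - prev)
        )
        batch_n = int(np.ceil(need * 1.1)) + 16
        if drawn + batch_n > cap:
            raise RuntimeError(
                f"population draw cap exceeded ({cap:.0f}); incidence likely "
                "miscalibrated for this scenario"
            )
        pop = simulate_population(scenario, batch_n, rng)
        drawn += batch_n
        is_case = pop.d == 1
        take_cases = np.flatnonzero(is_case)[: n_cases - got_cases]
        take_controls = np.flatnonzero(~is_case)[: n_controls - got_controls]
        keep = np.concatenate([take_cases, take_controls])
        got_cases += len(take_cases)
        got_controls += len(take_controls)
        parts.append(
            PopulationCohort(
                pop.g_disease[keep], pop.g_marker[keep], pop.y[keep], pop.d[keep]
            )
        )

    cat = {
        f: np.concatenate([getattr(p, f) for p in parts])
        for f in ("g_disease", "g_marker", "y", "d")
    }
    order = np.argsort(-cat["d"], kind="stable")  # cases first, batch order kept
    return CaseControlCohort(
        g_disease=cat["g_disease"][order],
        g_marker=cat["g_marker"][order],
        y=cat["y"][order],
        d=cat["d"][order],
        n_cases=n_cases,
        n_controls=n_controls,
    )
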