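"""Single-variant association tests and their combination.

Two component tests are computed per variant:

* test 1 — logistic regression of disease status on the genotype dosage
  (Wald statistic from the maximum-likelihood fit);
* test 2 — linear regression of the quantitative trait on dosage with
  adjustment for disease status (Wald statistic from OLS).

They are combined either with Fisher's combined probability test
(chi-square with 4 df on -2[ln p1 + ln p2]) or with a modified
inverse-variance weighted statistic: the trait-test effect is rescaled so
its standard error matches the disease test's, and the two effects are
averaged, giving S = (Z1 + Z2)/sqrt(2) at equal weights.  Unlike Fisher's
test, S is signed, so discordant effect directions cancel instead of
reinforcing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy import stats
from statsmodels.tools.sm_exceptions import (
    ConvergenceWarning,
    PerfectSeparationError,
    PerfectSeparationWarning,
)

P_FLOOR = 1e-300
#: median of the chi-square distribution with 1 df (genomic-control null median)
CHI2_1_MEDIAN = float(stats.chi2.ppf(0.5, 1))


@dataclass(frozen=True)
class RegressionResult:
    """One component test: effect estimate, SE, signed Z and two-sided p."""

    beta: float
    se: float
    z: float
    p: float
    n: int
    flag: str | None = None

    @property
    def ok(self) -> bool:
        return self.flag is None


@dataclass(frozen=True)
class CombinedResult:
    """A combined statistic: Fisher chi-square or the weighted score S."""

    method: str
    statistic: float
    p: float
    c: float | None = None
    b: float | None = None
    flag: str | None = None

    @property
    def ok(self) -> bool:
        return self.flag is None


def _flagged(n: int, flag: str) -> RegressionResult:
    return RegressionResult(np.nan, np.nan, np.nan, np.nan, n, flag=flag)


def _wald(beta: float, se: float, n: int) -> RegressionResult:
    z = beta / se
    return RegressionResult(beta, se, z, 2 * stats.norm.sf(abs(z)), n)


def logistic_assoc(d: np.ndarray, g: np.ndarray) -> RegressionResult:
    """Test 1: logistic regression of status on dosage (Wald).

    Dosages may be fractional (imputed data).  Degenerate inputs return a
    flagged result instead of raising: monomorphic genotype, a single
    outcome class, or (quasi-)complete separation of the ML fit.
    """
    d = np.asarray(d, dtype=float)
    g = np.asarray(g, dtype=float)
    n = len(d)
    if len(g) != n:
        raise ValueError("status and dosage arrays must be aligned")
    if np.ptp(g) == 0:
        return _flagged(n, "monomorphic")
    if d.min() == d.max():
        return _flagged(n, "single_class")
    X = np.column_stack([np.ones(n), g])
    try:
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            fit = sm.Logit(d, X).fit(disp=0, method="newton", maxiter=100)
        if any(issubclass(w.category, PerfectSeparationWarning) for w in caught):
            return _flagged(n, "separation")
        if not fit.mle_retvals.get("converged", False) or any(
            issubclass(w.category, ConvergenceWarning) for w in caught
        ):
            return _flagged(n, "nonconvergence")
    except (PerfectSeparationError, np.linalg.LinAlgError):
        return _flagged(n, "separation")
    beta, se = float(fit.params[1]), float(fit.bse[1])
    if not np.isfinite(se) or se > 1e3:
        return _flagged(n, "separation")
    return _wald(beta, se, n)


def linear_assoc_adjusted(
    y: np.ndarray, g: np.ndarray, d: np.ndarray
) -> RegressionResult:
    """Test 2: OLS of trait on dosage, adjusted for disease status (Wald).

    Returns the dosage coefficient.  A dosage constant within both status
    strata is collinear with the adjustment and is flagged.
    """
    y = np.asarray(y, dtype=float)
    g = np.asarray(g, dtype=float)
    d = np.asarray(d, dtype=float)
    n = len(y)
    if not (len(g) == n and len(d) == n):
        raise ValueError("trait, dosage and status arrays must be aligned")
    if not np.all(np.isfinite(y)):
        raise ValueError("trait values must be finite")
    if np.ptp(g) == 0:
        return _flagged(n, "monomorphic")
    X = np.column_stack([np.ones(n), g, d])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        return _flagged(n, "collinear")
    fit = sm.OLS(y, X).fit()
    return _wald(float(fit.params[1]), float(fit.bse[1]), n)


def fisher_combine(p1: float, p2: float, floor: float = P_FLOOR) -> CombinedResult:
    """Fisher's combined probability test on two independent p-values.

    chi2 = -2(ln p1 + ln p2), referred to a chi-square with 4 df.  P-values
    that underflow to 0 are clipped at ``floor`` with a warning.
    """
    for p in (p1, p2):
        if not (0 <= p <= 1):
            raise ValueError(f"p-values must lie in [0, 1], got {p}")
    if p1 == 0 or p2 == 0:
        warnings.warn(
            f"p-value of 0 clipped to {floor} before taking logs", RuntimeWarning
        )
    p1, p2 = max(p1, floor), max(p2, floor)
    chi2 = -2.0 * (np.log(p1) + np.log(p2))
    return CombinedResult("fisher", float(chi2), float(stats.chi2.sf(chi2, 4)))


def ivw_combine(
    r1: RegressionResult,
    r2: RegressionResult,
    b: float = 0.5,
    direction: str = "positive",
) -> CombinedResult:
    """Modified inverse-variance weighted combination of the two tests.

    The trait-test effect is multiplied by ``c = se1/se2`` — equivalent to
    rescaling the raw trait — so both effects share the variance se1^2.  The
    weighted sum ``L = b*beta1 + (1-b)*c*beta2`` then has variance
    ``(b^2 + (1-b)^2) * se1^2``, minimized at b = 1/2 where
    ``S = L/sd(L) = (z1 + z2)/sqrt(2)``.  ``direction="negative"`` flips the
    trait-test sign for traits negatively related to disease.
    """
    if not (0 < b < 1):
        raise ValueError("weight b must lie strictly in (0, 1)")
    if direction not in ("positive", "negative"):
        raise ValueError("direction must be 'positive' or 'negative'")
    if not (r1.ok and r2.ok):
        flag = r1.flag or r2.flag
        return CombinedResult("ivw", np.nan, np.nan, flag=flag)
    sign = 1.0 if direction == "positive" else -1.0
    c = r1.se / r2.se
    L = b * r1.beta + (1 - b) * c * (sign * r2.beta)
    S = L / np.sqrt((b**2 + (1 - b) ** 2) * r1.se**2)
    return CombinedResult(
        "ivw", float(S), float(2 * stats.norm.sf(abs(S))), c=float(c), b=b
    )


def genomic_inflation(pvals: np.ndarray) -> float:
    """Genomic-control inflation factor lambda.

    Each p-value is converted to its 1-df chi-square quantile; lambda is the
    median of those statistics divided by the null median 0.4549.
    """
    p = np.asarray(pvals, dtype=float)
    p = p[np.isfinite(p)]
    if p.size == 0:
        raise ValueError("no p-values supplied")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    chi2 = stats.chi2.isf(p, 1)
    return float(np.median(chi2) / CHI2_1_MEDIAN)
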