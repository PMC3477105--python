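"""Monte-Carlo power and type-I-error engine over the scenario grid.

Each replicate ascertains a fresh case-control cohort, applies the four
tests to the marker genotype, and records the replicate-level statistics.
Rejection proportions at a nominal level are then tabulated per test with
binomial standard errors.  Seeding is derived from the master seed and a
stable per-scenario key, so results are invariant to the order in which
scenarios are run.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .assoc import fisher_combine, ivw_combine, linear_assoc_adjusted, logistic_assoc
from .simulate import Scenario, ascertain_case_control, build_scenario

TESTS = ("logistic", "linear", "fisher", "ivw")

POWER_TABLE_COLUMNS = [
    "risk", "model", "coding", "r", "h2", "test",
    "n_cases", "n_controls", "replicates", "rejections", "power", "se",
]


@dataclass(frozen=True)
class ScenarioGrid:
    """Cartesian grid of simulation conditions for a power study."""

    risks: tuple[str, ...] = ("medium",)
    codings: tuple[str, ...] = ("additive",)
    disease_models: tuple[int, ...] = (1, 3)
    r_values: tuple[float, ...] = (0.0, 0.2, 0.4, 0.6, 0.8)
    h2_values: tuple[float, ...] = (0.002, 0.004, 0.006, 0.008, 0.010)
    replicates: int = 1000
    alpha: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must lie in (0, 1)")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ScenarioGrid":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        seq = lambda v: tuple(v) if isinstance(v, (list, tuple)) else (v,)
        kwargs = {}
        for yaml_key, attr in [
            ("risks", "risks"), ("codings", "codings"),
            ("disease_models", "disease_models"),
            ("r", "r_values"), ("h2", "h2_values"),
        ]:
            if yaml_key in raw:
                kwargs[attr] = seq(raw[yaml_key])
        for key in ("replicates", "alpha", "seed"):
            if key in raw:
                kwargs[key] = raw[key]
        return cls(**kwargs)

    def scenarios(self) -> list[Scenario]:
        out = []
        for risk in self.risks:
            for coding in self.codings:
                for model in self.disease_models:
                    for r in self.r_values:
                        # model 1 has no genotype->trait path: h2 is inert,
                        # so it contributes a single scenario per r
                        h2s = self.h2_values if model != 1 else (self.h2_values[0],)
                        for h2 in h2s:
                            out.append(
                                build_scenario(
                                    risk=risk, coding=coding, disease_model=model,
                                    r=r, h2=h2,
                                )
                            )
        return out


def scenario_seed(master_seed: int, scenario: Scenario) -> np.random.SeedSequence:
    """Seed sequence derived from the master seed and the scenario identity."""
    return np.random.SeedSequence([master_seed, zlib.crc32(scenario.key.encode())])


def simulate_test_statistics(
    scenario: Scenario, replicates: int, seed: int
) -> pd.DataFrame:
    """Per-replicate statistics of the four tests under one scenario.

    Returns one row per replicate with columns z1, p1 (logistic on the
    marker), z2, p2 (trait regression adjusted for status), fisher_chi2,
    p_fisher, s, p_ivw, and ok flags per component fit.
    """
    children = scenario_seed(seed, scenario).spawn(replicates)
    rows = np.empty((replicates, 8))
    ok = np.empty((replicates, 2), dtype=bool)
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        cohort = ascertain_case_control(scenario, rng=rng)
        r1 = logistic_assoc(cohort.d, cohort.g_marker)
        r2 = linear_assoc_adjusted(cohort.y, cohort.g_marker, cohort.d)
        if r1.ok and r2.ok:
            fisher = fisher_combine(r1.p, r2.p)
            ivw = ivw_combine(r1, r2)
            rows[i] = (r1.z, r1.p, r2.z, r2.p, fisher.statistic, fisher.p,
                       ivw.statistic, ivw.p)
        else:
            rows[i] = np.nan
            rows[i, 0:2] = (r1.z, r1.p)
            rows[i, 2:4] = (r2.z, r2.p)
        ok[i] = (r1.ok, r2.ok)
    df = pd.DataFrame(
        rows,
        columns=["z1", "p1", "z2", "p2", "fisher_chi2", "p_fisher", "s", "p_ivw"],
    )
    df["ok1"], df["ok2"] = ok[:, 0], ok[:, 1]
    return df


def run_scenario(
    scenario: Scenario,
    replicates: int = 1000,
    alpha: float = 0.01,
    seed: int = 0,
    failure_ceiling: float = 0.01,
    stats: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Empirical rejection proportions of the four tests for one scenario.

    A rejection is a two-sided p-value below alpha.  Replicates with flagged
    component fits are dropped from the affected denominators; if more than
    ``failure_ceiling`` of replicates fail, the scenario errors out.
    """
    if stats is None:
        stats = simulate_test_statistics(scenario, replicates, seed)
    pcols = {"logistic": "p1", "linear": "p2", "fisher": "p_fisher", "ivw": "p_ivw"}
    records = []
    for test, col in pcols.items():
        p = stats[col].to_numpy()
        valid = np.isfinite(p)
        n_valid = int(valid.sum())
        if n_valid < (1 - failure_ceiling) * len(stats):
            raise RuntimeError(
                f"{scenario.key}: {len(stats) - n_valid} of {len(stats)} replicates "
                f"failed for test '{test}' (ceiling {failure_ceiling:.0%})"
            )
        k = int((p[valid] < alpha).sum())
        power = k / n_valid
        records.append({
            "risk": scenario.risk,
            "model": scenario.disease_model,
            "coding": scenario.disease.coding,
            "r": scenario.ld.r,
            "h2": scenario.trait.h2,
            "test": test,
            "n_cases": scenario.n_cases,
            "n_controls": scenario.n_controls,
            "replicates": n_valid,
            "rejections": k,
            "power": power,
            "se": float(np.sqrt(power * (1 - power) / n_valid)),
        })
    return pd.DataFrame.from_records(records, columns=POWER_TABLE_COLUMNS)


def run_grid(
    grid: ScenarioGrid,
    cache_dir: str | Path | None = None,
    progress: bool = False,
) -> pd.DataFrame:
    """Run every scenario in the grid and concatenate the power tables.

    With ``cache_dir`` set, per-scenario tables are written as TSV keyed by
    scenario and grid settings, and re-runs resume from the cache.  Results
    do not depend on scenario execution order.
    """
    tables = []
    scenarios = grid.scenarios()
    for i, sc in enumerate(scenarios):
        cache_path = None
        if cache_dir is not None:
            cache_path = Path(cache_dir) / (
                f"{sc.key}-rep{grid.replicates}-a{grid.alpha:g}-s{grid.seed}.tsv"
            )
            if cache_path.exists():
                tables.append(pd.read_csv(cache_path, sep="\t"))
                continue
        if progress:
            print(f"[{i + 1}/{len(scenarios)}] {sc.key}", flush=True)
        tab = run_scenario(sc, grid.replicates, grid.alpha, grid.seed)
        if cache_path is not None:
            cache_path.parent.mkdir(parents=True, exist_ok=True)
            tab.to_csv(cache_path, sep="\t", index=False)
        tables.append(tab)
    return pd.concat(tables, ignore_index=True)
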