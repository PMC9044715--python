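"""Simulation study: type-I error and power of the uniformity tests.

Two suites.  The *uniformity suite* draws i.i.d. samples from a circular
distribution (uniform, unimodal, bimodal, trimodal; optionally aggregated
into 10-degree bins) and records, per sample size, the proportion of
replicates each test rejects at alpha — the type-I error when the
generator is uniform, the power otherwise.  The *hypothetical suite*
emulates a displacement study of an animal population with two groups
observed at ages 1..5: within each group-by-age cell, headings are von
Mises with the group's mean direction and a concentration that grows
linearly with age; the MANOVA (intercept + age + group) is scored per
term, with Rayleigh and Hermans–Rasson run on the pooled headings for the
intercept comparison.

Monte-Carlo nulls (the HR reference distribution and the calibrated
MANOVA's null p-values) depend only on the sample size and the fixed
design, so they are computed once per configuration and shared across
replicates, which keeps the 9999-replicate suites tractable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import TWO_PI, AngleSample, bin_angles
from .distributions import MixtureSpec, as_rng, sample_mixture
from .manova import (
    ModelSpec,
    batch_term_pvalues,
    build_design,
    intercept_theory_p_batch,
    null_term_pvalues,
)
from .uniformity import (
    hermans_rasson_batch,
    hermans_rasson_null_stats,
    rayleigh_p_from_z,
    rayleigh_z_batch,
)

UNIFORMITY_TESTS = ("rayleigh", "hr", "manova", "manova_mc")


@dataclass(frozen=True)
class Scenario:
    """One simulation scenario of the uniformity suite."""

    name: str
    generator: MixtureSpec
    sample_sizes: tuple[int, ...]
    binned: bool = False
    replicates: int = 9999
    alpha: float = 0.05
    bin_width: float = 10.0

    def __post_init__(self) -> None:
        sizes = tuple(int(n) for n in self.sample_sizes)
        if not sizes or any(n < 1 for n in sizes):
            raise ValueError("sample sizes must be positive")
        if any(b <= a for a, b in zip(sizes, sizes[1:])):
            raise ValueError("sample sizes must be increasing")
        object.__setattr__(self, "sample_sizes", sizes)


@dataclass(frozen=True)
class HypotheticalDesign:
    """Two groups observed at ages 1..5 with age-dependent clustering.

    kappa rises linearly over the five ages from kappa_start to kappa_end
    (per group); each group has a fixed mean direction.  Cells are equally
    allocated: n_total/10 subjects per group-by-age combination.
    """

    group_means: tuple[float, float] = (0.0, 0.0)  # radians
    kappa_schedules: tuple[tuple[float, float], ...] = ((0.0, 2.0), (0.0, 2.0))
    ages: tuple[int, ...] = (1, 2, 3, 4, 5)

    def __post_init__(self) -> None:
        if len(self.group_means) != len(self.kappa_schedules):
            raise ValueError("one kappa schedule per group required")
        for start, end in self.kappa_schedules:
            if start < 0 or end < 0:
                raise ValueError("kappa must be >= 0 everywhere")

    def kappa(self, group: int, age: int) -> float:
        start, end = self.kappa_schedules[group]
        span = len(self.ages) - 1
        return start + (end - start) * (age - self.ages[0]) / span


@dataclass(frozen=True)
class RejectionRateResult:
    """Estimated rejection proportion of one test (term) at one sample size."""

    scenario: str
    test: str
    term: str
    n: int
    replicates: int
    rate: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.rate <= 1.0):
            raise ValueError("rate outside [0, 1]")


def _draw_iid_matrix(spec: MixtureSpec, replicates: int, n: int, rng) -> np.ndarray:
    """(replicates, n) i.i.d. draws; i.i.d.-ness lets one flat draw serve all."""
    flat = sample_mixture(spec, replicates * n, rng)
    return flat.angles.reshape(replicates, n)


def _bin_matrix(theta: np.ndarray, width: float) -> np.ndarray:
    deg = np.rad2deg(theta)
    centers = np.mod(np.floor(deg / width + 0.5) * width, 360.0)
    return np.mod(np.deg2rad(centers), TWO_PI)


def _mc_rank_lower(observed: np.ndarray, nulls_sorted: np.ndarray) -> np.ndarray:
    """(1 + #{null <= obs}) / (B + 1) vectorised over observations."""
    count = np.searchsorted(nulls_sorted, observed, side="right")
    return (1.0 + count) / (nulls_sorted.size + 1.0)


def _mc_rank_upper(observed: np.ndarray, nulls_sorted: np.ndarray) -> np.ndarray:
    """(1 + #{null >= obs}) / (B + 1) vectorised over observations."""
    count = nulls_sorted.size - np.searchsorted(nulls_sorted, observed, side="left")
    return (1.0 + count) / (nulls_sorted.size + 1.0)


def run_uniformity_suite(
    scenario: Scenario,
    tests=UNIFORMITY_TESTS,
    rng=None,
    hr_null_B: int = 9999,
    mc_B: int = 999,
    hr_chunk: int = 128,
) -> list[RejectionRateResult]:
    """Rejection rate of each test at each sample size of a scenario.

    Monte-Carlo reference distributions (continuous-uniform, per the
    calibration's stated null — deliberately *not* binned even when the
    observed data are, which is what exposes the HR test's sensitivity to
    binning) are shared across replicates at a given n.
    """
    gen = as_rng(rng)
    results: list[RejectionRateResult] = []
    for n in scenario.sample_sizes:
        theta = _draw_iid_matrix(scenario.generator, scenario.replicates, n, gen)
        if scenario.binned:
            theta = _bin_matrix(theta, scenario.bin_width)
        if "rayleigh" in tests:
            p = rayleigh_p_from_z(rayleigh_z_batch(theta), n)
            results.append(
                RejectionRateResult(
                    scenario.name, "rayleigh", "uniformity", n,
                    scenario.replicates, float(np.mean(p < scenario.alpha)),
                )
            )
        if "manova" in tests or "manova_mc" in tests:
            p_theory = intercept_theory_p_batch(theta)
            if "manova" in tests:
                results.append(
                    RejectionRateResult(
                        scenario.name, "manova", "intercept", n,
                        scenario.replicates,
                        float(np.mean(p_theory < scenario.alpha)),
                    )
                )
            if "manova_mc" in tests:
                null_theta = gen.uniform(0.0, TWO_PI, size=(mc_B, n))
                null_p = np.sort(intercept_theory_p_batch(null_theta))
                p_mc = _mc_rank_lower(p_theory, null_p)
                results.append(
                    RejectionRateResult(
                        scenario.name, "manova_mc", "intercept", n,
                        scenario.replicates,
                        float(np.mean(p_mc < scenario.alpha)),
                    )
                )
        if "hr" in tests:
            nulls = np.sort(hermans_rasson_null_stats(n, hr_null_B, gen))
            stats_obs = np.empty(scenario.replicates)
            for start in range(0, scenario.replicates, hr_chunk):
                block = theta[start : start + hr_chunk]
                stats_obs[start : start + block.shape[0]] = hermans_rasson_batch(
                    block
                )
            p_hr = _mc_rank_upper(stats_obs, nulls)
            results.append(
                RejectionRateResult(
                    scenario.name, "hr", "uniformity", n,
                    scenario.replicates, float(np.mean(p_hr < scenario.alpha)),
                )
            )
    return results


def hypothetical_table(design: HypotheticalDesign, n_total: int) -> pd.DataFrame:
    """Fixed covariate table of the hypothetical study (group x age cells)."""
    n_cells = len(design.group_means) * len(design.ages)
    if n_total % n_cells:
        raise ValueError(f"n_total={n_total} not divisible by {n_cells} cells")
    per_cell = n_total // n_cells
    rows = [
        {"group": f"g{g + 1}", "age": age}
        for g in range(len(design.group_means))
        for age in design.ages
        for _ in range(per_cell)
    ]
    return pd.DataFrame(rows)


def simulate_hypothetical(
    design: HypotheticalDesign, n_total: int, replicates: int, rng
) -> np.ndarray:
    """(replicates, n_total) headings matching :func:`hypothetical_table` rows."""
    gen = as_rng(rng)
    n_cells = len(design.group_means) * len(design.ages)
    per_cell = n_total // n_cells
    out = np.empty((replicates, n_total))
    col = 0
    for g, mu in enumerate(design.group_means):
        for age in design.ages:
            kappa = design.kappa(g, age)
            draws = gen.vonmises(mu, kappa, size=(replicates, per_cell))
            out[:, col : col + per_cell] = np.mod(draws, TWO_PI)
            col += per_cell
    return out


def run_hypothetical_suite(
    design: HypotheticalDesign,
    n_totals,
    replicates: int = 9999,
    rng=None,
    alpha: float = 0.05,
    mc_B: int = 999,
    hr_null_B: int = 9999,
    include_hr: bool = True,
    scenario_name: str = "hypothetical",
    hr_chunk: int = 128,
) -> list[RejectionRateResult]:
    """Per-term MANOVA rejection rates plus pooled Rayleigh/HR comparisons."""
    gen = as_rng(rng)
    results: list[RejectionRateResult] = []
    for n_total in n_totals:
        table = hypothetical_table(design, n_total)
        spec = ModelSpec.from_term_names(["age", "group"], table)
        X, blocks, labels = build_design(table, spec)
        df_error = n_total - X.shape[1]
        Q, _ = np.linalg.qr(X)
        theta = simulate_hypothetical(design, n_total, replicates, gen)
        p_terms = batch_term_pvalues(Q, blocks, theta, df_error)
        term_names = ("intercept", "age", "group")
        for t, term in enumerate(term_names):
            results.append(
                RejectionRateResult(
                    scenario_name, "manova", term, n_total, replicates,
                    float(np.mean(p_terms[:, t] < alpha)),
                )
            )
        null_p = null_term_pvalues(X, blocks, mc_B, gen)
        for t, term in enumerate(term_names):
            p_mc = _mc_rank_lower(p_terms[:, t], np.sort(null_p[:, t]))
            results.append(
                RejectionRateResult(
                    scenario_name, "manova_mc", term, n_total, replicates,
                    float(np.mean(p_mc < alpha)),
                )
            )
        p_ray = rayleigh_p_from_z(rayleigh_z_batch(theta), n_total)
        results.append(
            RejectionRateResult(
                scenario_name, "rayleigh", "uniformity", n_total, replicates,
                float(np.mean(p_ray < alpha)),
            )
        )
        if include_hr:
            nulls = np.sort(hermans_rasson_null_stats(n_total, hr_null_B, gen))
            stats_obs = np.empty(replicates)
            for start in range(0, replicates, hr_chunk):
                block = theta[start : start + hr_chunk]
                stats_obs[start : start + block.shape[0]] = hermans_rasson_batch(
                    block
                )
            p_hr = _mc_rank_upper(stats_obs, nulls)
            results.append(
                RejectionRateResult(
                    scenario_name, "hr", "uniformity", n_total, replicates,
                    float(np.mean(p_hr < alpha)),
                )
            )
    return results


def summarize_suite(results) -> pd.DataFrame:
    """Tidy rate table keyed by (scenario, test, term, n) with 95% binomial CIs."""
    if not results:
        return pd.DataFrame(
            columns=[
                "scenario", "test", "term", "n", "replicates",
                "rate", "se", "ci_low", "ci_high",
            ]
        )
    df = pd.DataFrame(
        {
            "scenario": [r.scenario for r in results],
            "test": [r.test for r in results],
            "term": [r.term for r in results],
            "n": [r.n for r in results],
            "replicates": [r.replicates for r in results],
            "rate": [r.rate for r in results],
        }
    )
    se = np.sqrt(df["rate"] * (1.0 - df["rate"]) / df["replicates"])
    df["se"] = se
    df["ci_low"] = np.clip(df["rate"] - 1.96 * se, 0.0, 1.0)
    df["ci_high"] = np.clip(df["rate"] + 1.96 * se, 0.0, 1.0)
    return df.sort_values(["scenario", "test", "term", "n"]).reset_index(drop=True)


# canonical scenario generators of the simulation study ----------------------


def standard_scenarios(replicates: int = 9999) -> dict[str, Scenario]:
    """The distribution suites of the power study, with their sample-size grids."""
    uniform = MixtureSpec(
        (dict(family="uniform", params={}, weight=1.0),)
    )
    vm = MixtureSpec(
        (dict(family="vonmises", params={"mu": 0.0, "kappa": 1.0}, weight=1.0),)
    )
    wsn = MixtureSpec(
        (
            dict(
                family="wrappedskewnormal",
                params={"xi": 0.0, "omega": 2.0, "alpha": 30.0},
                weight=1.0,
            ),
        )
    )
    small_grid = (5, 10, 15, 25, 50, 100)
    return {
        "uniform": Scenario("uniform", uniform, small_grid, replicates=replicates),
        "uniform_binned": Scenario(
            "uniform_binned", uniform, (10, 15, 25, 50, 100),
            binned=True, replicates=replicates,
        ),
        "vm_unimodal": Scenario("vm_unimodal", vm, small_grid, replicates=replicates),
        "wsn_unimodal": Scenario("wsn_unimodal", wsn, small_grid, replicates=replicates),
        "bimodal_symmetric": Scenario(
            "bimodal_symmetric",
            MixtureSpec.vonmises_modes([0.0, 180.0], 1.0),
            (10, 20, 30, 50, 100, 200), replicates=replicates,
        ),
        "bimodal_asymmetric": Scenario(
            "bimodal_asymmetric",
            MixtureSpec.vonmises_modes([0.0, 240.0], 1.0),
            (10, 20, 30, 50, 100, 200), replicates=replicates,
        ),
        "trimodal_symmetric": Scenario(
            "trimodal_symmetric",
            MixtureSpec.vonmises_modes([0.0, 120.0, 240.0], 1.0),
            (15, 30, 45, 75, 150, 300), replicates=replicates,
        ),
        "trimodal_asymmetric": Scenario(
            "trimodal_asymmetric",
            MixtureSpec.vonmises_modes([0.0, 120.0, 270.0], 1.0),
            (15, 30, 45, 75, 150, 300), replicates=replicates,
        ),
    }
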