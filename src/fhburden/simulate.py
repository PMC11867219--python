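"""Monte-Carlo power and type-I-error engine for the family-history models.

Each replicate draws a cohort of n individuals by sequential binomial
sampling — sex, then case status given sex, then family history given sex and
case — from packaged cohort proportions, then draws a binary carrier variable
per phenotype cell from the logistic model

    logit P(G=1) = alpha + b1*Case + b2*FH + b3*Sex,
    b1 = log(OR), b2 = k_generate * log(OR)

with alpha = log(0.001) (baseline aggregate carrier frequency 0.001) and
b3 = log(1.15) by default.  Models null/1/2/3 are fitted on the grouped
8-cell table — sufficient for these covariates, so a 450,000-sample replicate
costs milliseconds — and power is the proportion of likelihood-ratio p-values
below each significance level (1 df for models 1 and 3, 2 df for model 2).

Replicate randomness is counter-based: `SeedSequence(master, spawn_key=...)`
keyed by (OR index, replicate index), so replicates are reproducible in any
execution order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .cohorts import CohortProportions
from .models import CohortCells, fit_model1, fit_model2, fit_model3, fit_null, lrt

__all__ = [
    "SimulationConfig",
    "PowerEstimate",
    "generate_cohort",
    "generate_carriers",
    "estimate_power",
    "estimate_type1",
    "power_curve",
]

DEFAULT_ALPHA = math.log(0.001)
DEFAULT_BETA3 = math.log(1.15)


@dataclass(frozen=True)
class SimulationConfig:
    """Generator and analysis settings for one simulation study."""

    proportions: CohortProportions
    n: int = 450_000
    reps: int = 5000
    or_grid: tuple[float, ...] = (2.0,)
    k_generate: float = 0.5
    k_fit: float = 0.5
    alpha: float = DEFAULT_ALPHA
    beta3: float = DEFAULT_BETA3
    levels: tuple[float, ...] = (0.05, 2.5e-6)
    seed: int = 0
    models: tuple[str, ...] = ("m1", "m2", "m3")
    # The sex covariate value 1 receives beta3.  Default: male coded 1.  In a
    # carrier-status regression for a female cancer, controls of the affected
    # sex are depleted of carriers (carriers became cases), so male sex is the
    # direction with the *higher* carrier frequency; beta3 = log(1.15) on
    # males is what a CHEK2-style breast-cohort fit estimates.
    female_coded_one: bool = False

    def __post_init__(self) -> None:
        if self.n < 1 or self.reps < 1:
            raise ValueError("n and reps must be >= 1")
        if any(not 0.0 < lv < 1.0 for lv in self.levels):
            raise ValueError("significance levels must be in (0, 1)")
        bad = [m for m in self.models if m not in ("m1", "m2", "m3")]
        if bad:
            raise ValueError(f"unknown models {bad}")


@dataclass
class PowerEstimate:
    """Per-model, per-level rejection rates with Monte-Carlo uncertainty."""

    odds_ratio: float
    table: pd.DataFrame  # model, level, power, se, ci_low, ci_high, reps_used, reps_excluded
    reps: int
    seed: int

    def power(self, model: str, level: float) -> float:
        t = self.table
        row = t[(t["model"] == model) & (t["level"] == level)]
        if row.empty:
            raise KeyError(f"no power entry for model={model!r} level={level}")
        return float(row["power"].iloc[0])


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def replicate_seed(master_seed: int, *key: int) -> np.random.SeedSequence:
    """Counter-based replicate seed: (master seed, key) -> SeedSequence."""
    return np.random.SeedSequence(master_seed, spawn_key=tuple(key))


def generate_cohort(config: SimulationConfig, seed) -> CohortCells:
    """Draw the 2x2x2 phenotype cell counts for one replicate.

    Sex, case-within-sex and FH-within-(sex, case) are successive binomial
    draws, exactly the sequential scheme the cohort proportions parameterise.
    Carrier status is all zero in the returned cells (see generate_carriers).
    """
    rng = _rng(seed)
    pr = config.proportions
    n_female = rng.binomial(config.n, pr.p_female)
    n_male = config.n - n_female
    sex_of_female = 1 if config.female_coded_one else 0
    group_n = {1: n_female, 0: n_male} if sex_of_female == 1 else {0: n_female, 1: n_male}
    p_case = {sex_of_female: pr.p_case_female, 1 - sex_of_female: pr.p_case_male}
    p_fh = {
        (sex_of_female, 0): pr.p_fh_female_control,
        (sex_of_female, 1): pr.p_fh_female_case,
        (1 - sex_of_female, 0): pr.p_fh_male_control,
        (1 - sex_of_female, 1): pr.p_fh_male_case,
    }
    counts = np.zeros((2, 2, 2, 2))
    for sex in (0, 1):
        n_cases = rng.binomial(group_n[sex], p_case[sex])
        for case, n_sc in ((1, n_cases), (0, group_n[sex] - n_cases)):
            n_fh = rng.binomial(n_sc, p_fh[(sex, case)])
            counts[sex, case, 1, 0] = n_fh
            counts[sex, case, 0, 0] = n_sc - n_fh
    return CohortCells(counts)


def generate_carriers(cells: CohortCells, odds_ratio: float, k_generate: float,
                      alpha: float, beta3: float, seed) -> CohortCells:
    """Split each phenotype cell into carriers/non-carriers by binomial draws
    from logit P(G=1) = alpha + log(OR)*case + k*log(OR)*fh + beta3*sex."""
    rng = _rng(seed)
    beta1 = math.log(odds_ratio)
    beta2 = k_generate * beta1
    margins = cells.phenotype_margins()
    counts = np.zeros((2, 2, 2, 2))
    for sex in (0, 1):
        for case in (0, 1):
            for fh in (0, 1):
                n_cell = int(margins[sex, case, fh])
                eta = alpha + beta1 * case + beta2 * fh + beta3 * sex
                prob = 1.0 / (1.0 + math.exp(-eta))
                carriers = rng.binomial(n_cell, prob) if n_cell > 0 else 0
                counts[sex, case, fh, 1] = carriers
                counts[sex, case, fh, 0] = n_cell - carriers
    return CohortCells(counts)


def _replicate_pvalues(cells: CohortCells, models: tuple[str, ...],
                       k_fits: tuple[float, ...]) -> dict[str, float]:
    """LRT p-value per requested model on one replicate's cells.

    Model 3 is fitted once per k in `k_fits`, keyed "m3" for the first k and
    "m3@k" for the rest.  Raises ValueError on degenerate replicates.
    """
    null_fit = fit_null(cells)
    out: dict[str, float] = {}
    for model in models:
        if model == "m1":
            fits = [("m1", fit_model1(cells))]
        elif model == "m2":
            fits = [("m2", fit_model2(cells))]
        else:
            fits = []
            for i, k in enumerate(k_fits):
                tag = "m3" if i == 0 else f"m3@{k:g}"
                fits.append((tag, fit_model3(cells, k=k)))
        for tag, fit in fits:
            if not fit.converged or not null_fit.converged:
                raise ValueError("non-converged fit")
            if fit.separated or null_fit.separated:
                raise ValueError("separated fit")
            _, _, p = lrt(fit, null_fit)
            out[tag] = p
    return out


def _summarize(rejections: dict[str, dict[float, int]], used: dict[str, int],
               excluded: dict[str, int], reps: int) -> pd.DataFrame:
    rows = []
    for tag, by_level in rejections.items():
        for level, count in by_level.items():
            n_used = used[tag]
            power = count / n_used if n_used else math.nan
            se = math.sqrt(power * (1 - power) / n_used) if n_used >= 2 else math.nan
            if n_used:
                ci = stats.binomtest(count, n_used).proportion_ci(0.95, method="exact")
                ci_low, ci_high = ci.low, ci.high
            else:
                ci_low = ci_high = math.nan
            rows.append({"model": tag, "level": level, "power": power, "se": se,
                         "ci_low": ci_low, "ci_high": ci_high,
                         "reps_used": n_used, "reps_excluded": excluded[tag]})
    return pd.DataFrame(rows)


def _run_one_or(config: SimulationConfig, odds_ratio: float, or_index: int,
                k_fits: tuple[float, ...]) -> pd.DataFrame:
    tags: list[str] = []
    for m in config.models:
        if m == "m3":
            tags.extend("m3" if i == 0 else f"m3@{k:g}" for i, k in enumerate(k_fits))
        else:
            tags.append(m)
    rejections = {t: {lv: 0 for lv in config.levels} for t in tags}
    used = {t: 0 for t in tags}
    excluded = {t: 0 for t in tags}
    import warnings as _warnings

    for rep in range(config.reps):
        rng = _rng(replicate_seed(config.seed, or_index, rep))
        cells = generate_cohort(config, rng)
        cells = generate_carriers(cells, odds_ratio, config.k_generate,
                                  config.alpha, config.beta3, rng)
        try:
            with _warnings.catch_warnings():
                # degenerate replicates are excluded and tallied, not warned
                _warnings.simplefilter("ignore", RuntimeWarning)
                pvals = _replicate_pvalues(cells, config.models, k_fits)
        except ValueError:
            for t in tags:
                excluded[t] += 1
            continue
        for t in tags:
            used[t] += 1
            for lv in config.levels:
                if pvals[t] < lv:
                    rejections[t][lv] += 1
    return _summarize(rejections, used, excluded, config.reps)


def estimate_power(config: SimulationConfig) -> list[PowerEstimate]:
    """Monte-Carlo power per OR in the config's grid, per model and level."""
    out = []
    for j, odds_ratio in enumerate(config.or_grid):
        table = _run_one_or(config, odds_ratio, j, (config.k_fit,))
        out.append(PowerEstimate(odds_ratio=odds_ratio, table=table,
                                 reps=config.reps, seed=config.seed))
    return out


def estimate_type1(config: SimulationConfig, ci_level: float = 0.99) -> PowerEstimate:
    """Type-I error under the null (OR = 1): rejection rate per model and level,
    with an exact binomial CI and a flag for whether the nominal level lies
    inside it."""
    cfg = replace(config, or_grid=(1.0,))
    est = estimate_power(cfg)[0]
    t = est.table
    flags, lows, highs = [], [], []
    for _, row in t.iterrows():
        n_used = int(row["reps_used"])
        if n_used == 0:
            flags.append(False)
            lows.append(math.nan)
            highs.append(math.nan)
            continue
        k = round(row["power"] * n_used)
        ci = stats.binomtest(int(k), n_used).proportion_ci(ci_level, method="exact")
        lows.append(ci.low)
        highs.append(ci.high)
        flags.append(bool(ci.low <= row["level"] <= ci.high))
    est.table = t.assign(ci_low=lows, ci_high=highs, nominal_consistent=flags)
    return est


def power_curve(config: SimulationConfig, or_grid=None, k_grid=None,
                cancer: str | None = None) -> pd.DataFrame:
    """Long-format power table over an OR grid and (for model 3) a k grid.

    Simulated replicates are shared across the k values at a given OR, so
    power differences across k are paired comparisons on identical data.
    """
    ors = tuple(or_grid) if or_grid is not None else config.or_grid
    ks = tuple(k_grid) if k_grid is not None else (config.k_fit,)
    rows = []
    for j, odds_ratio in enumerate(ors):
        table = _run_one_or(config, odds_ratio, j, ks)
        for _, row in table.iterrows():
            tag = row["model"]
            if tag.startswith("m3"):
                k = float(tag.split("@")[1]) if "@" in tag else ks[0]
                model = "m3"
            else:
                k, model = math.nan, tag
            rows.append({"cancer": cancer, "or": odds_ratio, "k": k, "model": model,
                         "level": row["level"], "power": row["power"], "se": row["se"],
                         "reps_used": row["reps_used"]})
    columns = ["cancer", "or", "k", "model", "level", "power", "se", "reps_used"]
    return pd.DataFrame(rows, columns=columns)
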