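"""Closed-form effective sample sizes for family-history-aware association tests.

Three strategies for a cohort cross-classified by case status and family
history (FH) are compared on a common scale: the size of a balanced
case-control study whose score test has the same expected Z.  With N00/N01
controls without/with FH and N10/N11 cases without/with FH (N0, N1 the
margins, N the total):

* case-control only (phenotype d):            Neff1 = 2 N0 N1 / N
* FH weighted by 1/2 (phenotype d + f/2):     Neff2 = [N00 N01 + N01 N10
      + N10 N11 + 4 (N00 N10 + N01 N11) + 9 N00 N11] / (2N)
* FH-positive controls as proxy cases
  (phenotype max(d, f)):                      Neff3 = N00 (N01 + 2 N10
      + 3 N11)^2 / (2N (N01 + N10 + N11))

All three reduce to 2 N0 N1 / N when nobody reports a family history.  The
expected score-test Z under a per-allele log rate ratio beta at allele
frequency p is E(Z) = beta * sqrt(2 p (1-p)) * sqrt(Neff / 2) for every
strategy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cohorts import CohortProportions

__all__ = [
    "FourCellCounts",
    "EffectSpec",
    "neff_case_control",
    "neff_weighted_fh",
    "neff_proxy",
    "expected_z",
    "counts_from_proportions",
]


@dataclass(frozen=True)
class FourCellCounts:
    """Case x family-history margins; real-valued counts are allowed so that
    expected-count designs can be analysed directly."""

    n00: float  # controls, no FH
    n01: float  # controls, FH
    n10: float  # cases, no FH
    n11: float  # cases, FH

    def __post_init__(self) -> None:
        for name in ("n00", "n01", "n10", "n11"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name}={v} must be finite and non-negative")

    @property
    def n0(self) -> float:
        return self.n00 + self.n01

    @property
    def n1(self) -> float:
        return self.n10 + self.n11

    @property
    def n(self) -> float:
        return self.n0 + self.n1


@dataclass(frozen=True)
class EffectSpec:
    """Allele frequency p (strictly interior) and per-allele log rate ratio."""

    p: float
    beta: float

    def __post_init__(self) -> None:
        if not 0.0 < self.p < 1.0:
            raise ValueError(f"allele frequency p={self.p} must be in (0, 1)")
        if not np.isfinite(self.beta):
            raise ValueError("beta must be finite")


def neff_case_control(counts: FourCellCounts) -> float:
    """Effective n of the plain case-control test: the harmonic-mean formula
    2 N0 N1 / N (equals N when the design is balanced)."""
    if counts.n == 0 or counts.n0 == 0 or counts.n1 == 0:
        return 0.0
    return 2.0 * counts.n0 * counts.n1 / counts.n


def neff_weighted_fh(counts: FourCellCounts) -> float:
    """Effective n of the d + f/2 weighted-family-history test."""
    if counts.n == 0:
        return 0.0
    c = counts
    quad = (c.n00 * c.n01 + c.n01 * c.n10 + c.n10 * c.n11
            + 4.0 * (c.n00 * c.n10 + c.n01 * c.n11) + 9.0 * c.n00 * c.n11)
    return quad / (2.0 * c.n)


def neff_proxy(counts: FourCellCounts) -> float:
    """Effective n of the proxy-case test on max(d, f), which pools cases with
    FH-positive controls."""
    c = counts
    denom = c.n01 + c.n10 + c.n11
    if c.n == 0 or denom == 0 or c.n00 == 0:
        return 0.0
    return c.n00 * (c.n01 + 2.0 * c.n10 + 3.0 * c.n11) ** 2 / (2.0 * c.n * denom)


_NEFF = {
    "cc": neff_case_control,
    "weighted": neff_weighted_fh,
    "proxy": neff_proxy,
}


def expected_z(effect: EffectSpec, counts: FourCellCounts, method: str = "weighted") -> float:
    """Expected score-test Z under the alternative, for one strategy.

    E(Z | beta) = beta * sqrt(2 p (1 - p)) * sqrt(Neff_method / 2), so
    squaring and dividing by 2 p (1-p) beta^2 recovers Neff/2 identically.
    """
    if method not in _NEFF:
        raise ValueError(f"method must be one of {sorted(_NEFF)}, got {method!r}")
    neff = _NEFF[method](counts)
    return effect.beta * np.sqrt(2.0 * effect.p * (1.0 - effect.p)) * np.sqrt(neff / 2.0)


def counts_from_proportions(proportions: CohortProportions, n: float) -> FourCellCounts:
    """Expected case x FH cell counts for a cohort of size n, collapsing sex.

    Counts are real-valued expected counts, not rounded draws.
    """
    if n < 0:
        raise ValueError("n must be non-negative")
    cells = proportions.cell_probabilities()
    out = {"n00": 0.0, "n01": 0.0, "n10": 0.0, "n11": 0.0}
    for (sex, case, fh), prob in cells.items():
        out[f"n{case}{fh}"] += n * prob
    return FourCellCounts(**out)
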