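"""Kinship-weighted pedigree score test.

For pedigrees each containing one genotyped proband (member 0) and any number
of ungenotyped relatives with known disease status, age and kinship to the
proband, the locally most powerful score test of genotype-disease association
replaces the proband's disease status by the kinship-weighted excess of
affected relatives over population expectation:

    U = sum_i sum_j (D_ij - L0(t_ij)) * 2 phi_ij0 * (g_i0 - 2p)
    V = 2 p (1 - p) * N * var_i( sum_j (D_ij - L0(t_ij)) * 2 phi_ij0 )
    Z = U / sqrt(V)

where L0(t) is the population cumulative disease hazard to age t, phi_ij0 the
kinship coefficient between relative j and the proband, p the allele
frequency and N the number of pedigrees.  The allele-sharing weight 2 phi is
1 for the proband, 1/2 for first-degree and 1/4 for second-degree relatives.

For a rare disease the L0 terms are negligible and, keeping only first-degree
relatives, the test reduces to regressing genotype on the composite phenotype
u = d + f/2 (d proband status, f the 0/1 family-history indicator) — the
composite used throughout the burden models.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "Pedigree",
    "IncidenceModel",
    "ScoreResult",
    "kinship_weight",
    "score_statistic",
    "score_variance",
    "score_test",
    "reduced_phenotype",
]

_KINSHIP_2PHI = {
    "self": 1.0,
    "first_degree": 0.5,
    "second_degree": 0.25,
    "unrelated": 0.0,
}


def kinship_weight(relationship: str) -> float:
    """Expected allele-sharing weight 2*phi for a named relationship."""
    try:
        return _KINSHIP_2PHI[relationship]
    except KeyError:
        raise ValueError(
            f"unknown relationship {relationship!r}; choose from {sorted(_KINSHIP_2PHI)}"
        ) from None


@dataclass
class Pedigree:
    """One pedigree: a genotyped proband plus relatives.

    Member 0 is the proband; `disease`, `age` and `kinship` are aligned arrays
    over all members including the proband (whose kinship with themself is
    1/2, i.e. weight 2*phi = 1).  Only the proband carries a genotype —
    relatives' genotypes are out of scope for this test.
    """

    pedigree_id: str
    proband_genotype: int | None
    disease: np.ndarray
    age: np.ndarray
    kinship: np.ndarray
    members: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.disease = np.asarray(self.disease, dtype=float)
        self.age = np.asarray(self.age, dtype=float)
        self.kinship = np.asarray(self.kinship, dtype=float)
        if not (self.disease.shape == self.age.shape == self.kinship.shape):
            raise ValueError(f"pedigree {self.pedigree_id}: member arrays differ in length")
        if not np.isin(self.disease, (0, 1)).all():
            raise ValueError(f"pedigree {self.pedigree_id}: disease status must be 0/1")
        if np.any(self.age < 0):
            raise ValueError(f"pedigree {self.pedigree_id}: ages must be >= 0")
        if np.any(self.kinship < 0) or np.any(self.kinship > 0.5):
            raise ValueError(f"pedigree {self.pedigree_id}: kinship must lie in [0, 1/2]")
        if self.proband_genotype is not None and self.proband_genotype not in (0, 1, 2):
            raise ValueError(f"pedigree {self.pedigree_id}: proband genotype must be 0/1/2")


class IncidenceModel:
    """Population cumulative hazard L0(t) as a piecewise-constant age-band table.

    Bands are half-open [a, b); ages at or beyond the last band boundary take
    the final value.  L0(0) = 0 and the table must be non-decreasing.
    """

    def __init__(self, band_starts, cumulative_hazard):
        starts = np.asarray(band_starts, dtype=float)
        values = np.asarray(cumulative_hazard, dtype=float)
        if starts.ndim != 1 or starts.shape != values.shape or starts.size == 0:
            raise ValueError("band_starts and cumulative_hazard must be equal-length 1-d")
        if np.any(np.diff(starts) <= 0):
            raise ValueError("band starts must be strictly increasing")
        if np.any(np.diff(values) < 0) or np.any(values < 0):
            raise ValueError("cumulative hazard must be non-negative and non-decreasing")
        self.band_starts = starts
        self.values = values

    @classmethod
    def zero(cls) -> "IncidenceModel":
        """The rare-disease approximation L0 = 0."""
        return cls([0.0], [0.0])

    def __call__(self, age) -> np.ndarray:
        age = np.asarray(age, dtype=float)
        idx = np.searchsorted(self.band_starts, age, side="right") - 1
        out = np.where(idx >= 0, self.values[np.clip(idx, 0, None)], 0.0)
        return out


@dataclass
class ScoreResult:
    u: float
    v: float
    z: float
    p: float
    n_pedigrees: int


def _weighted_sums(pedigrees: list[Pedigree], incidence: IncidenceModel) -> np.ndarray:
    """Per-pedigree S_i = sum_j (D_ij - L0(t_ij)) * 2 phi_ij0."""
    return np.array([
        float(np.sum((ped.disease - incidence(ped.age)) * 2.0 * ped.kinship))
        for ped in pedigrees
    ])


def _check_genotyped(pedigrees: list[Pedigree]) -> np.ndarray:
    genos = []
    for ped in pedigrees:
        if ped.proband_genotype is None:
            raise ValueError(f"pedigree {ped.pedigree_id} has no proband genotype")
        genos.append(ped.proband_genotype)
    return np.asarray(genos, dtype=float)


def score_statistic(pedigrees: list[Pedigree], incidence: IncidenceModel, p: float) -> float:
    """U = sum_i S_i (g_i0 - 2p), the kinship-weighted score numerator."""
    if not 0.0 < p < 1.0:
        raise ValueError("allele frequency p must be in (0, 1)")
    g = _check_genotyped(pedigrees)
    s = _weighted_sums(pedigrees, incidence)
    return float(np.sum(s * (g - 2.0 * p)))


def score_variance(pedigrees: list[Pedigree], incidence: IncidenceModel, p: float) -> float:
    """Null variance 2 p (1-p) N var(S), with the population (1/N) divisor."""
    if not 0.0 < p < 1.0:
        raise ValueError("allele frequency p must be in (0, 1)")
    s = _weighted_sums(pedigrees, incidence)
    n = len(s)
    return float(2.0 * p * (1.0 - p) * n * np.var(s))


def score_test(pedigrees: list[Pedigree], incidence: IncidenceModel, p: float) -> ScoreResult:
    """Z = U / sqrt(V) with a two-sided normal p-value.

    Under the null, permuting proband genotypes across pedigrees leaves Z
    standard normal — the calibration property the test suite checks.
    """
    u = score_statistic(pedigrees, incidence, p)
    v = score_variance(pedigrees, incidence, p)
    if v <= 0:
        raise ValueError(
            "degenerate score variance (all pedigrees have identical weighted "
            "phenotype sums); the test is undefined"
        )
    z = u / np.sqrt(v)
    return ScoreResult(u=u, v=v, z=float(z), p=float(2.0 * stats.norm.sf(abs(z))),
                       n_pedigrees=len(pedigrees))


def reduced_phenotype(d: int, n_affected_fdr: int, cap: bool = True) -> float:
    """Rare-disease composite u = d + f/2.

    `f` is the number of affected first-degree relatives; with `cap` (the
    default, matching the usual summary family-history variable) f is truncated
    at 1 so u is in {0, 0.5, 1, 1.5}.
    """
    if d not in (0, 1):
        raise ValueError("proband status d must be 0 or 1")
    if n_affected_fdr < 0:
        raise ValueError("number of affected relatives must be >= 0")
    f = min(n_affected_fdr, 1) if cap else n_affected_fdr
    return float(d) + 0.5 * f
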