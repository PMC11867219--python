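"""Cohort composition: conditional proportions over sex, disease and family history.

The package ships the composition of a large population exome cohort
(419,307 European-ancestry samples) for four cancers — breast, prostate,
bowel, lung — as packaged fixtures, so that power calculations and effective
sample sizes are reproducible without any data access.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import pandas as pd

CANCERS = ("breast", "prostate", "bowel", "lung")


@dataclass(frozen=True)
class CohortProportions:
    """Conditional cohort proportions.

    ``p_female`` is the marginal probability of female sex; case probabilities
    are conditional on sex; family-history (FH, >=1 affected first-degree
    relative) probabilities are conditional on sex and case status.
    """

    p_female: float
    p_case_female: float
    p_case_male: float
    p_fh_female_control: float
    p_fh_female_case: float
    p_fh_male_control: float
    p_fh_male_case: float

    def __post_init__(self) -> None:
        for name, value in self.__dict__.items():
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name}={value} is not a probability")

    def cell_probabilities(self) -> dict[tuple[int, int, int], float]:
        """Joint P(sex, case, fh) over the 2x2x2 phenotype cells.

        Keys are (sex, case, fh) with female coded sex=1.
        """
        p_sex = {1: self.p_female, 0: 1.0 - self.p_female}
        p_case = {1: self.p_case_female, 0: self.p_case_male}
        p_fh = {
            (1, 0): self.p_fh_female_control,
            (1, 1): self.p_fh_female_case,
            (0, 0): self.p_fh_male_control,
            (0, 1): self.p_fh_male_case,
        }
        out: dict[tuple[int, int, int], float] = {}
        for sex in (0, 1):
            for case in (0, 1):
                pc = p_case[sex] if case == 1 else 1.0 - p_case[sex]
                for fh in (0, 1):
                    pf = p_fh[(sex, case)] if fh == 1 else 1.0 - p_fh[(sex, case)]
                    out[(sex, case, fh)] = p_sex[sex] * pc * pf
        return out


def _read_fixture(name: str) -> pd.DataFrame:
    with resources.files("fhburden.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t", comment="#")


def load_proportions(cancer: str) -> CohortProportions:
    """Load the packaged cohort proportions for one of the four cancers."""
    if cancer not in CANCERS:
        raise KeyError(f"unknown cancer {cancer!r}; choose from {CANCERS}")
    table = _read_fixture("cohort_proportions.tsv").set_index("cancer")
    row = table.loc[cancer]
    return CohortProportions(**{k: float(row[k]) for k in row.index})


def load_cohort_counts(cancer: str) -> dict[str, int]:
    """Realized case/control counts by sex for one cancer (packaged fixture)."""
    if cancer not in CANCERS:
        raise KeyError(f"unknown cancer {cancer!r}; choose from {CANCERS}")
    table = _read_fixture("cohort_counts.tsv").set_index("cancer")
    return {k: int(v) for k, v in table.loc[cancer].items()}
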