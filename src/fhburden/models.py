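"""Carrier-status logistic models incorporating family history.

The burden association framework regresses gene carrier status G (0/1) on the
phenotype rather than the reverse — for a 2x2 table the odds ratio is the same
whichever margin is treated as the outcome, and this orientation makes family
history easy to add.  Four nested models are fitted, with FH the indicator of
>=1 affected first-degree relative:

* null:    logit P(G=1) = alpha + b3 Sex (+ covariates)
* model 1: ... + b1 Case                       (standard case-control burden)
* model 2: ... + b1 Case + b2 FH               (free FH effect; 2-df test)
* model 3: ... + b1 (Case + k FH)              (FH effect constrained to k*b1)

Model 3 with k = 1/2 is the locally most powerful choice for small effects,
because first-degree relatives share half their alleles; model 1 is k = 0 and
k = 1 treats a positive family history as a full proxy case.  For 0/1/2
genotypes (common variants) the analogues are adjacent-categories logit models
whose shared slope b1 is the per-allele log odds ratio.

All binary-covariate fits collapse to the 2x2x2x2 sex x case x FH x carrier
cell counts (`CohortCells`), which are sufficient, so a 450,000-sample fit
costs the same as an 8-row one.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._glm import GlmResult, fit_adjacent_categories_glm, fit_binomial_glm

__all__ = [
    "CohortCells",
    "ModelFit",
    "AssociationResult",
    "fit_null",
    "fit_model1",
    "fit_model2",
    "fit_model3",
    "fit_adjacent_categories",
    "lrt",
    "wald_test",
    "optimal_k",
    "run_gene_scan",
]


class CohortCells:
    """Joint counts over the sex x case x family-history x carrier strata.

    ``counts[sex, case, fh, carrier]`` is a (2, 2, 2, 2) non-negative array.
    These cells are the sufficient statistic for every model in this module
    whose covariates are the three binaries.
    """

    def __init__(self, counts: np.ndarray):
        counts = np.asarray(counts, dtype=float)
        if counts.shape != (2, 2, 2, 2):
            raise ValueError("counts must have shape (2, 2, 2, 2)")
        if np.any(counts < 0) or not np.all(np.isfinite(counts)):
            raise ValueError("counts must be finite and non-negative")
        self.counts = counts

    @classmethod
    def from_records(cls, records: pd.DataFrame) -> "CohortCells":
        """Tabulate per-sample records with columns sex, case, fh, carrier."""
        required = ["sex", "case", "fh", "carrier"]
        missing = [c for c in required if c not in records.columns]
        if missing:
            raise ValueError(f"records are missing columns: {missing}")
        arr = records[required].to_numpy()
        if not np.isin(arr, (0, 1)).all():
            raise ValueError("sex, case, fh and carrier must all be 0/1")
        idx = arr[:, 0] * 8 + arr[:, 1] * 4 + arr[:, 2] * 2 + arr[:, 3]
        return cls(np.bincount(idx.astype(int), minlength=16).reshape(2, 2, 2, 2))

    @property
    def n(self) -> float:
        return float(self.counts.sum())

    def phenotype_margins(self) -> np.ndarray:
        """(2, 2, 2) counts over sex x case x fh, collapsing carrier."""
        return self.counts.sum(axis=3)

    def to_records(self) -> pd.DataFrame:
        """Expand to one row per individual (integer counts required)."""
        rows = []
        for sex in (0, 1):
            for case in (0, 1):
                for fh in (0, 1):
                    for carrier in (0, 1):
                        c = self.counts[sex, case, fh, carrier]
                        if c != int(c):
                            raise ValueError("cannot expand non-integer cell counts")
                        rows.extend([(sex, case, fh, carrier)] * int(c))
        return pd.DataFrame(rows, columns=["sex", "case", "fh", "carrier"])

    def grouped(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(patterns, successes, trials): 8 rows of (sex, case, fh)."""
        patterns = np.array(
            [(sex, case, fh) for sex in (0, 1) for case in (0, 1) for fh in (0, 1)],
            dtype=float,
        )
        trials = self.counts.sum(axis=3).reshape(-1)
        successes = self.counts[:, :, :, 1].reshape(-1)
        return patterns, successes, trials


@dataclass
class ModelFit:
    """A fitted carrier-status model."""

    model: str
    params: pd.Series
    cov: pd.DataFrame
    loglik: float
    df: int
    n: float
    converged: bool
    separated: bool
    k: float | None = None
    beta1_name: str | None = None
    n_iter: int = 0

    @property
    def beta1(self) -> float:
        if self.beta1_name is None:
            raise ValueError(f"model {self.model!r} has no association coefficient")
        return float(self.params[self.beta1_name])

    @property
    def k_T(self) -> float:
        """Empirical k = beta2/beta1 — only defined for model 2."""
        if self.model not in ("m2", "ac-m2"):
            raise ValueError("k_T is defined only for model 2 fits")
        return float(self.params["fh"] / self.params["case"])

    def se(self, name: str) -> float:
        return float(np.sqrt(self.cov.loc[name, name]))


@dataclass
class AssociationResult:
    gene: str
    model: str
    k: float | None
    n_carriers: int
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_wald: float
    p_lrt: float
    converged: bool
    separated: bool
    exome_wide: bool = False
    suggestive: bool = False
    flags: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# design construction and the shared fitting path
# ---------------------------------------------------------------------------

_MODEL_TERMS = {
    "null": (),
    "m1": ("case",),
    "m2": ("case", "fh"),
    "m3": ("composite",),
}


def _design(patterns: pd.DataFrame, model: str, k: float | None,
            covariates: list[str]) -> tuple[np.ndarray, list[str]]:
    cols: list[np.ndarray] = [np.ones(len(patterns))]
    names = ["(intercept)"]
    for term in _MODEL_TERMS[model]:
        if term == "composite":
            cols.append(patterns["case"].to_numpy(float) + k * patterns["fh"].to_numpy(float))
            names.append("case_k_fh")
        else:
            cols.append(patterns[term].to_numpy(float))
            names.append(term)
    cols.append(patterns["sex"].to_numpy(float))
    names.append("sex")
    for cov in covariates:
        cols.append(patterns[cov].to_numpy(float))
        names.append(cov)
    return np.column_stack(cols), names


def _check_degenerate(X: np.ndarray, names: list[str], trials: np.ndarray) -> None:
    observed = trials > 0
    for j, name in enumerate(names):
        if name == "(intercept)":
            continue
        col = X[observed, j]
        if col.size and np.ptp(col) == 0:
            raise ValueError(
                f"covariate {name!r} is constant across the observed data; "
                "the coefficient is inestimable"
            )


def _prepare(data: CohortCells | pd.DataFrame,
             covariates: list[str] | None) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    """Return (pattern table, successes, trials) for either input form."""
    covariates = covariates or []
    if isinstance(data, CohortCells):
        if covariates:
            raise ValueError("extra covariates require per-sample records, not cells")
        patterns, successes, trials = data.grouped()
        table = pd.DataFrame(patterns, columns=["sex", "case", "fh"])
        return table, successes, trials
    records = data
    needed = ["sex", "case", "fh", "carrier", *covariates]
    missing = [c for c in needed if c not in records.columns]
    if missing:
        raise ValueError(f"records are missing columns: {missing}")
    if not covariates:
        return _prepare(CohortCells.from_records(records), None)
    # arbitrary covariates: group identical covariate patterns for speed
    keys = records[["sex", "case", "fh", *covariates]]
    grouped = records.assign(_n=1).groupby(
        [*keys.columns], as_index=False, sort=False
    ).agg(successes=("carrier", "sum"), trials=("_n", "sum"))
    return grouped[keys.columns], grouped["successes"].to_numpy(float), \
        grouped["trials"].to_numpy(float)


def _fit(data, model: str, k: float | None = None,
         covariates: list[str] | None = None) -> ModelFit:
    covariates = list(covariates or [])
    table, successes, trials = _prepare(data, covariates)
    X, names = _design(table, model, k, covariates)
    _check_degenerate(X, names, trials)
    res: GlmResult = fit_binomial_glm(X, successes, trials)
    if not res.converged:
        import warnings

        warnings.warn(f"model {model} did not converge after {res.n_iter} iterations",
                      RuntimeWarning, stacklevel=3)
    if res.separated:
        import warnings

        warnings.warn(f"model {model}: separation detected (|coef| > 15); "
                      "estimates are unreliable", RuntimeWarning, stacklevel=3)
    beta1_name = None
    if model == "m1":
        beta1_name = "case"
    elif model == "m2":
        beta1_name = "case"
    elif model == "m3":
        beta1_name = "case_k_fh"
    return ModelFit(
        model=model,
        params=pd.Series(res.coef, index=names),
        cov=pd.DataFrame(res.cov, index=names, columns=names),
        loglik=res.loglik,
        df=len(names),
        n=float(trials.sum()),
        converged=res.converged,
        separated=res.separated,
        k=k,
        beta1_name=beta1_name,
        n_iter=res.n_iter,
    )


def fit_null(data, covariates: list[str] | None = None) -> ModelFit:
    """Fit the covariates-only null model logit P(G=1) = alpha + b3 Sex."""
    return _fit(data, "null", covariates=covariates)


def fit_model1(data, covariates: list[str] | None = None) -> ModelFit:
    """Standard case-control burden model: + b1 Case."""
    return _fit(data, "m1", covariates=covariates)


def fit_model2(data, covariates: list[str] | None = None) -> ModelFit:
    """Free family-history model: + b1 Case + b2 FH; exposes k_T = b2/b1."""
    return _fit(data, "m2", covariates=covariates)


def fit_model3(data, k: float = 0.5, covariates: list[str] | None = None) -> ModelFit:
    """Composite-phenotype model: + b1 (Case + k FH) for a fixed weight k."""
    if not np.isfinite(k):
        raise ValueError("k must be finite")
    return _fit(data, "m3", k=float(k), covariates=covariates)


# ---------------------------------------------------------------------------
# tests on fitted models
# ---------------------------------------------------------------------------

_NULL_OF = {"m1": "null", "m2": "null", "m3": "null",
            "ac-m1": "ac-null", "ac-m2": "ac-null", "ac-m3": "ac-null"}


def lrt(fit: ModelFit, null_fit: ModelFit) -> tuple[float, int, float]:
    """Likelihood-ratio test of a model against its nested null.

    Returns (statistic, df, p).  The statistic 2*(l1 - l0) is clamped at zero;
    df is the difference in free parameters (1 for models 1/3, 2 for model 2).
    """
    if _NULL_OF.get(fit.model) != null_fit.model:
        raise ValueError(f"{null_fit.model!r} is not the nested null of {fit.model!r}")
    if fit.n != null_fit.n:
        raise ValueError("fits are on different data (n differs)")
    df = fit.df - null_fit.df
    if df <= 0:
        raise ValueError("alternative model has no extra parameters")
    stat = max(0.0, 2.0 * (fit.loglik - null_fit.loglik))
    return stat, df, float(stats.chi2.sf(stat, df))


def wald_test(fit: ModelFit, name: str | None = None) -> tuple[float, float, tuple[float, float]]:
    """Two-sided Wald test for one coefficient (default: the association term).

    Returns (z, p, (ci_low, ci_high)) with the 95% CI on the log-odds scale.
    """
    if name is None:
        name = fit.beta1_name
    est = float(fit.params[name])
    se = fit.se(name)
    if not np.isfinite(se) or se <= 0:
        raise ValueError(f"degenerate standard error for {name!r}")
    z = est / se
    p = float(2.0 * stats.norm.sf(abs(z)))
    half = 1.959963984540054 * se
    return z, p, (est - half, est + half)


def optimal_k(beta1: float) -> float:
    """Locally optimal family-history weight for a given case log-odds ratio.

    For a rare allele with relative risk e^b, the allele frequency in subjects
    with an affected first-degree relative is about the mean of the case and
    control frequencies, i.e. e^b2 = (e^b1 + 1)/2, giving
    k = log((e^b1 + 1)/2) / b1.  The small-effect limit is k = 1/2, and k
    increases with the effect size.
    """
    if not np.isfinite(beta1):
        raise ValueError("beta1 must be finite")
    if abs(beta1) < 1e-8:
        return 0.5
    return math.log((math.exp(beta1) + 1.0) / 2.0) / beta1


# ---------------------------------------------------------------------------
# adjacent-categories models for 0/1/2 genotypes
# ---------------------------------------------------------------------------

def _ac_prepare(genotypes: np.ndarray, phenotypes: pd.DataFrame,
                covariates: list[str]) -> tuple[pd.DataFrame, np.ndarray]:
    g = np.asarray(genotypes)
    if g.shape[0] != len(phenotypes):
        raise ValueError("genotypes and phenotypes differ in length")
    if not np.isin(g, (0, 1, 2)).all():
        raise ValueError("genotypes must be 0, 1 or 2")
    keys = phenotypes[["sex", "case", "fh", *covariates]].reset_index(drop=True)
    tab = keys.assign(_g=g).groupby([*keys.columns, "_g"]).size().unstack(
        "_g", fill_value=0)
    for level in (0, 1, 2):
        if level not in tab.columns:
            tab[level] = 0
    counts = tab[[0, 1, 2]].to_numpy(float)
    patterns = tab.index.to_frame(index=False)
    return patterns, counts


def fit_adjacent_categories(genotypes, phenotypes: pd.DataFrame, model: str = "m1",
                            k: float = 0.5,
                            covariates: list[str] | None = None) -> ModelFit:
    """Adjacent-categories logit fit for a 0/1/2 genotype.

    log P(G=j+1)/P(G=j) = alpha_j0 + slope terms, with the slope b1 shared
    across the two transitions — the per-allele log odds ratio.  `model`
    selects which phenotype terms enter, exactly as for the binary models.
    When a boundary genotype level is absent the model degenerates to the
    single observed transition and is fitted as ordinary logistic regression.
    """
    if model not in ("null", "m1", "m2", "m3"):
        raise ValueError(f"unknown model {model!r}")
    covariates = list(covariates or [])
    patterns, counts = _ac_prepare(np.asarray(genotypes), phenotypes, covariates)
    totals = counts.sum(axis=0)
    observed_levels = [j for j in range(3) if totals[j] > 0]
    if len(observed_levels) < 2:
        raise ValueError("genotype has fewer than 2 observed levels")
    tag = f"ac-{model}" if model != "null" else "ac-null"

    if len(observed_levels) == 2:
        lo, hi = observed_levels
        if hi - lo != 1:
            raise ValueError(
                "only genotype levels 0 and 2 observed; the adjacent-categories "
                "intercepts are not separately identifiable"
            )
        X, names = _design(patterns, model, k, covariates)
        trials = counts[:, lo] + counts[:, hi]
        res = fit_binomial_glm(X, counts[:, hi], trials)
        names = [f"alpha_{lo}0" if n == "(intercept)" else n for n in names]
        coef, cov = res.coef, res.cov
    else:
        Xs, names_full = _design(patterns, model, k, covariates)
        Xslopes = Xs[:, 1:]  # drop intercept; AC fitter supplies alpha_00/alpha_10
        res = fit_adjacent_categories_glm(Xslopes, counts)
        names = ["alpha_00", "alpha_10", *names_full[1:]]
        coef, cov = res.coef, res.cov

    beta1_name = {"m1": "case", "m2": "case", "m3": "case_k_fh"}.get(model)
    return ModelFit(
        model=tag,
        params=pd.Series(coef, index=names),
        cov=pd.DataFrame(cov, index=names, columns=names),
        loglik=res.loglik,
        df=len(names),
        n=float(counts.sum()),
        converged=res.converged,
        separated=res.separated,
        k=k if model == "m3" else None,
        beta1_name=beta1_name,
        n_iter=res.n_iter,
    )


# ---------------------------------------------------------------------------
# gene scan
# ---------------------------------------------------------------------------

EXOME_WIDE_P = 2.5e-6
SUGGESTIVE_P = 1e-3


def run_gene_scan(carriers, phenotypes: pd.DataFrame, model: str = "m3",
                  k: float = 0.5, covariates: list[str] | None = None,
                  thresholds: tuple[float, float] = (EXOME_WIDE_P, SUGGESTIVE_P),
                  ) -> tuple[pd.DataFrame, list[str]]:
    """Fit the chosen model per gene and report odds ratios and p-values.

    `carriers` maps gene id -> BurdenVector (or any object with `sample_ids`
    and boolean `carrier`).  Samples are joined to `phenotypes` by sample_id,
    never by position.  Genes with zero carriers among phenotyped samples are
    skipped and listed separately.  Significance flags use strict `<` at the
    exome-wide and suggestive thresholds.
    """
    pheno = phenotypes.set_index("sample_id")
    results: list[AssociationResult] = []
    skipped: list[str] = []
    exome_thr, sugg_thr = thresholds
    for gene, vec in carriers.items():
        carrier = pd.Series(np.asarray(vec.carrier, dtype=int),
                            index=pd.Index(vec.sample_ids, name="sample_id"))
        missing = carrier.index.difference(pheno.index)
        if len(missing):
            raise ValueError(
                f"gene {gene}: {len(missing)} carrier samples absent from phenotypes; "
                f"first offenders: {list(missing[:10])}"
            )
        df = pheno.loc[carrier.index].assign(carrier=carrier)
        n_carriers = int(df["carrier"].sum())
        if n_carriers == 0 or n_carriers == len(df):
            skipped.append(gene)
            continue
        null_fit = fit_null(df, covariates=covariates)
        if model == "m1":
            fit = fit_model1(df, covariates=covariates)
        elif model == "m2":
            fit = fit_model2(df, covariates=covariates)
        elif model == "m3":
            fit = fit_model3(df, k=k, covariates=covariates)
        else:
            raise ValueError(f"unknown model {model!r}")
        _, _, p_lrt = lrt(fit, null_fit)
        _, p_wald, (lo, hi) = wald_test(fit)
        results.append(AssociationResult(
            gene=gene, model=model, k=k if model == "m3" else None,
            n_carriers=n_carriers, odds_ratio=math.exp(fit.beta1),
            ci_low=math.exp(lo), ci_high=math.exp(hi),
            p_wald=p_wald, p_lrt=p_lrt,
            converged=fit.converged, separated=fit.separated,
            exome_wide=p_lrt < exome_thr, suggestive=p_lrt < sugg_thr,
        ))
    columns = ["gene", "model", "k", "n_carriers", "odds_ratio", "ci_low",
               "ci_high", "p_wald", "p_lrt", "converged", "separated",
               "exome_wide", "suggestive"]
    table = pd.DataFrame([{c: getattr(r, c) for c in columns} for r in results],
                         columns=columns)
    return table, skipped
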