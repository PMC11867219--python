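"""Internal maximum-likelihood machinery.

Two fitters live here:

* a grouped-binomial logistic IRLS (Newton) routine used by every carrier-status
  model — grouped rows are (covariate pattern, successes, trials), and
  per-individual data is just the trials==1 special case;
* a Newton fitter for the adjacent-categories logit model on 0/1/2 genotypes,
  parameterised as the constrained multinomial it is equivalent to.

Log-likelihoods omit the binomial / multinomial coefficient, which is constant
in the parameters, so likelihood-ratio statistics are unaffected and grouped
and expanded representations of the same data give identical values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

# |coefficient| beyond which a logistic fit is treated as separated: at this
# magnitude the fitted odds ratio exceeds 3e6 and the likelihood is flat.
SEPARATION_BOUND = 15.0


@dataclass
class GlmResult:
    coef: np.ndarray
    cov: np.ndarray
    loglik: float
    converged: bool
    separated: bool
    n_iter: int


def _binom_loglik(eta: np.ndarray, successes: np.ndarray, trials: np.ndarray) -> float:
    # k*eta - n*log(1+e^eta), stable via logaddexp
    return float(np.sum(successes * eta - trials * np.logaddexp(0.0, eta)))


def fit_binomial_glm(
    X: np.ndarray,
    successes: np.ndarray,
    trials: np.ndarray,
    *,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> GlmResult:
    """ML fit of a binomial logistic model on grouped data.

    Parameters
    ----------
    X : (m, p) design matrix, one row per covariate pattern.
    successes, trials : (m,) counts; rows with trials == 0 are inert.

    Convergence is declared when the maximum absolute score component drops
    below `tol`.  Step-halving guards the Newton update.
    """
    X = np.asarray(X, dtype=float)
    successes = np.asarray(successes, dtype=float)
    trials = np.asarray(trials, dtype=float)
    if X.ndim != 2 or X.shape[0] != successes.shape[0] or successes.shape != trials.shape:
        raise ValueError("design and count arrays are not conformable")
    if np.any(successes < 0) or np.any(successes > trials):
        raise ValueError("successes must lie in [0, trials]")
    total_s, total_t = successes.sum(), trials.sum()
    if total_t <= 0:
        raise ValueError("no observations (all trials zero)")
    if total_s == 0 or total_s == total_t:
        raise ValueError(
            "response is constant (all-carrier or no-carrier); the model is not identifiable"
        )

    m, p = X.shape
    beta = np.zeros(p)
    # warm start for an intercept-like first column
    if np.allclose(X[:, 0], 1.0):
        frac = total_s / total_t
        beta[0] = np.log(frac / (1.0 - frac))

    ll = _binom_loglik(X @ beta, successes, trials)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        score = X.T @ (successes - trials * mu)
        if np.max(np.abs(score)) < tol:
            converged = True
            break
        w = trials * mu * (1.0 - mu)
        info = (X * w[:, None]).T @ X
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(info, score, rcond=None)[0]
        # step-halving: never accept a likelihood decrease
        scale = 1.0
        for _ in range(30):
            cand = beta + scale * step
            ll_new = _binom_loglik(X @ cand, successes, trials)
            if ll_new >= ll - 1e-12:
                break
            scale *= 0.5
        beta = beta + scale * step
        ll = _binom_loglik(X @ beta, successes, trials)

    eta = X @ beta
    mu = 1.0 / (1.0 + np.exp(-eta))
    w = trials * mu * (1.0 - mu)
    info = (X * w[:, None]).T @ X
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        cov = np.full((p, p), np.nan)
    separated = bool(np.any(np.abs(beta) > SEPARATION_BOUND))
    return GlmResult(coef=beta, cov=cov, loglik=ll, converged=converged,
                     separated=separated, n_iter=it)


# ---------------------------------------------------------------------------
# adjacent-categories logit on 0/1/2 genotype counts
# ---------------------------------------------------------------------------

def _ac_scores(theta: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Category linear scores c_{rj} for j = 0,1,2.

    theta = (a0, a1, slopes...); the adjacent-categories model
    log P(G=j+1)/P(G=j) = a_j + s.x implies multinomial scores
    c_0 = 0, c_1 = a0 + s.x, c_2 = a0 + a1 + 2 s.x.
    """
    a0, a1 = theta[0], theta[1]
    sx = X @ theta[2:] if theta.size > 2 else np.zeros(X.shape[0])
    c = np.zeros((X.shape[0], 3))
    c[:, 1] = a0 + sx
    c[:, 2] = a0 + a1 + 2.0 * sx
    return c


def _ac_basis(theta_size: int, X: np.ndarray) -> np.ndarray:
    """d c_{rj} / d theta, shape (m, 3, p)."""
    m = X.shape[0]
    p = theta_size
    T = np.zeros((m, 3, p))
    T[:, 1, 0] = 1.0
    T[:, 2, 0] = 1.0
    T[:, 2, 1] = 1.0
    if p > 2:
        T[:, 1, 2:] = X
        T[:, 2, 2:] = 2.0 * X
    return T


def fit_adjacent_categories_glm(
    X: np.ndarray,
    counts: np.ndarray,
    *,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> GlmResult:
    """Newton ML fit of the adjacent-categories model on grouped genotype counts.

    X : (m, p_slope) covariate patterns; counts : (m, 3) genotype counts per
    pattern.  Returns coefficients ordered (alpha_00, alpha_10, slopes...).
    """
    X = np.asarray(X, dtype=float)
    counts = np.asarray(counts, dtype=float)
    if counts.shape != (X.shape[0], 3):
        raise ValueError("counts must be (m, 3) genotype-category counts")
    level_totals = counts.sum(axis=0)
    if np.count_nonzero(level_totals) < 2:
        raise ValueError("genotype has fewer than 2 observed levels; model not identifiable")

    p = 2 + X.shape[1]
    theta = np.zeros(p)
    T = _ac_basis(p, X)

    def loglik(th: np.ndarray) -> float:
        c = _ac_scores(th, X)
        logz = np.log(np.exp(c - c.max(axis=1, keepdims=True)).sum(axis=1)) + c.max(axis=1)
        return float(np.sum(counts * (c - logz[:, None])))

    ll = loglik(theta)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        c = _ac_scores(theta, X)
        P = np.exp(c - c.max(axis=1, keepdims=True))
        P /= P.sum(axis=1, keepdims=True)
        n_r = counts.sum(axis=1)
        Tbar = np.einsum("rj,rjp->rp", P, T)
        grad = np.einsum("rj,rjp->p", counts, T) - n_r @ Tbar
        if np.max(np.abs(grad)) < tol:
            converged = True
            break
        second = np.einsum("rj,rjp,rjq->rpq", P, T, T)
        fisher = np.einsum("r,rpq->pq", n_r, second - np.einsum("rp,rq->rpq", Tbar, Tbar))
        try:
            step = np.linalg.solve(fisher, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(fisher, grad, rcond=None)[0]
        scale = 1.0
        for _ in range(30):
            if loglik(theta + scale * step) >= ll - 1e-12:
                break
            scale *= 0.5
        theta = theta + scale * step
        ll = loglik(theta)

    c = _ac_scores(theta, X)
    P = np.exp(c - c.max(axis=1, keepdims=True))
    P /= P.sum(axis=1, keepdims=True)
    n_r = counts.sum(axis=1)
    Tbar = np.einsum("rj,rjp->rp", P, T)
    second = np.einsum("rj,rjp,rjq->rpq", P, T, T)
    fisher = np.einsum("r,rpq->pq", n_r, second - np.einsum("rp,rq->rpq", Tbar, Tbar))
    try:
        cov = np.linalg.inv(fisher)
    except np.linalg.LinAlgError:
        cov = np.full((p, p), np.nan)
    separated = bool(np.any(np.abs(theta) > SEPARATION_BOUND))
    return GlmResult(coef=theta, cov=cov, loglik=ll, converged=converged,
                     separated=separated, n_iter=it)
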