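"""Zero-inflated quantile rank-score machinery.

The test treats a taxon's normalized abundance Y as a two-part outcome: a
presence indicator I(Y>0) following a logistic model

    logit P(Y > 0 | X) = Z'zeta + gamma C,

and conditional quantiles of the positive part following a linear quantile
model

    Q_Y(tau | X, Y > 0) = Z'alpha(tau) + beta(tau) C.

The global null is gamma = 0 and beta(tau) = 0 for all tau.  This module
provides the marginal pieces: the count perturbation that breaks ties in
discrete outcomes, the logistic presence test of gamma = 0, the null
quantile fits (beta = 0), the zero-adjusted rank-score statistic

    S_tau = n^{-1/2} sum_i psi_tau(W_i - Z_i'alpha_hat(tau)) I(Y_i>0) C*_i,
    T_tau = S_tau / sqrt(n^{-1} tau (1-tau) C*'C*),

where C* is the residual of the zero-truncated variable of interest on the
zero-truncated covariates, and the cross-quantile covariance of the scores

    Sigma_kl = n^{-1} (min(tau_k, tau_l) - tau_k tau_l) C*'C*,

a Brownian-bridge kernel scaled by a non-negative scalar, hence positive
semidefinite by construction.  T_tau is asymptotically standard normal under
the null; p-values are two-sided.

Crucially the rank score runs on the non-zero subset but its variance uses
the zero-truncated C*, whose second moment carries P(Y>0|X): this is what
restores validity under zero inflation, where a plain quantile rank-score
test on the positive subset would underestimate the variance.

Conventions pinned here (they matter for exact reproducibility):

* psi_tau(0) = tau, i.e. psi_tau(u) = tau - I(u < 0);
* when the pinball-loss minimizer is an interval (possible for discrete
  data), the lower vertex is taken.  Intercept-only fits therefore use the
  order statistic at position ceil(m*tau); general fits solve the exact
  linear program.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
from scipy import stats
from scipy.optimize import linprog

from .table_io import Design

MIN_NONZERO = 15  # practical prevalence threshold for the quantile part


@dataclasses.dataclass
class PerturbedOutcome:
    """Outcome vector after tie-breaking perturbation W = Y + U, U~U(0,1)."""

    w: np.ndarray
    nonzero_mask: np.ndarray  # defined on the raw Y, never on W
    applied: bool


@dataclasses.dataclass
class LogisticTestResult:
    statistic: float
    p_l: float
    method: str
    converged: bool = True
    degenerate: bool = False


@dataclasses.dataclass
class ResidualizedCovariate:
    """C* — the zero-truncated variable residualized on the covariates."""

    c_star: np.ndarray
    nonzero_mask: np.ndarray
    m: int
    quadratic_norm: float
    rank_deficient: bool = False

    @property
    def degenerate(self) -> bool:
        return self.quadratic_norm <= 1e-12


@dataclasses.dataclass
class MarginalQuantileResult:
    tau: float
    alpha_hat: np.ndarray
    s: float
    t: float
    p_q: float


@dataclasses.dataclass
class ScoreCovariance:
    taus: np.ndarray
    sigma: np.ndarray


@dataclasses.dataclass
class ZinqMarginals:
    """Everything the combination step needs for one taxon."""

    logistic: LogisticTestResult | None
    quantile: list[MarginalQuantileResult]
    sigma: ScoreCovariance | None
    r_hat: float
    m: int
    n: int
    flags: list[str]


def perturb_counts(y: np.ndarray, discrete: bool, seed: int) -> PerturbedOutcome:
    """Add iid U(0,1) to a discrete outcome to break ties; no-op otherwise.

    The zero/non-zero mask is always taken from the raw ``y``.
    """
    y = np.asarray(y, dtype=float)
    mask = y > 0
    if not discrete:
        return PerturbedOutcome(y.copy(), mask, applied=False)
    rng = np.random.default_rng(seed)
    return PerturbedOutcome(y + rng.uniform(size=y.shape), mask, applied=True)


def _null_logistic_fit(d: np.ndarray, z: np.ndarray) -> np.ndarray:
    """Fitted probabilities of the covariates-only logistic model."""
    if z.shape[1] == 1 and np.allclose(z[:, 0], z[0, 0]):
        return np.full(d.shape[0], d.mean())
    import statsmodels.api as sm

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = sm.Logit(d, z).fit(disp=0, maxiter=100)
    return np.asarray(fit.predict(z))


def _score_statistic(d: np.ndarray, z: np.ndarray, c: np.ndarray) -> float:
    """Rao score statistic for adding ``c`` to the null logistic model."""
    p0 = _null_logistic_fit(d, z)
    w = p0 * (1.0 - p0)
    s = float(c @ (d - p0))
    zwz = z.T @ (z * w[:, None])
    zwc = z.T @ (c * w)
    var = float(c @ (c * w) - zwc @ np.linalg.solve(zwz, zwc))
    if var <= 0:
        return np.nan
    return s * s / var


def logistic_presence_test(
    nonzero_mask: np.ndarray, design: Design, method: str = "lrt"
) -> LogisticTestResult:
    """Test gamma = 0 in the presence model logit P(Y>0|X) = Z'zeta + gamma C.

    ``method`` is one of ``wald``, ``score`` or ``lrt`` (default).  Wald and
    LRT need the full-model maximum-likelihood fit; on non-convergence or
    separation they fall back to the Rao score test, which only requires the
    null fit and is defined even under separation.  An all-zero or
    all-nonzero mask (or a constant variable) is degenerate: no test.
    """
    if method not in ("wald", "score", "lrt"):
        raise ValueError(f"unknown logistic test method: {method!r}")
    d = np.asarray(nonzero_mask, dtype=float)
    c = design.variable
    z = design.covariates
    if d.min() == d.max() or np.ptp(c) == 0:
        return LogisticTestResult(np.nan, np.nan, method, degenerate=True)

    if method == "score":
        stat = _score_statistic(d, z, c)
        return LogisticTestResult(stat, float(stats.chi2.sf(stat, 1)), "score")

    import statsmodels.api as sm

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            full = sm.Logit(d, design.full_matrix()).fit(disp=0, maxiter=100)
        converged = bool(full.mle_retvals.get("converged", False))
        separated = np.max(np.abs(full.params)) > 50
        if not converged or separated:
            raise RuntimeError("logistic full fit unreliable")
        if method == "wald":
            zstat = float(full.params[-1] / full.bse[-1])
            stat = zstat * zstat
        else:  # lrt
            if z.shape[1] == 1 and np.allclose(z[:, 0], z[0, 0]):
                pbar = d.mean()
                llf_null = d.sum() * np.log(pbar) + (d.size - d.sum()) * np.log(1 - pbar)
            else:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    llf_null = sm.Logit(d, z).fit(disp=0, maxiter=100).llf
            stat = float(2.0 * (full.llf - llf_null))
            stat = max(stat, 0.0)
        return LogisticTestResult(stat, float(stats.chi2.sf(stat, 1)), method)
    except Exception:
        stat = _score_statistic(d, z, c)
        return LogisticTestResult(
            stat, float(stats.chi2.sf(stat, 1)), "score", converged=False
        )


def residualize(design: Design, nonzero_mask: np.ndarray) -> ResidualizedCovariate:
    """Project the zero-truncated variable off the zero-truncated covariates.

    C~ = C * I(Y>0), Z~ = Z * I(Y>0) (rows zeroed), and
    C* = (I - Z~(Z~'Z~)^{-1}Z~') C~ — the least-squares residual, which is
    exactly zero at zero positions and orthogonal to Z~.  A singular Z~'Z~
    falls back to the pseudo-inverse (flagged).
    """
    mask = np.asarray(nonzero_mask, dtype=bool)
    c_tilde = design.variable * mask
    z_tilde = design.covariates * mask[:, None]
    coefs, _, rank, _ = np.linalg.lstsq(z_tilde, c_tilde, rcond=None)
    c_star = c_tilde - z_tilde @ coefs
    c_star[~mask] = 0.0
    return ResidualizedCovariate(
        c_star=c_star,
        nonzero_mask=mask,
        m=int(mask.sum()),
        quadratic_norm=float(c_star @ c_star),
        rank_deficient=rank < design.p,
    )


def fit_quantile(w: np.ndarray, x: np.ndarray, tau: float) -> np.ndarray:
    """Exact pinball-loss minimizer of w on design x at level tau.

    Solved as the standard quantile-regression linear program (HiGHS).  An
    intercept-only design short-circuits to the order statistic at position
    ceil(m*tau) — the lower vertex of the minimizing interval, matching the
    pinned tie-break.
    """
    w = np.asarray(w, dtype=float)
    x = np.atleast_2d(np.asarray(x, dtype=float))
    m, p = x.shape
    if m < p + 1:
        raise ValueError(f"need at least p+1={p + 1} observations, got {m}")
    if p == 1 and np.allclose(x[:, 0], 1.0):
        return np.array([np.quantile(w, tau, method="inverted_cdf")])
    cost = np.concatenate([np.zeros(p), np.full(m, tau), np.full(m, 1.0 - tau)])
    a_eq = np.hstack([x, np.eye(m), -np.eye(m)])
    bounds = [(None, None)] * p + [(0.0, None)] * (2 * m)
    res = linprog(cost, A_eq=a_eq, b_eq=w, bounds=bounds, method="highs")
    if not res.success:
        raise RuntimeError(f"quantile LP failed at tau={tau}: {res.message}")
    return res.x[:p]


def fit_null_quantile(
    w: PerturbedOutcome | np.ndarray,
    design: Design,
    nonzero_mask: np.ndarray | None,
    tau: float,
) -> np.ndarray:
    """Null fit alpha_hat(tau): quantile regression of W on Z alone, on the
    non-zero subset (the pinball loss carries the I(Y>0) factor)."""
    if isinstance(w, PerturbedOutcome):
        values = w.w
        if nonzero_mask is None:
            nonzero_mask = w.nonzero_mask
    else:
        values = np.asarray(w, dtype=float)
    mask = np.asarray(nonzero_mask, dtype=bool)
    return fit_quantile(values[mask], design.covariates[mask], tau)


def rank_score_test(
    w: PerturbedOutcome | np.ndarray,
    design: Design,
    nonzero_mask: np.ndarray | None,
    resid: ResidualizedCovariate,
    tau: float,
    alpha_hat: np.ndarray | None = None,
) -> MarginalQuantileResult:
    """Zero-adjusted quantile rank-score test of beta(tau) = 0."""
    if isinstance(w, PerturbedOutcome):
        values = w.w
        if nonzero_mask is None:
            nonzero_mask = w.nonzero_mask
    else:
        values = np.asarray(w, dtype=float)
    mask = np.asarray(nonzero_mask, dtype=bool)
    n = values.shape[0]
    if alpha_hat is None:
        alpha_hat = fit_null_quantile(values, design, mask, tau)
    if resid.degenerate:
        return MarginalQuantileResult(tau, alpha_hat, np.nan, np.nan, np.nan)
    residuals = values[mask] - design.covariates[mask] @ alpha_hat
    psi = tau - (residuals < 0)  # psi_tau(0) = tau
    s = float(psi @ resid.c_star[mask]) / np.sqrt(n)
    variance = tau * (1.0 - tau) * resid.quadratic_norm / n
    t = s / np.sqrt(variance)
    p_q = float(2.0 * stats.norm.sf(abs(t)))
    return MarginalQuantileResult(tau, alpha_hat, s, t, p_q)


def score_covariance(
    taus: np.ndarray, resid: ResidualizedCovariate, n: int
) -> ScoreCovariance:
    """Covariance of the rank scores across the quantile grid."""
    taus = np.asarray(taus, dtype=float)
    if resid.degenerate:
        raise ValueError("residualized covariate is degenerate (C*'C* = 0)")
    kernel = np.minimum.outer(taus, taus) - np.outer(taus, taus)
    return ScoreCovariance(taus, kernel * (resid.quadratic_norm / n))


def zinq_marginals(
    y: np.ndarray,
    design: Design,
    grid: np.ndarray,
    *,
    discrete: bool = True,
    logistic_method: str = "lrt",
    seed: int = 0,
) -> ZinqMarginals:
    """All marginal tests for one taxon: perturbation, presence test,
    per-tau rank-score tests and the score covariance.

    Degeneracies never abort: an all-zero taxon yields no tests, a zero-free
    taxon drops the logistic part (its combination weight is r_hat = 0), a
    taxon with fewer than p+2 non-zeros or a variable constant on the
    non-zero subset skips the quantile part.  Everything is flagged.
    """
    y = np.asarray(y, dtype=float)
    n = y.shape[0]
    flags: list[str] = []
    outcome = perturb_counts(y, discrete, seed)
    mask = outcome.nonzero_mask
    m = int(mask.sum())
    r_hat = 1.0 - m / n

    if m == 0:
        return ZinqMarginals(None, [], None, r_hat, 0, n, ["degenerate"])

    logistic: LogisticTestResult | None = None
    if m < n:
        logistic = logistic_presence_test(mask, design, logistic_method)
        if logistic.degenerate:
            flags.append("logistic_degenerate")
        elif not logistic.converged:
            flags.append("logistic_fallback_score")
    else:
        flags.append("zero_free")

    if m < MIN_NONZERO:
        flags.append("low_prevalence")
    if m < design.p + 2:
        flags.append("insufficient_nonzero")
        return ZinqMarginals(logistic, [], None, r_hat, m, n, flags)

    resid = residualize(design, mask)
    if resid.rank_deficient:
        flags.append("rank_deficient")
    if resid.degenerate:
        flags.append("constant_covariate")
        return ZinqMarginals(logistic, [], None, r_hat, m, n, flags)

    quantile = [
        rank_score_test(outcome, design, mask, resid, float(tau)) for tau in grid
    ]
    sigma = score_covariance(np.asarray(grid, dtype=float), resid, n)
    return ZinqMarginals(logistic, quantile, sigma, r_hat, m, n, flags)


def standard_rank_score_baseline(
    y: np.ndarray,
    design: Design,
    grid: np.ndarray,
    seed: int = 0,
    discrete: bool = True,
) -> list[MarginalQuantileResult]:
    """Classical quantile rank-score tests ignoring zero inflation.

    All n observations enter; zeros are perturbed into (0,1) to break ties
    (for discrete data every observation gets the U(0,1) perturbation).  No
    zero-truncation of the design.  On zero-free continuous data this is
    identical to :func:`rank_score_test`.
    """
    y = np.asarray(y, dtype=float)
    rng = np.random.default_rng(seed)
    if discrete:
        w = y + rng.uniform(size=y.shape)
    else:
        w = y.copy()
        zeros = y == 0
        w[zeros] = rng.uniform(size=int(zeros.sum()))
    full_mask = np.ones(y.shape[0], dtype=bool)
    resid = residualize(design, full_mask)
    return [
        rank_score_test(w, design, full_mask, resid, float(tau)) for tau in grid
    ]
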