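"""Combining the logistic and per-quantile p-values into one decision.

Two combiners are offered.  The Cauchy combination uses

    T = r_hat * tan((0.5 - p_L) pi) + sum_k w_k tan((0.5 - p_k) pi),

with the observed zero proportion r_hat as the logistic weight and quantile
weights proportional to (1 - r_hat) * [tau_k I(tau_k<=0.5) +
(1-tau_k) I(tau_k>0.5)], so all weights sum to one and central quantiles
count more than tail ones.  T is standard Cauchy under the null (robust to
the dependence between the marginal tests), so the combined p-value is
0.5 - arctan(T)/pi.

The MinP combiner takes the smallest marginal p-value T_min as its statistic
and calibrates it against the joint null law: the logistic test is
asymptotically independent of the rank scores, and the rank-score vector is
multivariate normal with the known Brownian-bridge covariance, so

    p = 1 - (1 - T_min) * P(all quantile p-values > T_min),

where the joint probability is estimated by resampling score vectors from
N(0, Sigma_hat).

This module also owns the quantile-grid policy and the per-taxon / per-table
orchestration.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import stats

from .normalization import NormalizedTable
from .table_io import Design
from .zinq_core import (
    MIN_NONZERO,
    ScoreCovariance,
    ZinqMarginals,
    zinq_marginals,
)

DEFAULT_GRID = np.array([0.1, 0.25, 0.5, 0.75, 0.9])
RARE_OR_DISCRETE_GRID = np.array([0.25, 0.5, 0.75])


@dataclasses.dataclass
class QuantileGrid:
    taus: np.ndarray
    origin: str  # default_common | default_rare_or_discrete | user

    def __post_init__(self) -> None:
        self.taus = np.asarray(self.taus, dtype=float)
        if self.taus.size < 1:
            raise ValueError("grid must contain at least one quantile level")
        if np.any(self.taus <= 0) or np.any(self.taus >= 1):
            raise ValueError("quantile levels must lie strictly in (0, 1)")
        if np.any(np.diff(self.taus) <= 0):
            raise ValueError("quantile levels must be strictly increasing")


@dataclasses.dataclass
class CauchyWeights:
    r_hat: float
    w: np.ndarray  # per-quantile weights; r_hat + sum(w) == 1


@dataclasses.dataclass
class ZinqResult:
    """Per-taxon outcome of the full test."""

    taxon_id: str
    n: int
    m: int
    r_hat: float
    grid: list[float]
    p_logistic: float
    p_quantile: dict[float, float]
    t_quantile: dict[float, float]
    p_minp: float
    p_cauchy: float
    t_minp: float
    minp_se: float
    flags: list[str]
    seed: int | None = None


def choose_grid(
    m: int, discrete: bool, user_grid: np.ndarray | None = None
) -> QuantileGrid | None:
    """Quantile-grid policy for a taxon with ``m`` non-zero observations.

    A user grid is honored whenever its size is below ``m`` (more quantile
    levels than non-zero measurements makes the marginal results too
    dependent).  Otherwise the conservative five-point default
    {0.1, 0.25, 0.5, 0.75, 0.9} is used for continuous data with m >= 30,
    and the central three-point grid {0.25, 0.5, 0.75} for discrete data or
    smaller m.  Below 15 non-zeros quantile testing is refused (returns
    ``None``; the caller flags the taxon).
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    if user_grid is not None:
        grid = QuantileGrid(user_grid, "user")
        if grid.taus.size >= m:
            raise ValueError(
                f"grid has {grid.taus.size} quantile levels but the taxon has only "
                f"{m} non-zero measurements; the number of quantile levels must be "
                "less than the number of non-zero measurements"
            )
        return grid
    if m < MIN_NONZERO:
        return None
    if discrete or m < 30:
        return QuantileGrid(RARE_OR_DISCRETE_GRID.copy(), "default_rare_or_discrete")
    return QuantileGrid(DEFAULT_GRID.copy(), "default_common")


def cauchy_weights(grid: QuantileGrid | np.ndarray, r_hat: float) -> CauchyWeights:
    """Zero-part weight r_hat plus central-heavy quantile weights summing to 1."""
    if not 0.0 <= r_hat <= 1.0:
        raise ValueError("r_hat must lie in [0, 1]")
    taus = grid.taus if isinstance(grid, QuantileGrid) else np.asarray(grid, float)
    base = np.where(taus <= 0.5, taus, 1.0 - taus)
    w = (1.0 - r_hat) * base / base.sum()
    return CauchyWeights(r_hat, w)


def _tan_half(p: np.ndarray) -> np.ndarray:
    """tan((0.5 - p) * pi) computed as cot(pi p), accurate for tiny p."""
    return 1.0 / np.tan(np.pi * p)


def combine_cauchy(
    p_l: float, p_q: list[float] | np.ndarray, weights: CauchyWeights
) -> float:
    """Weighted Cauchy combination of the logistic and quantile p-values.

    NA components are dropped and the remaining weights renormalized to sum
    to one, which preserves the standard-Cauchy null law.  p-values are
    clipped to [1e-15, 1 - 1e-15] before the tangent transform.
    """
    ps = np.concatenate([[p_l], np.asarray(p_q, dtype=float)])
    ws = np.concatenate([[weights.r_hat], weights.w])
    keep = np.isfinite(ps) & (ws > 0)
    if not keep.any():
        return np.nan
    ps = np.clip(ps[keep], 1e-15, 1.0 - 1e-15)
    ws = ws[keep]
    ws = ws / ws.sum()
    t = float(ws @ _tan_half(ps))
    if t > 1e7:  # asymptote of 0.5 - arctan(t)/pi, avoids cancellation
        return 1.0 / (np.pi * t)
    return float(0.5 - np.arctan(t) / np.pi)


def combine_minp(
    p_l: float,
    p_q: list[float] | np.ndarray,
    sigma: ScoreCovariance | None,
    b: int = 10_000,
    seed: int = 0,
) -> tuple[float, float, float]:
    """MinP combination calibrated by multivariate-normal resampling.

    Returns ``(p_combined, t_minp, mc_se)`` where ``mc_se`` is the binomial
    Monte-Carlo standard error of the estimated joint probability.  With no
    quantile part the combined p-value is the logistic p-value; with a
    missing logistic p-value the (1 - T_min) factor is dropped.
    """
    p_q = np.asarray(p_q, dtype=float)
    p_q = p_q[np.isfinite(p_q)]
    have_l = np.isfinite(p_l)
    if p_q.size == 0:
        return (float(p_l) if have_l else np.nan, float(p_l), 0.0)
    if sigma is None:
        raise ValueError("score covariance required when quantile p-values present")
    if b < 1000:
        raise ValueError("need at least 1000 resampling draws")
    t_min = float(np.min(np.concatenate([[p_l], p_q])) if have_l else p_q.min())
    taus = sigma.taus
    cov = sigma.sigma
    sd = np.sqrt(np.diag(cov))
    # correlation matrix of the scores; jitter guards exact singularity
    corr = cov / np.outer(sd, sd)
    chol = np.linalg.cholesky(corr + 1e-12 * np.eye(len(taus)))
    rng = np.random.default_rng(seed)
    draws = rng.standard_normal((b, len(taus))) @ chol.T
    p_draws = 2.0 * stats.norm.sf(np.abs(draws))
    joint = float(np.mean(np.all(p_draws > t_min, axis=1)))
    mc_se = float(np.sqrt(joint * (1.0 - joint) / b))
    factor = (1.0 - t_min) if have_l else 1.0
    return 1.0 - factor * joint, t_min, mc_se


def zinq_test(
    y: np.ndarray,
    design: Design,
    *,
    discrete: bool = True,
    grid: np.ndarray | None = None,
    logistic_method: str = "lrt",
    minp_draws: int = 10_000,
    seed: int = 0,
    taxon_id: str = "taxon",
) -> ZinqResult:
    """Full zero-inflated quantile test for one taxon.

    Runs the marginal tests then both combiners.  Degenerate taxa are never
    an error: flags record what could not be computed and the corresponding
    p-values are NA.
    """
    y = np.asarray(y, dtype=float)
    m = int(np.sum(y > 0))
    flags: list[str] = []
    chosen = None
    if m >= 1:
        chosen = choose_grid(m, discrete, grid)
    if chosen is None:
        taus = np.array([])
        if 1 <= m < MIN_NONZERO:
            flags.append("low_prevalence")
    else:
        taus = chosen.taus
    marg = zinq_marginals(
        y,
        design,
        taus,
        discrete=discrete,
        logistic_method=logistic_method,
        seed=seed,
    )
    flags = sorted(set(flags) | set(marg.flags))
    p_l = marg.logistic.p_l if marg.logistic is not None else np.nan
    p_q = np.array([q.p_q for q in marg.quantile])
    taus_used = [q.tau for q in marg.quantile]

    finite_q = np.isfinite(p_q).any()
    if not np.isfinite(p_l) and not finite_q:
        p_cauchy = p_minp = t_minp = minp_se = np.nan
    else:
        if finite_q:
            weights = cauchy_weights(np.array(taus_used), marg.r_hat)
            p_cauchy = combine_cauchy(p_l, p_q, weights)
            p_minp, t_minp, minp_se = combine_minp(
                p_l, p_q, marg.sigma, b=minp_draws, seed=seed + 1
            )
        else:
            p_cauchy = p_minp = t_minp = float(p_l)
            minp_se = 0.0
    return ZinqResult(
        taxon_id=taxon_id,
        n=marg.n,
        m=marg.m,
        r_hat=marg.r_hat,
        grid=list(taus_used),
        p_logistic=float(p_l) if np.isfinite(p_l) else np.nan,
        p_quantile={q.tau: q.p_q for q in marg.quantile},
        t_quantile={q.tau: q.t for q in marg.quantile},
        p_minp=p_minp,
        p_cauchy=p_cauchy,
        t_minp=t_minp,
        minp_se=minp_se,
        flags=flags,
        seed=seed,
    )


def zinq_table(
    table: NormalizedTable,
    design: Design,
    *,
    grid: np.ndarray | None = None,
    logistic_method: str = "lrt",
    minp_draws: int = 10_000,
    seed: int = 0,
) -> list[ZinqResult]:
    """Run :func:`zinq_test` on every taxon of a normalized table.

    A single base seed deterministically derives one sub-seed per taxon, so
    repeated runs are bit-identical and independent of chunking.  Per-taxon
    problems are flagged, never fatal.
    """
    if table.n_samples != design.n:
        raise ValueError("table and design disagree on the number of samples")
    taxon_seeds = [
        int(s.generate_state(1)[0] % (2**31))
        for s in np.random.SeedSequence(seed).spawn(table.n_taxa)
    ]
    results = []
    for j, taxon_id in enumerate(table.taxon_ids):
        results.append(
            zinq_test(
                table.values[:, j],
                design,
                discrete=table.discrete,
                grid=grid,
                logistic_method=logistic_method,
                minp_draws=minp_draws,
                seed=taxon_seeds[j],
                taxon_id=taxon_id,
            )
        )
    return results
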