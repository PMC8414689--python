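"""Simulation harness: rejection rates, FPR/TPR, BH adjustment, heterogeneity.

Type I error and power are estimated as rejection fractions over replicated
synthetic datasets, always reported with binomial Monte-Carlo standard
errors so calibration can be judged against sampling noise.  Table-wide
analyses use Benjamini-Hochberg adjusted p-values.  The heterogeneity of an
association is summarized by the coefficient of variation of the variable's
coefficients across the presence model and 19 quantile levels
tau = 0.05, ..., 0.95: near-constant coefficients (a homogeneous shift)
give a small CV, sign-changing or tail-concentrated effects a large one.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .table_io import Design
from .zinq_core import fit_quantile

HETEROGENEITY_GRID = np.round(np.arange(0.05, 0.96, 0.05), 2)  # 19 levels


@dataclasses.dataclass
class SimulationReport:
    """Per-method, per-alpha rejection rates with Monte-Carlo errors."""

    scenario: str
    methods: list[str]
    alphas: list[float]
    rates: np.ndarray  # methods x alphas
    ses: np.ndarray
    n_replicates: int
    n_failed: int = 0
    n_na: int = 0
    seed: int | None = None

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, method in enumerate(self.methods):
            for k, alpha in enumerate(self.alphas):
                rows.append(
                    {
                        "scenario": self.scenario,
                        "method": method,
                        "alpha": alpha,
                        "rate": self.rates[i, k],
                        "mc_se": self.ses[i, k],
                        "replicates": self.n_replicates,
                        "failed": self.n_failed,
                    }
                )
        return pd.DataFrame(rows)


def rejection_rate(pvals: Sequence[float], alpha: float) -> float:
    """Fraction of finite p-values below ``alpha``; NAs never reject."""
    pvals = np.asarray(pvals, dtype=float)
    if pvals.size == 0:
        raise ValueError("empty p-value list")
    finite = pvals[np.isfinite(pvals)]
    if finite.size == 0:
        return 0.0
    return float(np.mean(finite < alpha))


def run_calibration_study(
    generator: Callable[[int], object],
    test: Callable[[object], dict[str, float] | float],
    reps: int,
    alphas: Sequence[float],
    seed: int,
    scenario: str = "calibration",
) -> SimulationReport:
    """Estimate rejection rates of ``test`` over ``reps`` generated datasets.

    ``generator(seed_i)`` produces one dataset; ``test(dataset)`` returns a
    p-value or a dict of p-values keyed by method label.  Per-replicate
    seeds derive deterministically from the master seed, so results are
    reproducible regardless of how replicates would be chunked.  Replicates
    raising an exception are skipped and counted.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    alphas = [float(a) for a in alphas]
    sub_seeds = [
        int(s.generate_state(1)[0] % (2**31))
        for s in np.random.SeedSequence(seed).spawn(reps)
    ]
    collected: dict[str, list[float]] = {}
    n_failed = 0
    for s in sub_seeds:
        try:
            result = test(generator(s))
        except Exception:
            n_failed += 1
            continue
        if not isinstance(result, dict):
            result = {"test": float(result)}
        for label, p in result.items():
            collected.setdefault(label, []).append(float(p))
    methods = list(collected)
    done = reps - n_failed
    rates = np.zeros((len(methods), len(alphas)))
    ses = np.zeros_like(rates)
    n_na = 0
    for i, label in enumerate(methods):
        ps = np.asarray(collected[label])
        n_na += int(np.sum(~np.isfinite(ps)))
        for k, alpha in enumerate(alphas):
            rate = rejection_rate(ps, alpha)
            rates[i, k] = rate
            ses[i, k] = np.sqrt(rate * (1.0 - rate) / max(done, 1))
    return SimulationReport(
        scenario, methods, alphas, rates, ses, done, n_failed, n_na, seed
    )


def _extract_pvals(results: Iterable, which: str) -> np.ndarray:
    out = []
    for r in results:
        if isinstance(r, (int, float, np.floating)):
            out.append(float(r))
        else:
            out.append(getattr(r, f"p_{which}"))
    return np.asarray(out, dtype=float)


def fpr_tpr_table(
    results_null: list,
    results_alt: list,
    alphas: Sequence[float],
    which: str = "cauchy",
) -> SimulationReport:
    """False/true positive rates from null and alternative result tables.

    Inputs are lists of per-taxon results (or bare p-values), or lists of
    such lists for multiple tables, in which case per-table rates are
    averaged.  Degenerate taxa (NA p-values) are excluded from the
    denominators and counted separately.
    """
    if not results_null or not results_alt:
        raise ValueError("need non-empty null and alternative results")

    def tables(results: list) -> list[np.ndarray]:
        if isinstance(results[0], list):
            return [_extract_pvals(t, which) for t in results]
        return [_extract_pvals(results, which)]

    null_tables, alt_tables = tables(results_null), tables(results_alt)
    alphas = [float(a) for a in alphas]
    rates = np.zeros((2, len(alphas)))
    n_na = 0
    for i, group in enumerate((null_tables, alt_tables)):
        for k, alpha in enumerate(alphas):
            per_table = []
            for ps in group:
                finite = ps[np.isfinite(ps)]
                n_na += int(np.sum(~np.isfinite(ps)))
                per_table.append(np.mean(finite < alpha) if finite.size else 0.0)
            rates[i, k] = float(np.mean(per_table))
    n_tables = len(null_tables)
    total = sum(ps.size for ps in null_tables)
    ses = np.sqrt(rates * (1 - rates) / max(total, 1))
    return SimulationReport(
        "fpr_tpr", ["fpr", "tpr"], alphas, rates, ses, n_tables, n_na=n_na // 2
    )


def adjust_bh(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, NAs passed through."""
    pvals = np.asarray(pvals, dtype=float)
    adjusted = np.full(pvals.shape, np.nan)
    finite = np.isfinite(pvals)
    if finite.any():
        adjusted[finite] = multipletests(pvals[finite], method="fdr_bh")[1]
    return adjusted


def coefficient_of_variation(values: Sequence[float]) -> float:
    """|sd / mean| with sample sd (n-1); +inf when the mean is ~0."""
    values = np.asarray(values, dtype=float)
    mean = values.mean()
    if abs(mean) < 1e-12:
        return np.inf
    return float(abs(values.std(ddof=1) / mean))


def heterogeneity_cv(
    y: np.ndarray,
    design: Design,
    cv_grid: np.ndarray = HETEROGENEITY_GRID,
    discrete: bool = True,
    seed: int = 0,
) -> float:
    """Heterogeneity of a taxon's association with the variable of interest.

    Fits the full two-part model (variable included) and returns the
    coefficient of variation of the 20 variable coefficients: the logistic
    gamma_1 plus beta_1(tau) at the 19 grid levels.  Homogeneous
    (location-shift) associations give low values; crossing or
    tail-concentrated effects give high ones.
    """
    import statsmodels.api as sm

    y = np.asarray(y, dtype=float)
    mask = y > 0
    m = int(mask.sum())
    if m < design.p + 3:
        raise ValueError("too few non-zero observations for the quantile fits")
    x = design.full_matrix()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            gamma1 = float(sm.Logit(mask.astype(float), x).fit(disp=0).params[-1])
        except Exception:  # separation: ridge-penalized fallback
            fit = sm.GLM(
                mask.astype(float), x, family=sm.families.Binomial()
            ).fit_regularized(alpha=1e-3, L1_wt=0.0)
            gamma1 = float(fit.params[-1])
    w = y[mask]
    if discrete:
        w = w + np.random.default_rng(seed).uniform(size=w.size)
    xm = x[mask]
    coefs = [gamma1]
    for tau in cv_grid:
        coefs.append(float(fit_quantile(w, xm, float(tau))[-1]))
    return coefficient_of_variation(coefs)
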