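"""Count-table normalization: rarefaction, TSS, CSS and CLR.

Read depth varies between samples for technical, not biological, reasons, so
counts must be made comparable before association testing.  Four strategies
are provided:

* rarefaction — subsample every sample without replacement to a common depth
  (multivariate hypergeometric draw); output stays integer-valued.
* TSS (total sum scaling) — divide by the library size; rows sum to one.
* CSS (cumulative sum scaling) — divide by the cumulative count up to a fixed
  quantile of the sample's positive counts, times a scale constant.
* CLR (centered log-ratio) — log counts centered by their per-sample mean
  log; removes compositional constraints; rows sum to zero.

``rarefy_average`` additionally builds the smoothed "starting data" used to
seed simulations: several independent rarefactions averaged elementwise.

The downstream test treats discrete outcomes (raw counts, rarefied counts)
differently from continuous ones (it perturbs them to break ties), so every
normalized table carries a ``discrete`` flag.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .table_io import TaxonTable


@dataclasses.dataclass
class NormalizedTable:
    """Normalized abundance matrix tagged with its normalization method."""

    values: np.ndarray
    method: str  # none | rarefaction | tss | css | clr
    discrete: bool
    sample_ids: list[str]
    taxon_ids: list[str]

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_taxa(self) -> int:
        return self.values.shape[1]


def as_normalized(table: TaxonTable) -> NormalizedTable:
    """Wrap raw counts unchanged (method "none", discrete)."""
    return NormalizedTable(
        table.counts.astype(float), "none", True,
        list(table.sample_ids), list(table.taxon_ids),
    )


def _check_depth(table: TaxonTable, depth: int) -> None:
    if depth < 1:
        raise ValueError("depth must be a positive integer")
    sizes = table.library_sizes
    short = [sid for sid, s in zip(table.sample_ids, sizes) if s < depth]
    if short:
        raise ValueError(
            f"depth {depth} exceeds library size of samples: {', '.join(short)}"
        )


def rarefy(table: TaxonTable, depth: int, seed: int) -> NormalizedTable:
    """Subsample each sample's reads without replacement to exactly ``depth``.

    Each row is a multivariate-hypergeometric draw from that sample's counts,
    so taxa absent from a sample stay absent.  One seed governs the table.
    """
    _check_depth(table, depth)
    out = _rarefy_once(table.counts, depth, np.random.default_rng(seed))
    return NormalizedTable(
        out.astype(float), "rarefaction", True,
        list(table.sample_ids), list(table.taxon_ids),
    )


def _rarefy_once(counts: np.ndarray, depth: int, rng: np.random.Generator) -> np.ndarray:
    out = np.empty_like(counts)
    for i in range(counts.shape[0]):
        out[i] = rng.multivariate_hypergeometric(counts[i], depth)
    return out


def rarefy_average(
    table: TaxonTable, depth: int, times: int, seed: int
) -> NormalizedTable:
    """Elementwise mean of ``times`` independent rarefactions.

    Averaging removes the sampling noise of any single rarefaction
    (entry variance shrinks like 1/times); used to build smooth starting
    data for simulation, not as a general normalization.
    """
    if times < 1:
        raise ValueError("times must be >= 1")
    _check_depth(table, depth)
    rng = np.random.default_rng(seed)  # one stream: times=1 equals rarefy(seed)
    acc = np.zeros(table.counts.shape, dtype=float)
    for _ in range(times):
        acc += _rarefy_once(table.counts, depth, rng)
    acc /= times
    return NormalizedTable(
        acc, "rarefaction", times == 1,
        list(table.sample_ids), list(table.taxon_ids),
    )


def tss(table: TaxonTable) -> NormalizedTable:
    """Total sum scaling: divide each sample by its library size."""
    sizes = table.library_sizes.astype(float)
    empty = [sid for sid, s in zip(table.sample_ids, sizes) if s == 0]
    if empty:
        raise ValueError(f"zero library size for samples: {', '.join(empty)}")
    values = table.counts / sizes[:, None]
    return NormalizedTable(
        values, "tss", False, list(table.sample_ids), list(table.taxon_ids)
    )


def css(
    table: TaxonTable, quantile: float = 0.5, scale: float = 1000.0
) -> NormalizedTable:
    """Cumulative sum scaling at a fixed quantile of each sample's positives.

    For sample i the scaling factor s_i is the sum of counts y_ij <= q_i,
    where q_i is the ``quantile``-level empirical quantile of the sample's
    positive counts — the lowest positive value at or above the nominal
    level (order-statistic convention, no interpolation).  Values are
    counts / s_i * scale; zeros stay zero.
    """
    if not 0.0 < quantile < 1.0:
        raise ValueError("quantile must be in (0, 1)")
    if scale <= 0:
        raise ValueError("scale must be positive")
    values = np.empty(table.counts.shape, dtype=float)
    for i, sid in enumerate(table.sample_ids):
        row = table.counts[i]
        positives = row[row > 0]
        if positives.size == 0:
            raise ValueError(f"sample {sid!r} has no positive counts")
        q = np.quantile(positives, quantile, method="inverted_cdf")
        s = row[row <= q].sum()
        if s == 0:
            raise ValueError(f"CSS scaling factor is zero for sample {sid!r}")
        values[i] = row / s * scale
    return NormalizedTable(
        values, "css", False, list(table.sample_ids), list(table.taxon_ids)
    )


def clr(
    table: TaxonTable,
    zero_policy: str = "pseudocount",
    pseudocount: float = 0.5,
) -> NormalizedTable:
    """Centered log-ratio transform: log counts minus their per-sample mean.

    Zeros are undefined under the log; ``zero_policy`` selects the handling:

    * ``"error"`` — refuse tables containing zeros;
    * ``"pseudocount"`` — add ``pseudocount`` to every count first (rows
      still sum to zero);
    * ``"pseudocount-keep-zeros"`` — transform with the pseudocount but set
      originally-zero cells back to 0, re-introducing the zero inflation so
      the presence/absence part of downstream tests still operates.
    """
    if zero_policy not in ("error", "pseudocount", "pseudocount-keep-zeros"):
        raise ValueError(f"unknown zero_policy: {zero_policy!r}")
    counts = table.counts.astype(float)
    if zero_policy == "error":
        if np.any(counts == 0):
            raise ValueError("zero counts present; use a pseudocount zero_policy")
        shifted = counts
    else:
        if pseudocount <= 0:
            raise ValueError("pseudocount must be positive")
        shifted = counts + pseudocount
    logs = np.log(shifted)
    values = logs - logs.mean(axis=1, keepdims=True)
    if zero_policy == "pseudocount-keep-zeros":
        values = np.where(counts == 0, 0.0, values)
    return NormalizedTable(
        values, "clr", False, list(table.sample_ids), list(table.taxon_ids)
    )


def normalize(
    table: TaxonTable,
    method: str,
    *,
    depth: int | None = None,
    seed: int = 0,
    css_quantile: float = 0.5,
    css_scale: float = 1000.0,
    clr_zero_policy: str = "pseudocount",
    clr_pseudocount: float = 0.5,
) -> NormalizedTable:
    """Dispatch to one of the normalization strategies by name."""
    if method == "none":
        return as_normalized(table)
    if method == "rarefaction":
        if depth is None:
            depth = int(table.library_sizes.min())
        return rarefy(table, depth, seed)
    if method == "tss":
        return tss(table)
    if method == "css":
        return css(table, css_quantile, css_scale)
    if method == "clr":
        return clr(table, clr_zero_policy, clr_pseudocount)
    raise ValueError(f"unknown normalization method: {method!r}")
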