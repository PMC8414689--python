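"""Reading, validating and aligning taxon count tables and sample metadata.

A taxon table is a samples x taxa matrix of non-negative integer read counts
with unique sample and taxon identifiers.  A design holds the variable of
interest C (binary 0/1 or quantitative) together with the nuisance covariate
matrix Z, whose first column is always the intercept.  Categorical covariates
are expanded to reference-coded indicator columns against the
lexicographically first level, so design matrices are deterministic.

Missing values ("" or "NA") are hard errors, never imputed: the downstream
tests have no missing-data theory.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

_NA_TOKENS = {"", "NA", "NaN", "nan", "N/A", "na"}


class TableValidationError(ValueError):
    """Raised when a count table or metadata table violates its contract."""


@dataclasses.dataclass
class TaxonTable:
    """Raw integer count matrix (n samples x J taxa) with identifiers.

    ``library_sizes`` always equals the row sums of ``counts``.
    """

    counts: np.ndarray
    sample_ids: list[str]
    taxon_ids: list[str]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise TableValidationError("counts must be a 2-d matrix")
        if np.any(self.counts < 0):
            raise TableValidationError("counts must be non-negative")
        if not np.all(self.counts == np.floor(self.counts)):
            raise TableValidationError("counts must be integers")
        self.counts = self.counts.astype(np.int64)
        if len(self.sample_ids) != self.counts.shape[0]:
            raise TableValidationError("sample_ids length mismatch")
        if len(self.taxon_ids) != self.counts.shape[1]:
            raise TableValidationError("taxon_ids length mismatch")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise TableValidationError("duplicate sample IDs")
        if len(set(self.taxon_ids)) != len(self.taxon_ids):
            raise TableValidationError("duplicate taxon IDs")

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def n_taxa(self) -> int:
        return self.counts.shape[1]

    @property
    def library_sizes(self) -> np.ndarray:
        return self.counts.sum(axis=1)


@dataclasses.dataclass
class Design:
    """Variable of interest C plus covariate matrix Z (intercept included).

    ``covariates`` is n x p with a leading all-ones column; ``covariate_names``
    names each Z column (the first is "intercept").
    """

    variable: np.ndarray
    covariates: np.ndarray
    variable_name: str = "C"
    covariate_names: list[str] = dataclasses.field(default_factory=list)
    sample_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.variable = np.asarray(self.variable, dtype=float).ravel()
        self.covariates = np.atleast_2d(np.asarray(self.covariates, dtype=float))
        n = self.variable.shape[0]
        if self.covariates.shape[0] != n:
            raise TableValidationError("variable and covariates disagree on n")
        if np.any(~np.isfinite(self.variable)) or np.any(~np.isfinite(self.covariates)):
            raise TableValidationError("design contains missing/non-finite values")
        if not np.allclose(self.covariates[:, 0], 1.0):
            raise TableValidationError("first covariate column must be the intercept")
        if np.linalg.matrix_rank(self.covariates) < self.covariates.shape[1]:
            raise TableValidationError("covariate matrix Z is rank deficient")
        if not self.covariate_names:
            self.covariate_names = ["intercept"] + [
                f"z{j}" for j in range(1, self.covariates.shape[1])
            ]

    @property
    def n(self) -> int:
        return self.variable.shape[0]

    @property
    def p(self) -> int:
        return self.covariates.shape[1]

    def full_matrix(self) -> np.ndarray:
        """Design matrix X = [Z, C] with the variable of interest last."""
        return np.column_stack([self.covariates, self.variable])

    def subset(self, idx: np.ndarray) -> "Design":
        ids = [self.sample_ids[i] for i in idx] if self.sample_ids is not None else None
        return Design(
            self.variable[idx],
            self.covariates[idx],
            self.variable_name,
            list(self.covariate_names),
            ids,
        )


def _sniff_delimiter(path: str, delimiter: str | None) -> str:
    if delimiter is not None:
        return delimiter
    with open(path) as fh:
        first = fh.readline()
    return "\t" if first.count("\t") >= first.count(",") else ","


def _read_frame(path: str, delimiter: str | None) -> pd.DataFrame:
    sep = _sniff_delimiter(path, delimiter)
    frame = pd.read_csv(path, sep=sep, index_col=0, dtype=str, keep_default_na=False)
    frame.index = frame.index.astype(str)
    return frame


def read_count_table(
    path: str,
    orientation: str = "samples_in_rows",
    delimiter: str | None = None,
) -> TaxonTable:
    """Read a delimited count matrix and validate it into a :class:`TaxonTable`.

    ``orientation`` is ``"samples_in_rows"`` (default) or ``"taxa_in_rows"``;
    the returned table is always samples x taxa.  The delimiter is
    auto-detected between tab and comma unless given explicitly.  Any
    negative, missing or non-numeric cell raises a
    :class:`TableValidationError` naming the offending row and column.
    """
    if orientation not in ("samples_in_rows", "taxa_in_rows"):
        raise ValueError(f"unknown orientation: {orientation!r}")
    frame = _read_frame(path, delimiter)
    values = np.empty(frame.shape, dtype=float)
    for i, row_id in enumerate(frame.index):
        for j, col_id in enumerate(frame.columns):
            cell = frame.iat[i, j].strip()
            if cell in _NA_TOKENS:
                raise TableValidationError(
                    f"missing value at row {row_id!r}, column {col_id!r}"
                )
            try:
                value = float(cell)
            except ValueError as exc:
                raise TableValidationError(
                    f"non-numeric cell {cell!r} at row {row_id!r}, column {col_id!r}"
                ) from exc
            if value < 0:
                raise TableValidationError(
                    f"negative count {cell!r} at row {row_id!r}, column {col_id!r}"
                )
            values[i, j] = value
    row_ids = [str(x) for x in frame.index]
    col_ids = [str(x) for x in frame.columns]
    if orientation == "taxa_in_rows":
        values = values.T
        row_ids, col_ids = col_ids, row_ids
    return TaxonTable(values, sample_ids=row_ids, taxon_ids=col_ids)


def read_metadata(
    path: str,
    variable_name: str,
    covariate_names: list[str] | None = None,
    delimiter: str | None = None,
) -> Design:
    """Read per-sample metadata into a :class:`Design`.

    The variable of interest must be numeric (binary 0/1 or quantitative).
    Numeric covariates are used as-is; categorical covariates are expanded to
    k-1 indicator columns, reference-coded against the lexicographically
    first level.  Missing values raise an error listing the samples affected.
    """
    covariate_names = list(covariate_names or [])
    frame = _read_frame(path, delimiter)
    for name in [variable_name, *covariate_names]:
        if name not in frame.columns:
            raise TableValidationError(f"metadata column {name!r} not found")
        bad = [
            str(sid)
            for sid, cell in zip(frame.index, frame[name])
            if str(cell).strip() in _NA_TOKENS
        ]
        if bad:
            raise TableValidationError(
                f"missing values in column {name!r} for samples: {', '.join(bad)}"
            )

    def _numeric(col: pd.Series) -> np.ndarray | None:
        try:
            return col.astype(float).to_numpy()
        except ValueError:
            return None

    variable = _numeric(frame[variable_name])
    if variable is None:
        raise TableValidationError(
            f"variable column {variable_name!r} must be numeric (binary 0/1 or quantitative)"
        )

    n = frame.shape[0]
    columns: list[np.ndarray] = [np.ones(n)]
    names: list[str] = ["intercept"]
    for name in covariate_names:
        values = _numeric(frame[name])
        if values is not None:
            columns.append(values)
            names.append(name)
            continue
        levels = sorted(frame[name].astype(str).str.strip().unique())
        reference, rest = levels[0], levels[1:]
        logger.debug("covariate %r reference level: %r", name, reference)
        for level in rest:
            columns.append(
                (frame[name].astype(str).str.strip() == level).to_numpy(dtype=float)
            )
            names.append(f"{name}[{level}]")
    return Design(
        variable,
        np.column_stack(columns),
        variable_name=variable_name,
        covariate_names=names,
        sample_ids=[str(x) for x in frame.index],
    )


def align_samples(table: TaxonTable, design: Design) -> tuple[TaxonTable, Design]:
    """Restrict table and design to their common samples, in table order.

    Idempotent; raises if the intersection is empty.  The number of dropped
    samples is logged.
    """
    if design.sample_ids is None:
        raise TableValidationError("design has no sample IDs to align on")
    design_pos = {sid: i for i, sid in enumerate(design.sample_ids)}
    keep_table = [i for i, sid in enumerate(table.sample_ids) if sid in design_pos]
    if not keep_table:
        raise TableValidationError("no samples in common between table and design")
    common_ids = [table.sample_ids[i] for i in keep_table]
    dropped = (table.n_samples - len(keep_table)) + (design.n - len(keep_table))
    if dropped:
        logger.info("align_samples dropped %d non-overlapping samples", dropped)
    new_table = TaxonTable(
        table.counts[keep_table], sample_ids=common_ids, taxon_ids=list(table.taxon_ids)
    )
    new_design = design.subset(np.array([design_pos[sid] for sid in common_ids]))
    return new_table, new_design


def results_frame(results: list, bh_on: str = "cauchy") -> pd.DataFrame:
    """Assemble per-taxon test results into a tidy DataFrame.

    One row per taxon: identifiers, zero proportion, the logistic and per-tau
    p-values, both combined p-values and BH-adjusted values of the combiner
    selected by ``bh_on``.  Taxa skipped for low prevalence keep their row
    with NA p-values and a flag.
    """
    from .evaluation import adjust_bh  # local import to avoid a cycle

    all_taus = sorted({tau for r in results for tau in (r.grid or [])})
    rows = []
    for r in results:
        row: dict[str, object] = {
            "taxon_id": r.taxon_id,
            "n": r.n,
            "n_nonzero": r.m,
            "r_hat": r.r_hat,
            "flags": ";".join(r.flags) if r.flags else "",
            "p_logistic": r.p_logistic,
        }
        for tau in all_taus:
            row[f"p_q_{tau:g}"] = r.p_quantile.get(tau, np.nan)
        row["p_minp"] = r.p_minp
        row["p_cauchy"] = r.p_cauchy
        rows.append(row)
    frame = pd.DataFrame(rows)
    source = frame["p_minp"] if bh_on == "minp" else frame["p_cauchy"]
    frame["p_bh"] = adjust_bh(source.to_numpy())
    return frame


def write_results(results: list, path: str, bh_on: str = "cauchy") -> None:
    """Write per-taxon results as a TSV; round-trips to within 1e-12."""
    frame = results_frame(results, bh_on=bh_on)
    frame.to_csv(path, sep="\t", index=False, float_format="%.17g", na_rep="NA")
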