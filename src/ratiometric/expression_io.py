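"""Expression-matrix loading, isoform aggregation, and gene-inclusion filters.

The central container is :class:`ExpressionMatrix`, a validated genes x
samples grid of non-negative abundances (FPKM or comparable units).  All
pairwise statistics in :mod:`ratiometric.measures` and
:mod:`ratiometric.pairscan` operate on the genes kept by the filters here.

Two filters are provided:

* :func:`filter_by_expression` — the bulk rule: keep a gene when its
  abundance is at or above a floor (default 1 FPKM) in at least a given
  fraction of samples (default 95%).
* :func:`filter_multi_batch` — the single-cell rule: keep a gene when it is
  expressed in all but a small number of cells (default 1) in *every* batch.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "FilterReport",
    "load_expression_table",
    "write_expression_table",
    "aggregate_isoforms",
    "filter_by_expression",
    "filter_multi_batch",
    "load_isoform_map",
]


class ExpressionValidationError(ValueError):
    """Raised when an expression table violates the container invariants."""


@dataclass(frozen=True)
class ExpressionMatrix:
    """Genes x samples grid of finite, non-negative abundances.

    Parameters
    ----------
    gene_ids
        Unique row identifiers.
    sample_ids
        Unique column identifiers.
    values
        2-D float array of shape ``(len(gene_ids), len(sample_ids))``.
    """

    gene_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "gene_ids", tuple(str(g) for g in self.gene_ids))
        object.__setattr__(self, "sample_ids", tuple(str(s) for s in self.sample_ids))
        if values.ndim != 2:
            raise ExpressionValidationError("values must be a 2-D array")
        if values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ExpressionValidationError(
                f"value grid {values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            dupes = _duplicates(self.gene_ids)
            raise ExpressionValidationError(f"duplicate gene ids: {sorted(dupes)}")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            dupes = _duplicates(self.sample_ids)
            raise ExpressionValidationError(f"duplicate sample ids: {sorted(dupes)}")
        if not np.all(np.isfinite(values)):
            raise ExpressionValidationError("values must be finite (no NaN/inf)")
        if np.any(values < 0):
            raise ExpressionValidationError("abundances must be non-negative")

    # -- convenience -------------------------------------------------------
    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def gene(self, gene_id: str) -> np.ndarray:
        """Return one gene's expression vector across samples."""
        try:
            idx = self.gene_ids.index(gene_id)
        except ValueError:
            raise KeyError(f"unknown gene id: {gene_id!r}") from None
        return self.values[idx]

    def subset_genes(self, keep: Sequence[str]) -> "ExpressionMatrix":
        """Row-subset preserving the order given in ``keep``."""
        index = {g: i for i, g in enumerate(self.gene_ids)}
        rows = [index[g] for g in keep]
        return ExpressionMatrix(tuple(keep), self.sample_ids, self.values[rows])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.gene_ids), columns=list(self.sample_ids)
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ExpressionMatrix":
        return cls(
            tuple(map(str, frame.index)),
            tuple(map(str, frame.columns)),
            frame.to_numpy(dtype=float),
        )


@dataclass(frozen=True)
class FilterReport:
    """Record of a gene-inclusion filter run."""

    n_genes_in: int
    n_genes_out: int
    min_value: float
    min_fraction: float
    dropped_gene_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.n_genes_out > self.n_genes_in:
            raise ValueError("n_genes_out cannot exceed n_genes_in")
        if len(self.dropped_gene_ids) != self.n_genes_in - self.n_genes_out:
            raise ValueError("dropped count inconsistent with gene counts")


def _duplicates(items: Iterable[str]) -> set[str]:
    seen: set[str] = set()
    dupes: set[str] = set()
    for item in items:
        if item in seen:
            dupes.add(item)
        seen.add(item)
    return dupes


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def load_expression_table(
    path: str | Path,
    delimiter: str = "\t",
    genes_in_rows: bool = True,
) -> ExpressionMatrix:
    """Read a delimited expression table into an :class:`ExpressionMatrix`.

    The first row and first column hold identifiers; the body must be
    numeric.  A malformed cell raises a parse error naming the offending
    row and column; duplicate identifiers raise a validation error.
    """
    path = Path(path)
    frame = pd.read_csv(path, sep=delimiter, index_col=0, dtype=str)
    if not genes_in_rows:
        frame = frame.T
    numeric = frame.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & frame.notna()
    missing = frame.isna()
    problems = bad | missing
    if problems.to_numpy().any():
        row_pos, col_pos = np.argwhere(problems.to_numpy())[0]
        raise ExpressionValidationError(
            f"non-numeric cell at gene {frame.index[row_pos]!r}, "
            f"sample {frame.columns[col_pos]!r} in {path}"
        )
    return ExpressionMatrix.from_frame(numeric)


def write_expression_table(
    matrix: ExpressionMatrix,
    path: str | Path,
    delimiter: str = "\t",
) -> None:
    """Write a matrix as delimited text with gene ids in the first column."""
    frame = matrix.to_frame()
    frame.index.name = "gene_id"
    frame.to_csv(path, sep=delimiter)


def load_isoform_map(path: str | Path, delimiter: str = "\t") -> dict[str, str]:
    """Read a 2-column isoform-id -> gene-id mapping."""
    frame = pd.read_csv(path, sep=delimiter, header=None, dtype=str, comment="#")
    if frame.shape[1] < 2:
        raise ExpressionValidationError(
            f"isoform map {path} must have two columns (isoform, gene)"
        )
    return dict(zip(frame.iloc[:, 0], frame.iloc[:, 1]))


# ---------------------------------------------------------------------------
# Aggregation and filtering
# ---------------------------------------------------------------------------

def aggregate_isoforms(
    matrix: ExpressionMatrix,
    isoform_to_gene: Mapping[str, str],
    unmapped: str = "error",
) -> ExpressionMatrix:
    """Sum isoform-level rows into gene-level rows.

    Every row id must be present in ``isoform_to_gene``; with
    ``unmapped="drop"`` unmapped isoforms are silently discarded instead.
    Output genes appear in order of first occurrence; sample order is
    preserved; total signal is conserved when the mapping is total.
    """
    if unmapped not in ("error", "drop"):
        raise ValueError("unmapped must be 'error' or 'drop'")
    missing = [g for g in matrix.gene_ids if g not in isoform_to_gene]
    if missing and unmapped == "error":
        raise ExpressionValidationError(
            f"{len(missing)} isoform id(s) missing from the map, e.g. {missing[:5]}"
        )
    order: list[str] = []
    rows: dict[str, np.ndarray] = {}
    for i, isoform in enumerate(matrix.gene_ids):
        gene = isoform_to_gene.get(isoform)
        if gene is None:
            continue
        if gene not in rows:
            rows[gene] = np.zeros(matrix.n_samples)
            order.append(gene)
        rows[gene] = rows[gene] + matrix.values[i]
    if not order:
        raise ExpressionValidationError("no isoforms mapped to any gene")
    values = np.vstack([rows[g] for g in order])
    return ExpressionMatrix(tuple(order), matrix.sample_ids, values)


def filter_by_expression(
    matrix: ExpressionMatrix,
    min_value: float = 1.0,
    min_fraction: float = 0.95,
) -> tuple[ExpressionMatrix, FilterReport]:
    """Keep genes expressed at ``>= min_value`` in ``>= min_fraction`` of samples.

    Both comparisons are inclusive, so a gene at exactly the boundary is
    kept.  With the defaults this is the 1-FPKM / 95%-of-samples rule used
    for bulk panels.
    """
    if not 0.0 <= min_fraction <= 1.0:
        raise ValueError("min_fraction must be in [0, 1]")
    frac = (matrix.values >= min_value).mean(axis=1)
    keep_mask = frac >= min_fraction
    kept = [g for g, k in zip(matrix.gene_ids, keep_mask) if k]
    dropped = tuple(g for g, k in zip(matrix.gene_ids, keep_mask) if not k)
    report = FilterReport(
        n_genes_in=matrix.n_genes,
        n_genes_out=len(kept),
        min_value=min_value,
        min_fraction=min_fraction,
        dropped_gene_ids=dropped,
    )
    return matrix.subset_genes(kept), report


def filter_multi_batch(
    batches: Sequence[ExpressionMatrix],
    allowed_misses_per_batch: int = 1,
    expression_floor: float = 1.0,
) -> tuple[list[str], list[ExpressionMatrix]]:
    """Single-cell gene filter across batches.

    A gene is kept iff in *every* batch it is expressed (value >=
    ``expression_floor``) in at least ``batch size - allowed_misses_per_batch``
    cells.  With two batches of 10 cells and one allowed miss per batch this
    keeps genes expressed in at least 18 of the 20 cells.

    Returns the merged kept gene list (lexicographic) and the batches
    subset to those genes.
    """
    if not batches:
        raise ValueError("at least one batch is required")
    universes = [set(b.gene_ids) for b in batches]
    shared = set.intersection(*universes)
    if not shared:
        raise ExpressionValidationError("batches have disjoint gene ids")
    kept: list[str] = []
    for gene in sorted(shared):
        ok = True
        for batch in batches:
            expressed = int(np.sum(batch.gene(gene) >= expression_floor))
            if expressed < batch.n_samples - allowed_misses_per_batch:
                ok = False
                break
        if ok:
            kept.append(gene)
    return kept, [b.subset_genes(kept) for b in batches]
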