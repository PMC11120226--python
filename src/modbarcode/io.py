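"""Expression-matrix containers, delimited-text I/O, and median centering.

The universal currency of the package is a genes x samples numeric table.
Two thin dataclasses wrap a :class:`pandas.DataFrame`:

* :class:`ExpressionMatrix` — raw values on a declared scale (``linear`` for
  TPM-like abundances, ``log2`` for logged intensities).
* :class:`CenteredMatrix` — per-gene log2 fold-change versus the gene's
  median (or mean), with the per-gene medians and averages retained so they
  can be written out alongside the centered values.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

Scale = Literal["linear", "log2"]

__all__ = [
    "ExpressionMatrix",
    "CenteredMatrix",
    "read_expression",
    "write_expression",
    "median_center",
    "filter_low_expression",
    "as_frame",
]


class ExpressionIOError(ValueError):
    """Raised for malformed expression tables."""


def _check_axis_unique(index: pd.Index, what: str) -> None:
    if index.has_duplicates:
        dupes = index[index.duplicated()].unique().tolist()[:5]
        raise ExpressionIOError(f"duplicate {what}: {dupes}")


@dataclass
class ExpressionMatrix:
    """Genes x samples expression values on a declared scale.

    Parameters
    ----------
    data : pandas.DataFrame
        Numeric table with gene ids as index and sample ids as columns.
    scale : {"linear", "log2"}
        ``linear`` values (TPM, normalized counts, linear intensities) must
        be non-negative; ``log2`` values may be any finite number.
    """

    data: pd.DataFrame
    scale: Scale = "linear"

    def __post_init__(self) -> None:
        if not isinstance(self.data, pd.DataFrame):
            self.data = pd.DataFrame(self.data)
        if self.data.shape[0] == 0 or self.data.shape[1] == 0:
            raise ExpressionIOError("empty expression matrix")
        if self.scale not in ("linear", "log2"):
            raise ExpressionIOError(f"unknown scale {self.scale!r}")
        _check_axis_unique(self.data.index, "gene ids")
        _check_axis_unique(self.data.columns, "sample ids")
        self.data.index = self.data.index.astype(str)
        self.data.columns = self.data.columns.astype(str)
        values = self.data.to_numpy(dtype=float, copy=False)
        if not np.isfinite(values).all():
            g, s = np.argwhere(~np.isfinite(values))[0]
            raise ExpressionIOError(
                f"non-finite value at gene {self.data.index[g]!r}, "
                f"sample {self.data.columns[s]!r}"
            )
        if self.scale == "linear" and (values < 0).any():
            g, s = np.argwhere(values < 0)[0]
            raise ExpressionIOError(
                f"negative linear-scale value at gene {self.data.index[g]!r}, "
                f"sample {self.data.columns[s]!r}"
            )

    @property
    def gene_ids(self) -> list[str]:
        return self.data.index.tolist()

    @property
    def sample_ids(self) -> list[str]:
        return self.data.columns.tolist()

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def log2_values(self, pseudo: float = 1.0) -> pd.DataFrame:
        """Values on log2 scale; linear data is transformed as log2(x + pseudo)."""
        if self.scale == "log2":
            return self.data
        if pseudo <= 0 and (self.data.to_numpy() <= 0).any():
            raise ExpressionIOError("pseudo must be > 0 for linear data with zeros")
        return np.log2(self.data + pseudo)


@dataclass
class CenteredMatrix:
    """Per-gene centered log2 fold-change values plus the centering statistics.

    ``data`` holds log2(value) - per-gene median (or mean); ``medians`` and
    ``averages`` are the per-gene statistics of the *logged* values before
    centering, kept as separate columns on export for spreadsheet use.
    """

    data: pd.DataFrame
    medians: pd.Series
    averages: pd.Series
    center: Literal["median", "mean"] = "median"

    def __post_init__(self) -> None:
        _check_axis_unique(self.data.index, "gene ids")
        _check_axis_unique(self.data.columns, "sample ids")
        for name, stat in (("medians", self.medians), ("averages", self.averages)):
            if len(stat) != self.data.shape[0]:
                raise ExpressionIOError(f"{name} length != number of genes")

    @property
    def gene_ids(self) -> list[str]:
        return self.data.index.tolist()

    @property
    def sample_ids(self) -> list[str]:
        return self.data.columns.tolist()

    def to_frame(self, include_stats: bool = True) -> pd.DataFrame:
        """Exportable table; centering statistics prepended as columns."""
        if not include_stats:
            return self.data.copy()
        out = self.data.copy()
        out.insert(0, "median", self.medians)
        out.insert(1, "average", self.averages)
        return out


def as_frame(m: ExpressionMatrix | CenteredMatrix | pd.DataFrame) -> pd.DataFrame:
    """Extract the genes x samples DataFrame from any accepted container."""
    if isinstance(m, (ExpressionMatrix, CenteredMatrix)):
        return m.data
    return m


def _sep_for(path: Path, sep: str | None) -> str:
    if sep is not None:
        return sep
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_expression(
    path: str | Path, scale: Scale = "linear", sep: str | None = None
) -> ExpressionMatrix:
    """Read a delimited expression table (gene rows, sample columns, header row).

    Duplicate gene ids are collapsed by keeping the row with the highest
    average value (the better-measured probe/transcript); the collapse is
    logged. Non-numeric or missing cells raise a parse error naming the
    offending row and column.
    """
    path = Path(path)
    sep = _sep_for(path, sep)
    try:
        raw = pd.read_csv(path, sep=sep, index_col=0, header=0, dtype=str)
    except pd.errors.EmptyDataError as exc:
        raise ExpressionIOError(f"{path}: empty file") from exc
    except pd.errors.ParserError as exc:
        raise ExpressionIOError(f"{path}: malformed table ({exc})") from exc
    if raw.shape[0] == 0 or raw.shape[1] == 0:
        raise ExpressionIOError(f"{path}: empty expression matrix")
    coerced = raw.apply(pd.to_numeric, errors="coerce")
    bad = ~np.isfinite(coerced.to_numpy(dtype=float))
    if bad.any():
        g, s = np.argwhere(bad)[0]
        cell = raw.iat[g, s]
        raise ExpressionIOError(
            f"{path}: non-numeric cell {cell!r} at gene {raw.index[g]!r}, "
            f"column {raw.columns[s]!r}"
        )
    # correctly-rounded float conversion so write -> read is bit-exact
    numeric = pd.DataFrame(
        raw.to_numpy(dtype=float), index=raw.index, columns=raw.columns
    )
    if numeric.index.has_duplicates:
        means = numeric.mean(axis=1)
        order = np.argsort(-means.to_numpy(), kind="stable")
        deduped = numeric.iloc[order]
        dropped = int(deduped.index.duplicated().sum())
        numeric = deduped[~deduped.index.duplicated()].reindex(
            raw.index.drop_duplicates()
        )
        logger.warning(
            "%s: collapsed %d duplicate gene id rows (kept highest-average row)",
            path,
            dropped,
        )
    return ExpressionMatrix(numeric, scale=scale)


def write_expression(
    m: ExpressionMatrix | CenteredMatrix,
    path: str | Path,
    sep: str | None = None,
    include_stats: bool = False,
) -> None:
    """Write a matrix as delimited text; round-trips to full precision."""
    path = Path(path)
    sep = _sep_for(path, sep)
    frame = m.to_frame(include_stats) if isinstance(m, CenteredMatrix) else m.data
    frame.to_csv(path, sep=sep, index_label="gene_id", float_format="%.17g")


def median_center(
    m: ExpressionMatrix,
    pseudo: float = 1.0,
    center: Literal["median", "mean"] = "median",
) -> CenteredMatrix:
    """Center each gene on log2 scale, yielding log2 fold-change vs the gene median.

    Linear-scale input is first transformed to ``log2(value + pseudo)``.
    The per-gene medians and averages of the logged values are retained so
    the centered table can be exported with its centering statistics.
    """
    if pseudo <= 0:
        raise ValueError("pseudo must be positive")
    if m.data.shape[1] == 0:
        raise ExpressionIOError("cannot center a zero-sample matrix")
    logged = m.log2_values(pseudo)
    medians = logged.median(axis=1)
    averages = logged.mean(axis=1)
    reference = medians if center == "median" else averages
    centered = logged.sub(reference, axis=0)
    return CenteredMatrix(centered, medians=medians, averages=averages, center=center)


def filter_low_expression(
    m: ExpressionMatrix, quantile: float
) -> ExpressionMatrix:
    """Drop the bottom ``quantile`` of genes by mean expression.

    Low-absolute-expression genes correlate poorly with everything and only
    add noise to module building; this prefilter removes them before the
    correlation stage.
    """
    if not 0 <= quantile < 1:
        raise ValueError("quantile must be in [0, 1)")
    if quantile == 0:
        return m
    means = m.data.mean(axis=1)
    cutoff = means.quantile(quantile)
    keep = means > cutoff
    if keep.sum() == 0:  # all-tied degenerate case
        warnings.warn("low-expression prefilter would drop all genes; skipped")
        return m
    return ExpressionMatrix(m.data.loc[keep], scale=m.scale)
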