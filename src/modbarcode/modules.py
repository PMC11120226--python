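"""Hierarchical clustering of sparsified neighbourhood rows into gene modules.

Each gene's row of the sparsified correlation matrix is its neighbourhood
profile. Genes are clustered on the distance d(i, j) = 1 - r(row_i, row_j)
(Pearson correlation between the two neighbourhood rows), the tree is cut
at a fixed height (default 0.8 on the [0, 2] correlation-distance scale),
and labels are renumbered by decreasing module size. Every gene lands in
exactly one module; genes whose neighbourhood row is degenerate (all zero,
i.e. zero rank variance upstream) are parked in the reserved module 0.

Clustering raw expression rows directly is retained as the rejected
baseline (`baseline_modules`) for regression testing: it conflates
expression level with co-expression and produces markedly poorer modules.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage as scipy_linkage
from scipy.spatial.distance import pdist, squareform

from .correlation import SparsifiedMatrix
from .io import CenteredMatrix, ExpressionMatrix, as_frame

logger = logging.getLogger(__name__)

UNCLUSTERED = 0

__all__ = [
    "ModuleAssignment",
    "build_modules",
    "baseline_modules",
    "write_assignment",
    "read_assignment",
]


@dataclass
class ModuleAssignment:
    """One-module-per-gene partition with size-ordered integer labels.

    Module ids are contiguous integers 1..M ordered by decreasing size
    (ties broken by the lexicographically smallest member gene id); id 0 is
    reserved for unclustered/degenerate genes. Modules smaller than
    ``min_report_size`` stay in the assignment but are excluded from
    module-level reports by default.
    """

    modules: pd.Series  # gene id -> int module id
    height: float | None = None
    min_report_size: int = 25

    def __post_init__(self) -> None:
        self.modules = self.modules.astype(int)
        self.modules.index = self.modules.index.astype(str)
        if self.modules.index.has_duplicates:
            raise ValueError("duplicate gene ids in module assignment")

    @property
    def gene_ids(self) -> list[str]:
        return self.modules.index.tolist()

    @property
    def module_sizes(self) -> pd.Series:
        return self.modules.value_counts().sort_index()

    @property
    def module_ids(self) -> list[int]:
        return sorted(set(self.modules) - {UNCLUSTERED})

    def reported_modules(self, min_size: int | None = None) -> list[int]:
        """Module ids large enough for module-level analyses."""
        floor = self.min_report_size if min_size is None else min_size
        sizes = self.module_sizes
        return [m for m in self.module_ids if sizes[m] >= floor]

    def members(self, module_id: int) -> list[str]:
        return self.modules.index[self.modules == module_id].tolist()

    def subset(self, gene_ids) -> "ModuleAssignment":
        present = self.modules.index.intersection(pd.Index(gene_ids))
        return ModuleAssignment(
            self.modules.loc[present],
            height=self.height,
            min_report_size=self.min_report_size,
        )


def _renumber_by_size(labels: pd.Series) -> pd.Series:
    """Relabel clusters as 1..M by decreasing size, ties by smallest member id."""
    out = pd.Series(UNCLUSTERED, index=labels.index, dtype=int)
    keyed = []
    for lab, members in labels.groupby(labels):
        if lab == UNCLUSTERED:
            continue
        keyed.append((-len(members), min(members.index), lab))
    for new_id, (_, _, lab) in enumerate(sorted(keyed), start=1):
        out[labels == lab] = new_id
    return out


def build_modules(
    s: SparsifiedMatrix,
    height: float = 0.8,
    linkage: str = "average",
) -> ModuleAssignment:
    """Cluster sparsified neighbourhood rows and cut the tree into modules."""
    if height <= 0:
        raise ValueError("cut height must be positive")
    X = s.data.to_numpy(dtype=float)
    genes = s.data.index
    degenerate = X.std(axis=1) == 0
    if degenerate.any():
        logger.warning(
            "%d degenerate (all-zero) rows assigned to unclustered module 0",
            int(degenerate.sum()),
        )
    labels = pd.Series(UNCLUSTERED, index=genes, dtype=int)
    active = ~degenerate
    n_active = int(active.sum())
    if n_active == 1:
        labels[active] = 1
    elif n_active > 1:
        rows = X[active]
        dist = pdist(rows, metric="correlation")  # 1 - Pearson r of rows
        np.clip(dist, 0.0, 2.0, out=dist)
        tree = scipy_linkage(dist, method=linkage)
        cut = fcluster(tree, t=height, criterion="distance")
        labels.loc[genes[active]] = cut
    return ModuleAssignment(_renumber_by_size(labels), height=height)


def baseline_modules(
    m: ExpressionMatrix | CenteredMatrix | pd.DataFrame,
    n_modules: int,
    metric: str = "euclidean",
    linkage: str = "average",
) -> ModuleAssignment:
    """Cluster raw expression rows directly (the rejected baseline).

    Straightforward hierarchical clustering of genes on the expression
    values — Euclidean distance by default, as naive tooling defaults would
    give — cut to a matched number of modules. Kept so the superiority of
    the sparsified-correlation route stays under regression test.
    """
    frame = (
        m.log2_values() if isinstance(m, ExpressionMatrix) and m.scale == "linear"
        else as_frame(m)
    )
    X = frame.to_numpy(dtype=float)
    if n_modules < 1:
        raise ValueError("n_modules must be >= 1")
    dist = pdist(X, metric=metric)
    if metric == "correlation":
        dist = np.clip(np.nan_to_num(dist, nan=1.0), 0.0, 2.0)
    tree = scipy_linkage(dist, method=linkage)
    cut = fcluster(tree, t=n_modules, criterion="maxclust")
    labels = pd.Series(cut, index=frame.index)
    return ModuleAssignment(_renumber_by_size(labels))


def write_assignment(a: ModuleAssignment, path: str | Path) -> None:
    frame = a.modules.rename("module_id").rename_axis("gene_id").reset_index()
    frame.to_csv(path, sep="\t", index=False)


def read_assignment(
    path: str | Path,
    validate_against: ExpressionMatrix | CenteredMatrix | pd.DataFrame | None = None,
    min_report_size: int = 25,
) -> tuple[ModuleAssignment, list[str]]:
    """Read a two-column (gene_id, module_id) TSV.

    Returns the assignment plus a warning list of genes absent from
    ``validate_against`` (they stay in the table; downstream steps simply
    cannot use them).
    """
    frame = pd.read_csv(path, sep="\t")
    if frame.shape[0] == 0 or frame.shape[1] < 2:
        raise ValueError(f"{path}: empty or malformed assignment table")
    gene_col, module_col = frame.columns[:2]
    series = pd.Series(
        frame[module_col].to_numpy(), index=frame[gene_col].astype(str)
    )
    assignment = ModuleAssignment(series, min_report_size=min_report_size)
    missing: list[str] = []
    if validate_against is not None:
        universe = as_frame(validate_against).index
        missing = [g for g in assignment.gene_ids if g not in universe]
        if missing:
            logger.warning(
                "%d assignment genes absent from the expression matrix", len(missing)
            )
    return assignment, missing
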