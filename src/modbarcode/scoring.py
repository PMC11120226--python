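"""Collapse modules to per-sample scores via the iterative fixed-point median.

A module's collapsed score is a single value per sample summarizing its
members. Starting from all members, the procedure alternates (1) score =
per-sample median of the currently retained members' centered values and
(2) retained = members whose Spearman correlation with the score exceeds
``r_keep`` (default 0.6, strict inequality), until the retained set repeats
— the fixed point. The final medians are the collapsed values. Retained
sets can in principle oscillate, so every visited set is remembered and a
revisit terminates the loop with ``converged=False``. If a step would empty
the retained set (a module that simply does not cohere in this dataset, a
routine occurrence when transferring modules to foreign data), the plain
median over all members is returned, flagged as unconverged, so downstream
steps always have a score to work with.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .io import CenteredMatrix
from .modules import UNCLUSTERED, ModuleAssignment

logger = logging.getLogger(__name__)

__all__ = [
    "ModuleScore",
    "CollapsedScores",
    "collapse_module",
    "collapse_all",
    "gene_module_correlation",
]


def _standardized_ranks(values: np.ndarray) -> np.ndarray:
    """Rank rows (average ties), center and L2-normalize; zero-variance rows -> 0."""
    ranks = rankdata(values, axis=1, method="average")
    centered = ranks - ranks.mean(axis=1, keepdims=True)
    norms = np.sqrt((centered**2).sum(axis=1))
    safe = np.where(norms == 0, 1.0, norms)
    z = centered / safe[:, None]
    z[norms == 0] = 0.0
    return z


def spearman_rows_vs_rows(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Spearman rho between every row of ``a`` and every row of ``b``."""
    return np.clip(_standardized_ranks(a) @ _standardized_ranks(b).T, -1.0, 1.0)


@dataclass
class ModuleScore:
    """One module's collapsed score row and its convergence diagnostics."""

    score: pd.Series
    retained: list[str]
    converged: bool
    iterations: int


@dataclass
class CollapsedScores:
    """Modules x samples collapsed-score matrix with per-module diagnostics."""

    scores: pd.DataFrame  # module id (index) x sample id
    retained_genes: dict[int, list[str]] = field(default_factory=dict)
    converged: dict[int, bool] = field(default_factory=dict)
    iterations: dict[int, int] = field(default_factory=dict)

    @property
    def module_ids(self) -> list[int]:
        return self.scores.index.tolist()

    @property
    def sample_ids(self) -> list[str]:
        return self.scores.columns.tolist()

    def retained_frame(self) -> pd.DataFrame:
        rows = [
            {"module_id": mid, "gene_id": g}
            for mid, genes in self.retained_genes.items()
            for g in genes
        ]
        return pd.DataFrame(rows, columns=["module_id", "gene_id"])


def collapse_module(
    cm: CenteredMatrix,
    members: Sequence[str],
    r_keep: float = 0.6,
    max_iter: int = 50,
) -> ModuleScore:
    """Collapse one module to a per-sample score by the fixed-point median.

    The fixed point is exact retained-set equality between successive
    iterations; visited-set cycle detection guarantees termination even if
    the retained set oscillates.
    """
    if len(members) == 0:
        raise ValueError("module has no members")
    present = [g for g in members if g in cm.data.index]
    dropped = len(members) - len(present)
    if dropped:
        logger.warning("%d module members absent from the matrix, dropped", dropped)
    if not present:
        raise ValueError("no module member is present in the matrix")
    if cm.data.shape[1] < 3:
        raise ValueError("collapse requires at least 3 samples")

    values = cm.data.loc[present].to_numpy(dtype=float)
    index = {g: i for i, g in enumerate(present)}
    samples = cm.data.columns

    def median_of(genes: tuple[str, ...]) -> np.ndarray:
        rows = values[[index[g] for g in genes]]
        return np.median(rows, axis=0)

    retained: tuple[str, ...] = tuple(sorted(present))
    visited = {retained}
    converged = False
    iterations = 0
    for iterations in range(1, max_iter + 1):
        score = median_of(retained)
        rho = spearman_rows_vs_rows(values, score[None, :])[:, 0]
        new = tuple(g for g in sorted(present) if rho[index[g]] > r_keep)
        if len(new) == 0:
            # module does not cohere here: plain median over all members
            return ModuleScore(
                score=pd.Series(median_of(tuple(sorted(present))), index=samples),
                retained=sorted(present),
                converged=False,
                iterations=iterations,
            )
        if new == retained:
            converged = True
            break
        if new in visited:  # oscillation
            retained = new
            break
        visited.add(new)
        retained = new
    return ModuleScore(
        score=pd.Series(median_of(retained), index=samples),
        retained=list(retained),
        converged=converged,
        iterations=iterations,
    )


def collapse_all(
    cm: CenteredMatrix,
    a: ModuleAssignment,
    r_keep: float = 0.6,
    max_iter: int = 50,
    min_size: int = 1,
) -> CollapsedScores:
    """Collapse every module of an assignment (module 0 is never collapsed).

    Per-module failures (e.g. no member present in the matrix) are recorded
    by omitting the module, not by aborting the whole run.
    """
    sizes = a.module_sizes
    module_ids = [m for m in a.module_ids if sizes[m] >= min_size]
    rows, retained, converged, iters = {}, {}, {}, {}
    for mid in module_ids:
        try:
            ms = collapse_module(cm, a.members(mid), r_keep=r_keep, max_iter=max_iter)
        except ValueError as exc:
            logger.warning("module %d skipped: %s", mid, exc)
            continue
        rows[mid] = ms.score
        retained[mid] = ms.retained
        converged[mid] = ms.converged
        iters[mid] = ms.iterations
    scores = (
        pd.DataFrame(rows).T.reindex(list(rows))
        if rows
        else pd.DataFrame(index=pd.Index([], dtype=int), columns=cm.data.columns)
    )
    scores.index.name = "module_id"
    return CollapsedScores(
        scores=scores, retained_genes=retained, converged=converged, iterations=iters
    )


def gene_module_correlation(
    cm: CenteredMatrix,
    cs: CollapsedScores,
    assignment: ModuleAssignment | None = None,
) -> pd.DataFrame:
    """Spearman rho between every gene's centered profile and every module score.

    The full genes x modules table lets a user spot genes that correlate
    highly — positively or negatively — with several modules, i.e. plausible
    multi-module memberships. When an assignment is supplied, each gene's
    own module and its rho to it are added as dedicated columns.
    """
    if list(cm.data.columns) != list(cs.scores.columns):
        raise ValueError("sample ids of the matrix and the scores differ")
    if cs.scores.shape[0] == 0:
        return pd.DataFrame(index=cm.data.index)
    rho = spearman_rows_vs_rows(
        cm.data.to_numpy(dtype=float), cs.scores.to_numpy(dtype=float)
    )
    table = pd.DataFrame(rho, index=cm.data.index, columns=cs.scores.index)
    if assignment is not None:
        own = assignment.modules.reindex(table.index)
        table["own_module"] = own.fillna(UNCLUSTERED).astype(int)
        own_rho = np.full(len(table), np.nan)
        col_pos = {mid: j for j, mid in enumerate(cs.scores.index)}
        for i, mid in enumerate(table["own_module"].to_numpy()):
            if mid in col_pos:
                own_rho[i] = rho[i, col_pos[mid]]
        table["own_module_rho"] = own_rho
    return table
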