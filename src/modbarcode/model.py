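"""Model/Results facade over the module-discovery pipeline.

`CoexpressionModules` is the model: an expression cohort plus the
discovery hyperparameters. `fit()` runs correlation -> sparsification ->
clustering and returns a `ModuleResults` object that carries the module
assignment and hands out the downstream products — collapsed scores,
gene-module correlation tables, transfer to foreign datasets, barcodes,
and exports — so a typical analysis reads::

    model = CoexpressionModules.from_file("tpm.tsv", scale="linear")
    res = model.fit()
    print(res.summary())
    scores = res.collapse()
    transferred = res.transfer(foreign)
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from . import export as _export
from .barcode import BarcodeTable, discretize, nmf_subtype
from .correlation import CorrelationMatrix, SparsifiedMatrix, sparsify, spearman_matrix
from .io import (
    CenteredMatrix,
    ExpressionMatrix,
    Scale,
    filter_low_expression,
    median_center,
    read_expression,
)
from .modules import ModuleAssignment, build_modules
from .scoring import CollapsedScores, collapse_all, gene_module_correlation
from .transfer import TransferResult, transfer_modules

__all__ = ["CoexpressionModules", "ModuleResults"]


class CoexpressionModules:
    """Co-expression module model for a genes x samples expression cohort.

    Parameters
    ----------
    data : ExpressionMatrix or DataFrame
        The gold-standard cohort the modules are derived from.
    keep_fraction : float
        Per-gene fraction of highest correlations retained (default 0.05).
    height : float
        Tree-cut height on the correlation-distance dendrogram (default 0.8).
    linkage : str
        Hierarchical linkage method (default ``average``).
    min_report_size : int
        Smallest module size included in module-level reports (default 25).
    prefilter_quantile : float or None
        If set, drop this bottom quantile of genes by mean expression
        before the correlation stage.
    """

    def __init__(
        self,
        data: ExpressionMatrix | pd.DataFrame,
        scale: Scale = "linear",
        keep_fraction: float = 0.05,
        height: float = 0.8,
        linkage: str = "average",
        min_report_size: int = 25,
        prefilter_quantile: float | None = None,
        pseudo: float = 1.0,
    ) -> None:
        if not isinstance(data, ExpressionMatrix):
            data = ExpressionMatrix(data, scale=scale)
        self.data = data
        self.keep_fraction = keep_fraction
        self.height = height
        self.linkage = linkage
        self.min_report_size = min_report_size
        self.prefilter_quantile = prefilter_quantile
        self.pseudo = pseudo

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame, scale: Scale = "linear", **kwargs):
        return cls(frame, scale=scale, **kwargs)

    @classmethod
    def from_file(cls, path: str | Path, scale: Scale = "linear", **kwargs):
        return cls(read_expression(path, scale=scale), **kwargs)

    def fit(self) -> "ModuleResults":
        """Discover modules: Spearman matrix, top-fraction sparsify, cluster, cut."""
        data = self.data
        if self.prefilter_quantile:
            data = filter_low_expression(data, self.prefilter_quantile)
        corr = spearman_matrix(data)
        sparse = sparsify(corr, self.keep_fraction)
        assignment = build_modules(sparse, height=self.height, linkage=self.linkage)
        assignment.min_report_size = self.min_report_size
        centered = median_center(data, pseudo=self.pseudo)
        return ModuleResults(
            model=self,
            assignment=assignment,
            centered=centered,
            correlation=corr,
            sparsified=sparse,
        )


@dataclass
class ModuleResults:
    """Fitted module structure plus lazy access to every downstream product."""

    model: CoexpressionModules
    assignment: ModuleAssignment
    centered: CenteredMatrix
    correlation: CorrelationMatrix | None = None
    sparsified: SparsifiedMatrix | None = None
    _scores: CollapsedScores | None = None

    def collapse(self, r_keep: float = 0.6, max_iter: int = 50) -> CollapsedScores:
        """Collapsed module scores of the fitting cohort (cached at defaults)."""
        if r_keep == 0.6 and max_iter == 50:
            if self._scores is None:
                self._scores = collapse_all(
                    self.centered, self.assignment, r_keep=r_keep, max_iter=max_iter
                )
            return self._scores
        return collapse_all(
            self.centered, self.assignment, r_keep=r_keep, max_iter=max_iter
        )

    def gene_module_correlation(self) -> pd.DataFrame:
        return gene_module_correlation(self.centered, self.collapse(), self.assignment)

    def transfer(
        self,
        foreign: ExpressionMatrix | CenteredMatrix,
        r_keep: float = 0.6,
        with_reference: bool = True,
    ) -> TransferResult:
        """Apply the fitted modules to a foreign dataset with coherence QC."""
        reference = self.model.data if with_reference else None
        return transfer_modules(
            foreign, self.assignment, reference=reference, r_keep=r_keep
        )

    def barcodes(
        self, z_hi: float = 0.5, modules: Sequence[int] | None = None
    ) -> BarcodeTable:
        if modules is None:
            modules = [
                m
                for m in self.assignment.reported_modules()
                if m in self.collapse().module_ids
            ]
        return discretize(self.collapse(), z_hi=z_hi, modules=modules)

    def subtype(self, k: int, labels=None, seed: int = 0):
        return nmf_subtype(self.collapse(), k=k, labels=labels, seed=seed)

    def to_gmt(self, path: str | Path, prefix: str = "MODULE") -> int:
        return _export.modules_to_gmt(
            self.assignment, path, prefix=prefix, min_size=self.assignment.min_report_size
        )

    def to_workbook(self, path: str | Path, **kwargs) -> None:
        _export.colorized_workbook(self.centered, self.assignment, path, **kwargs)

    def to_heatmap(self, path: str | Path, **kwargs) -> None:
        _export.heatmap_png(self.centered, self.assignment, path, **kwargs)

    def summary(self) -> str:
        """Human-readable fit summary in the style of a model results table."""
        sizes = self.assignment.module_sizes
        reported = self.assignment.reported_modules()
        n_genes, n_samples = self.model.data.shape
        lines = [
            "Co-expression module discovery",
            "=" * 46,
            f"{'Genes':<28}{n_genes:>18}",
            f"{'Samples':<28}{n_samples:>18}",
            f"{'Keep fraction':<28}{self.model.keep_fraction:>18}",
            f"{'Cut height':<28}{self.model.height:>18}",
            f"{'Linkage':<28}{self.model.linkage:>18}",
            f"{'Modules (total)':<28}{len(self.assignment.module_ids):>18}",
            f"{'Modules (>= {0} genes)'.format(self.assignment.min_report_size):<28}"
            f"{len(reported):>18}",
            f"{'Unclustered genes':<28}{int(sizes.get(0, 0)):>18}",
            "-" * 46,
            f"{'module':>8}{'size':>8}{'collapsed':>12}{'converged':>12}",
        ]
        scores = self.collapse()
        for mid in reported:
            collapsed = mid in scores.module_ids
            conv = scores.converged.get(mid, False)
            lines.append(
                f"{mid:>8}{int(sizes[mid]):>8}{str(collapsed):>12}{str(conv):>12}"
            )
        lines.append("=" * 46)
        return "\n".join(lines)
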