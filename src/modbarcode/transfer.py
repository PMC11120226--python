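"""Apply gold-standard modules to a foreign dataset and quantify coherence.

Modules derived from a large, uniformly processed reference cohort can be
re-used on smaller, lower-quality datasets (FFPE RNAseq, microarray,
pseudo-bulk single cell). Transfer restricts each module to the genes the
foreign platform measures, re-centers and re-collapses there, and reports
each member gene's Spearman correlation to its own collapsed score — the
intra-module correlation. The per-module average of those correlations is
the dataset-quality readout: it drops as platform noise rises.

Microarray platforms additionally suffer non-uniform probe quality; the
best predictor of a poorly correlating probe is its average intensity, so
`filter_probes` removes probes whose mean linear intensity falls below a
platform cutoff (default 50) and returns the full intensity-vs-correlation
diagnostic table for inspection.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import CenteredMatrix, ExpressionMatrix, median_center
from .modules import UNCLUSTERED, ModuleAssignment
from .scoring import CollapsedScores, collapse_all, spearman_rows_vs_rows

logger = logging.getLogger(__name__)

__all__ = ["TransferReport", "TransferResult", "transfer_modules", "filter_probes"]


@dataclass
class TransferReport:
    """Per-gene and per-module intra-module correlation in a foreign dataset."""

    per_gene: pd.DataFrame  # gene_id, module_id, rho
    per_module: pd.DataFrame  # module_id, n_genes, mean_rho[, reference_mean_rho]
    coverage: float  # fraction of assignment genes found in the foreign data
    missing_modules: list[int] = field(default_factory=list)


@dataclass
class TransferResult:
    scores: CollapsedScores
    report: TransferReport
    centered: CenteredMatrix


def _center(m: ExpressionMatrix | CenteredMatrix, pseudo: float) -> CenteredMatrix:
    return m if isinstance(m, CenteredMatrix) else median_center(m, pseudo=pseudo)


def _intra_module_rho(
    centered: CenteredMatrix, a: ModuleAssignment, cs: CollapsedScores
) -> pd.DataFrame:
    """rho of each assigned gene (present in the data) to its own module score."""
    rows = []
    for mid in cs.module_ids:
        members = [g for g in a.members(mid) if g in centered.data.index]
        if not members:
            continue
        rho = spearman_rows_vs_rows(
            centered.data.loc[members].to_numpy(dtype=float),
            cs.scores.loc[[mid]].to_numpy(dtype=float),
        )[:, 0]
        rows.extend(
            {"gene_id": g, "module_id": mid, "rho": r} for g, r in zip(members, rho)
        )
    return pd.DataFrame(rows, columns=["gene_id", "module_id", "rho"])


def _per_module_means(per_gene: pd.DataFrame) -> pd.DataFrame:
    if per_gene.empty:
        return pd.DataFrame(columns=["module_id", "n_genes", "mean_rho"])
    grouped = per_gene.groupby("module_id")["rho"].agg(["size", "mean"]).reset_index()
    grouped.columns = ["module_id", "n_genes", "mean_rho"]
    return grouped


def transfer_modules(
    foreign: ExpressionMatrix | CenteredMatrix,
    a: ModuleAssignment,
    reference: ExpressionMatrix | CenteredMatrix | None = None,
    r_keep: float = 0.6,
    min_overlap: float = 0.2,
    pseudo: float = 1.0,
) -> TransferResult:
    """Re-collapse a module assignment on a foreign dataset and QC the fit.

    Each module is restricted to genes the foreign data measures, the data
    is median-centered and collapsed, and every member gene is correlated
    to its module's collapsed score. If a ``reference`` dataset (typically
    the gold standard the modules came from) is supplied, its per-module
    average rho is recomputed *on the gene subset shared with the foreign
    platform* and reported side by side, so the comparison is like for like.
    """
    foreign_genes = (foreign.data if isinstance(foreign, CenteredMatrix) else foreign.data).index
    overlap = [g for g in a.gene_ids if g in foreign_genes]
    coverage = len(overlap) / len(a.gene_ids)
    if not overlap:
        raise ValueError("no overlap between foreign gene ids and the assignment")
    if coverage < min_overlap:
        warnings.warn(
            f"only {coverage:.1%} of assignment genes found in the foreign data"
        )
    sub = a.subset(overlap)
    centered = _center(foreign, pseudo)
    cs = collapse_all(centered, sub, r_keep=r_keep)
    missing = [m for m in a.module_ids if m not in cs.module_ids]
    if missing:
        logger.warning("modules absent from the foreign data: %s", missing)
    per_gene = _intra_module_rho(centered, sub, cs)
    per_module = _per_module_means(per_gene)

    if reference is not None:
        ref_centered = _center(reference, pseudo)
        ref_sub = a.subset(
            [g for g in overlap if g in ref_centered.data.index]
        )
        ref_cs = collapse_all(ref_centered, ref_sub, r_keep=r_keep)
        ref_means = _per_module_means(
            _intra_module_rho(ref_centered, ref_sub, ref_cs)
        )[["module_id", "mean_rho"]].rename(columns={"mean_rho": "reference_mean_rho"})
        per_module = per_module.merge(ref_means, on="module_id", how="left")

    report = TransferReport(
        per_gene=per_gene,
        per_module=per_module,
        coverage=coverage,
        missing_modules=missing,
    )
    return TransferResult(scores=cs, report=report, centered=centered)


def filter_probes(
    foreign: ExpressionMatrix,
    a: ModuleAssignment,
    cutoff: float = 50.0,
    r_keep: float = 0.6,
    pseudo: float = 1.0,
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Remove low-intensity probes and return the intensity/coherence diagnostics.

    Probe intensity is the mean linear-scale value across samples. Probes
    with mean intensity below ``cutoff`` are removed; the returned table
    keeps one row per input probe (intensity, module, intra-module rho,
    pass flag), the data behind the intensity-versus-correlation scatter a
    user inspects to pick a platform cutoff.
    """
    if foreign.scale != "linear":
        raise ValueError("probe filtering expects linear-scale intensities")
    intensity = foreign.data.mean(axis=1)
    result = transfer_modules(foreign, a, r_keep=r_keep, pseudo=pseudo)
    rho = result.report.per_gene.set_index("gene_id")["rho"]
    module_of = a.modules.reindex(foreign.data.index).fillna(UNCLUSTERED).astype(int)
    quality = pd.DataFrame(
        {
            "gene_id": foreign.data.index,
            "mean_intensity": intensity.to_numpy(),
            "module_id": module_of.to_numpy(),
            "intra_module_rho": rho.reindex(foreign.data.index).to_numpy(),
            "passed": (intensity >= cutoff).to_numpy(),
        }
    ).reset_index(drop=True)
    kept = quality.loc[quality["passed"], "gene_id"].tolist()
    if not kept:
        raise ValueError(f"intensity cutoff {cutoff} removes every probe")
    if len(kept) < 0.1 * foreign.data.shape[0]:
        warnings.warn(
            f"intensity cutoff {cutoff} removes more than 90% of probes"
        )
    filtered = ExpressionMatrix(foreign.data.loc[kept], scale="linear")
    return filtered, quality
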