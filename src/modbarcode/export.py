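"""GMT geneset export, colorized spreadsheet heatmaps, and static heatmaps.

Modules are only useful downstream if they travel in the formats the rest
of the ecosystem speaks: GMT genesets (one tab-delimited line per module:
name, description, genes) that drop straight into MSigDb collections, and
pre-colored spreadsheet workbooks in which the centered log2 fold-change
values are painted on a blue-white-red ramp — an interactive heatmap that
keeps the actual numbers in the cells and sorts like any spreadsheet.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .io import CenteredMatrix
from .modules import UNCLUSTERED, ModuleAssignment

logger = logging.getLogger(__name__)

__all__ = [
    "modules_to_gmt",
    "read_gmt",
    "colorized_workbook",
    "heatmap_png",
]


def modules_to_gmt(
    a: ModuleAssignment,
    path: str | Path,
    prefix: str = "MODULE",
    description: str = "co-expression module",
    min_size: int | None = 1,
) -> int:
    """Write one GMT geneset per module of at least ``min_size`` genes.

    Returns the number of genesets written; smaller modules and the
    unclustered bin are skipped (logged). Lines are strictly tab-delimited
    with >= 3 fields, the dialect enrichment tools expect.
    """
    floor = 1 if min_size is None else min_size
    written = skipped = 0
    with open(path, "w") as fh:
        for mid in a.module_ids:
            genes = sorted(a.members(mid))
            if len(genes) < floor:
                skipped += 1
                continue
            fields = [f"{prefix}_{mid}", description, *genes]
            fh.write("\t".join(fields) + "\n")
            written += 1
    if skipped:
        logger.info("skipped %d modules below min size %d", skipped, floor)
    return written


def read_gmt(path: str | Path) -> dict[str, tuple[str, list[str]]]:
    """Parse a GMT file into {name: (description, genes)}; validates the grammar."""
    out: dict[str, tuple[str, list[str]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: fewer than 3 tab-delimited fields")
            name, desc, *genes = fields
            if name in out:
                raise ValueError(f"{path}:{lineno}: duplicate geneset name {name!r}")
            genes = [g for g in genes if g]
            if not genes:
                raise ValueError(f"{path}:{lineno}: empty gene list")
            out[name] = (desc, genes)
    return out


# qualitative palette for module side-colors (hex RGB, no leading #)
_MODULE_PALETTE = [
    "4E79A7", "F28E2B", "E15759", "76B7B2", "59A14F", "EDC948",
    "B07AA1", "FF9DA7", "9C755F", "BAB0AC",
]


def _ramp_color(value: float, vmin: float, vmax: float) -> str:
    """Blue-white-red ramp as an aRGB hex string; the midpoint maps to white."""
    mid = (vmin + vmax) / 2.0
    t = np.clip((value - mid) / ((vmax - vmin) / 2.0 or 1.0), -1.0, 1.0)
    if t >= 0:  # white -> red
        r, g, b = 255, round(255 * (1 - t)), round(255 * (1 - t))
    else:  # blue -> white
        r, g, b = round(255 * (1 + t)), round(255 * (1 + t)), 255
    return f"FF{r:02X}{g:02X}{b:02X}"


def _ordered_genes(
    cm: CenteredMatrix,
    a: ModuleAssignment,
    sort_stat: pd.Series | None,
) -> list[str]:
    genes = [g for g in cm.gene_ids if g in a.modules.index]
    module_of = a.modules

    def key(g: str):
        mid = module_of[g]
        mid_key = (mid == UNCLUSTERED, mid)  # module 0 last
        if sort_stat is not None and g in sort_stat.index:
            return (*mid_key, -float(sort_stat[g]), g)
        return (*mid_key, 0.0, g)

    return sorted(genes, key=key)


def colorized_workbook(
    cm: CenteredMatrix,
    a: ModuleAssignment,
    path: str | Path,
    sort_stat: pd.Series | None = None,
    vmin: float = -2.0,
    vmax: float = 2.0,
    max_cells: int = 2_000_000,
) -> None:
    """Write an XLSX 'live heatmap': genes grouped by module, cells pre-colored.

    Column layout: gene id, module id, module color swatch, optional sort
    statistic, then one column per sample holding the exact centered value
    with a blue-white-red fill over [vmin, vmax] (0 maps to white). Genes
    are ordered by module, then by descending ``sort_stat`` within each
    module. Oversize matrices are gene-downsampled to the cell budget with
    a warning.
    """
    from openpyxl import Workbook
    from openpyxl.styles import Font, PatternFill

    genes = _ordered_genes(cm, a, sort_stat)
    n_samples = cm.data.shape[1]
    if len(genes) * n_samples > max_cells:
        keep = max(1, max_cells // n_samples)
        warnings.warn(
            f"matrix exceeds the {max_cells}-cell budget; keeping every "
            f"{len(genes) // keep + 1}th gene"
        )
        genes = genes[:: len(genes) // keep + 1]

    wb = Workbook()
    ws = wb.active
    ws.title = "heatmap"
    header = ["gene_id", "module_id", "module_color"]
    if sort_stat is not None:
        header.append(sort_stat.name or "sort_stat")
    header.extend(cm.sample_ids)
    ws.append(header)
    for cell in ws[1]:
        cell.font = Font(bold=True)

    for g in genes:
        mid = int(a.modules[g])
        row: list = [g, mid, ""]
        if sort_stat is not None:
            row.append(float(sort_stat.get(g, np.nan)))
        values = cm.data.loc[g]
        row.extend(float(v) for v in values)
        ws.append(row)
        r = ws.max_row
        mod_color = _MODULE_PALETTE[mid % len(_MODULE_PALETTE)]
        ws.cell(row=r, column=3).fill = PatternFill(
            start_color=f"FF{mod_color}", end_color=f"FF{mod_color}", fill_type="solid"
        )
        first_val_col = len(header) - n_samples + 1
        for j, v in enumerate(values):
            color = _ramp_color(float(v), vmin, vmax)
            ws.cell(row=r, column=first_val_col + j).fill = PatternFill(
                start_color=color, end_color=color, fill_type="solid"
            )
    ws.freeze_panes = ws.cell(row=2, column=4)
    wb.save(path)


def heatmap_png(
    cm: CenteredMatrix,
    a: ModuleAssignment,
    path: str | Path,
    vmin: float = -2.0,
    vmax: float = 2.0,
    dpi: int = 150,
) -> None:
    """Static module-banded heatmap of centered values (genes ordered by module)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.colors import ListedColormap

    genes = _ordered_genes(cm, a, None)
    if not genes:
        raise ValueError("no genes shared between the matrix and the assignment")
    values = cm.data.loc[genes].to_numpy(dtype=float)
    module_ids = a.modules.loc[genes].to_numpy()

    fig, (ax_bar, ax_hm) = plt.subplots(
        1,
        2,
        figsize=(8, 6),
        gridspec_kw={"width_ratios": [1, 30], "wspace": 0.02},
    )
    palette = ListedColormap([f"#{c}" for c in _MODULE_PALETTE])
    ax_bar.imshow(
        (module_ids % len(_MODULE_PALETTE))[:, None],
        aspect="auto",
        cmap=palette,
        vmin=0,
        vmax=len(_MODULE_PALETTE) - 1,
        interpolation="nearest",
    )
    ax_bar.set_xticks([])
    ax_bar.set_yticks([])
    ax_bar.set_ylabel("genes (by module)")
    im = ax_hm.imshow(
        values,
        aspect="auto",
        cmap="bwr",
        vmin=vmin,
        vmax=vmax,
        interpolation="nearest",
    )
    ax_hm.set_yticks([])
    ax_hm.set_xlabel("samples")
    fig.colorbar(im, ax=ax_hm, label="log2 fold-change vs gene median")
    fig.savefig(path, dpi=dpi, bbox_inches="tight")
    plt.close(fig)
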