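"""Gene-gene Spearman correlation and per-gene top-fraction sparsification.

The module-discovery pipeline starts from the full gene-gene Spearman
correlation matrix. To isolate the strongest co-expression neighbourhoods,
each gene keeps only its top fraction (default 5%) of partners by signed
correlation; everything else in that gene's row is zeroed. The per-row
thresholding deliberately breaks symmetry: each row is a gene's
neighbourhood profile, the object that is subsequently clustered. Keeping
the *highest* signed values (not absolute values) means anticorrelated
genes never enter a gene's neighbourhood.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .io import CenteredMatrix, ExpressionMatrix, as_frame

__all__ = ["CorrelationMatrix", "SparsifiedMatrix", "spearman_matrix", "sparsify"]


@dataclass
class CorrelationMatrix:
    """Symmetric gene-gene Spearman rho with zero-variance genes flagged."""

    rho: pd.DataFrame
    zero_variance: list[str] = field(default_factory=list)
    method: str = "spearman"

    @property
    def gene_ids(self) -> list[str]:
        return self.rho.index.tolist()


@dataclass
class SparsifiedMatrix:
    """Per-row top-k sparsified correlation matrix (rows are neighbourhood profiles)."""

    data: pd.DataFrame
    keep_fraction: float
    k: int

    @property
    def gene_ids(self) -> list[str]:
        return self.data.index.tolist()


def _rank_rows(values: np.ndarray) -> np.ndarray:
    return rankdata(values, axis=1, method="average")


def spearman_matrix(
    m: ExpressionMatrix | CenteredMatrix | pd.DataFrame,
    min_samples: int = 3,
    block_size: int = 2048,
) -> CorrelationMatrix:
    """All-pairs Spearman correlation between gene rows.

    Ranks are computed per gene with average-rank tie handling, then the
    correlation is the Pearson correlation of the ranks, evaluated blockwise
    as a matrix product of standardized rank rows so genome-scale matrices
    never materialize intermediate G x n copies per pair. Genes with zero
    rank variance (constant profiles) get rho 0 against everything and are
    reported in ``zero_variance``.
    """
    frame = as_frame(m)
    genes = frame.index
    values = frame.to_numpy(dtype=float)
    n = values.shape[1]
    if n < min_samples:
        raise ValueError(f"need at least {min_samples} samples, got {n}")
    ranks = _rank_rows(values)
    centered = ranks - ranks.mean(axis=1, keepdims=True)
    norms = np.sqrt((centered**2).sum(axis=1))
    degenerate = norms == 0
    safe = np.where(degenerate, 1.0, norms)
    z = centered / safe[:, None]
    z[degenerate] = 0.0

    G = z.shape[0]
    rho = np.empty((G, G), dtype=float)
    for start in range(0, G, block_size):
        stop = min(start + block_size, G)
        rho[start:stop] = z[start:stop] @ z.T
    np.clip(rho, -1.0, 1.0, out=rho)
    rho = (rho + rho.T) / 2.0  # enforce exact symmetry
    diag = np.where(degenerate, 0.0, 1.0)
    np.fill_diagonal(rho, diag)
    return CorrelationMatrix(
        pd.DataFrame(rho, index=genes, columns=genes),
        zero_variance=genes[degenerate].tolist(),
    )


def sparsify(c: CorrelationMatrix, keep_fraction: float = 0.05) -> SparsifiedMatrix:
    """Keep, per gene row, only the top-fraction highest correlations.

    For G genes each row retains its k = ceil(keep_fraction * (G - 1))
    highest off-diagonal entries (signed rho, self excluded) and zeroes the
    rest; the diagonal keeps its incoming value (1, or 0 for flagged
    zero-variance genes, whose rows stay all-zero). Ties at the k-th value are broken by
    lexicographic gene id so the result is deterministic. The ceiling
    guarantees every gene keeps at least one neighbour.
    """
    if not 0 < keep_fraction <= 1:
        raise ValueError("keep_fraction must be in (0, 1]")
    rho = c.rho.to_numpy(dtype=float)
    G = rho.shape[0]
    if G < 2:
        raise ValueError("need at least 2 genes to sparsify")
    k = math.ceil(keep_fraction * (G - 1))
    genes = c.rho.index
    # rank of each gene id in lexicographic order, used as the tie-break key
    lex_rank = np.empty(G, dtype=int)
    lex_rank[np.argsort(genes.to_numpy())] = np.arange(G)

    out = np.zeros_like(rho)
    for i in range(G):
        row = rho[i].copy()
        row[i] = -np.inf  # exclude self from the ranking
        order = np.lexsort((lex_rank, -row))
        keep = order[:k]
        out[i, keep] = rho[i, keep]
    # restore the diagonal (1 for valid genes, 0 for flagged zero-variance rows,
    # whose rows must stay all-zero so clustering can park them as unclustered)
    np.fill_diagonal(out, np.diag(rho))
    return SparsifiedMatrix(
        pd.DataFrame(out, index=genes, columns=genes),
        keep_fraction=keep_fraction,
        k=k,
    )


def write_sparsified_triples(s: SparsifiedMatrix, path: str | Path) -> None:
    """Export retained gene-gene-rho entries as a three-column TSV."""
    rows, cols = np.nonzero(s.data.to_numpy())
    genes = s.data.index.to_numpy()
    frame = pd.DataFrame(
        {
            "gene_a": genes[rows],
            "gene_b": genes[cols],
            "rho": s.data.to_numpy()[rows, cols],
        }
    )
    frame = frame[frame.gene_a != frame.gene_b]
    frame.to_csv(path, sep="\t", index=False, float_format="%.17g")
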