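"""Barcodes, subtypes, rank aggregation, core members, and module conservation.

A modular barcode reads a sample as an ordered vector of discretized module
levels (HI / MID / LO), obtained by robust-z standardizing each collapsed
score row across samples. Subtypes can be called either by a declarative
rule over the levels (e.g. "the unique HI module names the subtype") or by
non-negative matrix factorization of the collapsed scores. Companion
utilities cover the surrounding analyses: median-split sample grouping for
survival tools, non-parametric average-rank gene aggregation across
samples, extraction of core module members conserved across independent
module sets, and a Jaccard-overlap conservation analysis of whole module
catalogues.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage as scipy_linkage
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import squareform
from scipy.stats import rankdata
from sklearn.decomposition import NMF

from .io import CenteredMatrix, ExpressionMatrix, as_frame
from .modules import UNCLUSTERED, ModuleAssignment
from .scoring import CollapsedScores

logger = logging.getLogger(__name__)

HI, MID, LO = "HI", "MID", "LO"
_MAD_SCALE = 1.4826  # consistency factor making MAD comparable to a std dev

__all__ = [
    "BarcodeTable",
    "CoreMemberSet",
    "discretize",
    "median_split",
    "nmf_subtype",
    "average_rank",
    "core_members",
    "module_conservation",
]


def _scores_frame(cs: CollapsedScores | pd.DataFrame) -> pd.DataFrame:
    return cs.scores if isinstance(cs, CollapsedScores) else cs


@dataclass
class BarcodeTable:
    """Samples x modules table of HI/MID/LO levels."""

    levels: pd.DataFrame  # samples x modules, values in {HI, MID, LO}
    z_hi: float
    flat_modules: list[int] = field(default_factory=list)  # zero-MAD, forced MID

    def barcode(self, sample: str) -> tuple[str, ...]:
        return tuple(self.levels.loc[sample])

    def call_subtypes(
        self, labels: Mapping[int, str], fallback: str = "Low"
    ) -> pd.Series:
        """Unique-HI rule: a sample whose barcode has exactly one HI module
        among ``labels`` gets that module's label; everything else gets the
        fallback label."""
        calls = {}
        cols = [m for m in labels if m in self.levels.columns]
        for sample, row in self.levels[cols].iterrows():
            hi = [m for m in cols if row[m] == HI]
            calls[sample] = labels[hi[0]] if len(hi) == 1 else fallback
        return pd.Series(calls, name="subtype")


def discretize(
    cs: CollapsedScores | pd.DataFrame,
    z_hi: float = 0.5,
    modules: Sequence[int] | None = None,
) -> BarcodeTable:
    """Discretize collapsed scores into HI/MID/LO levels per sample.

    Each module row is standardized across samples with a robust z-score,
    (x - median) / (1.4826 * MAD), so the levels are invariant to affine
    rescaling of the row. HI if z >= z_hi, LO if z <= -z_hi, else MID. A
    zero-MAD (flat) module carries no relative information: all its samples
    are MID and the module is flagged.
    """
    scores = _scores_frame(cs)
    if scores.shape[1] < 3:
        raise ValueError("discretization requires at least 3 samples")
    if modules is not None:
        scores = scores.loc[list(modules)]
    values = scores.to_numpy(dtype=float)
    med = np.median(values, axis=1, keepdims=True)
    mad = np.median(np.abs(values - med), axis=1, keepdims=True) * _MAD_SCALE
    flat = mad[:, 0] == 0
    safe = np.where(mad == 0, 1.0, mad)
    z = (values - med) / safe
    z[flat] = 0.0
    levels = np.full(values.shape, MID, dtype=object)
    levels[z >= z_hi] = HI
    levels[z <= -z_hi] = LO
    levels[flat] = MID
    flat_ids = scores.index[flat].tolist()
    if flat_ids:
        logger.warning("flat (zero-MAD) modules forced to MID: %s", flat_ids)
    table = pd.DataFrame(levels, index=scores.index, columns=scores.columns).T
    return BarcodeTable(levels=table, z_hi=z_hi, flat_modules=flat_ids)


def median_split(
    cs: CollapsedScores | pd.DataFrame, module: int
) -> tuple[list[str], list[str]]:
    """Split samples at a module score's median; ties at the median go low."""
    scores = _scores_frame(cs)
    if module not in scores.index:
        raise KeyError(f"module {module} not in the score matrix")
    row = scores.loc[module]
    cut = row.median()
    low = row.index[row <= cut].tolist()
    high = row.index[row > cut].tolist()
    if not high:
        warnings.warn(f"module {module}: constant scores, every sample in the low group")
    return low, high


def _best_match_concordance(clusters: pd.Series, labels: pd.Series) -> float:
    """Accuracy under the optimal one-to-one cluster-label matching."""
    table = pd.crosstab(clusters, labels)
    rows, cols = linear_sum_assignment(table.to_numpy(), maximize=True)
    return float(table.to_numpy()[rows, cols].sum() / len(clusters))


def nmf_subtype(
    cs: CollapsedScores | pd.DataFrame,
    k: int,
    labels: pd.Series | Mapping[str, str] | None = None,
    seed: int = 0,
    n_restarts: int = 20,
    max_iter: int = 500,
) -> tuple[pd.Series, float | None]:
    """Cluster samples by rank-k NMF of the collapsed scores.

    Scores are shifted to non-negative by subtracting the global minimum;
    the samples x modules matrix is factorized with ``n_restarts`` random
    seed-controlled initializations, keeping the factorization with the
    lowest reconstruction error. A sample's cluster is the argmax component
    of its factor row. With reference ``labels``, concordance is the
    accuracy under the optimal one-to-one cluster-to-label matching, which
    is by construction at least the accuracy of any fixed mapping.
    """
    scores = _scores_frame(cs)
    n_samples = scores.shape[1]
    if k > n_samples:
        raise ValueError(f"k={k} exceeds the number of samples ({n_samples})")
    if k < 1:
        raise ValueError("k must be >= 1")
    if k == 1:
        clusters = pd.Series(0, index=scores.columns, name="cluster")
    else:
        X = (scores - scores.min().min()).T.to_numpy(dtype=float)
        rng = np.random.default_rng(seed)
        best_err, best_w = np.inf, None
        for _ in range(n_restarts):
            model = NMF(
                n_components=k,
                init="random",
                random_state=int(rng.integers(2**31 - 1)),
                max_iter=max_iter,
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                w = model.fit_transform(X)
            if model.reconstruction_err_ < best_err:
                best_err, best_w = model.reconstruction_err_, w
        clusters = pd.Series(
            best_w.argmax(axis=1), index=scores.columns, name="cluster"
        )
    concordance = None
    if labels is not None:
        labels = pd.Series(labels).reindex(clusters.index)
        concordance = _best_match_concordance(clusters, labels)
    return clusters, concordance


def average_rank(m: ExpressionMatrix | CenteredMatrix | pd.DataFrame) -> pd.Series:
    """Non-parametric gene ranking: rank within each sample, average across samples.

    Genes are ranked ascending by value within every sample (average ranks
    at ties); the output is each gene's mean rank. Because it only uses
    within-sample ranks, the ordering is invariant to any monotone
    per-sample transform — the point of using it to aggregate fold-changes
    across heterogeneous samples or datasets.
    """
    frame = as_frame(m)
    if frame.shape[1] < 1:
        raise ValueError("average_rank needs at least one sample")
    ranks = rankdata(frame.to_numpy(dtype=float), axis=0, method="average")
    return pd.Series(ranks.mean(axis=1), index=frame.index, name="average_rank")


@dataclass
class CoreMemberSet:
    """Genes belonging to a concept's mapped module in >= T of C datasets."""

    concept: str
    genes: list[str]
    threshold: int
    n_datasets: int
    counts: pd.Series  # per candidate gene, number of datasets supporting it


def core_members(
    assignments: Sequence[ModuleAssignment],
    concept_map: Sequence[int],
    threshold: int,
    concept: str = "concept",
) -> CoreMemberSet:
    """Extract genes conserved in a concept's module across independent module sets.

    ``concept_map`` names, per dataset, the module id that carries the
    concept (e.g. cell cycle) there. A gene is a core member if it belongs
    to the mapped module in at least ``threshold`` of the datasets; T=1
    gives the union, T=C the intersection, and raising T never grows the set.
    """
    C = len(assignments)
    if len(concept_map) != C:
        raise ValueError("concept_map must name one module per dataset")
    if not 1 <= threshold <= C:
        raise ValueError(f"threshold must be in 1..{C}")
    counts: dict[str, int] = {}
    for a, mid in zip(assignments, concept_map):
        if mid not in set(a.modules.values):
            raise KeyError(f"module {mid} not present in assignment")
        for g in a.members(mid):
            counts[g] = counts.get(g, 0) + 1
    series = pd.Series(counts, dtype=int).sort_index()
    genes = series.index[series >= threshold].tolist()
    return CoreMemberSet(
        concept=concept, genes=genes, threshold=threshold, n_datasets=C, counts=series
    )


@dataclass
class ConservationResult:
    """Cross-dataset module overlap (Jaccard) and its clustering."""

    jaccard: pd.DataFrame  # modules x modules, labels "<dataset>:<module id>"
    clusters: pd.Series  # module label -> conserved-group id
    cut_height: float


def module_conservation(
    assignments: Sequence[ModuleAssignment],
    names: Sequence[str] | None = None,
    min_size: int | None = None,
    cut_height: float = 0.8,
) -> ConservationResult:
    """Find module groups conserved across datasets by Jaccard-overlap clustering.

    Every reportable module of every dataset becomes one object; the
    pairwise Jaccard index of their gene sets is hierarchically clustered
    (average linkage on 1 - Jaccard) and the tree cut at ``cut_height``.
    Copies of a module conserved across datasets land in one group. The
    Jaccard matrix itself is part of the result so it can be exported to
    other consensus-clustering tools.
    """
    if len(assignments) < 2:
        raise ValueError("conservation analysis needs at least 2 assignments")
    names = list(names) if names is not None else [f"d{i}" for i in range(len(assignments))]
    sets: dict[str, set[str]] = {}
    for name, a in zip(names, assignments):
        for mid in a.reported_modules(min_size):
            sets[f"{name}:{mid}"] = set(a.members(mid))
    labels = list(sets)
    n = len(labels)
    jac = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            inter = len(sets[labels[i]] & sets[labels[j]])
            union = len(sets[labels[i]] | sets[labels[j]])
            jac[i, j] = jac[j, i] = inter / union if union else 0.0
    jaccard = pd.DataFrame(jac, index=labels, columns=labels)
    if n >= 2 and np.all(jac[~np.eye(n, dtype=bool)] == 0):
        warnings.warn("no module overlap between datasets (disjoint gene universes?)")
    if n < 2:
        clusters = pd.Series(dict.fromkeys(labels, 1), dtype=int)
    else:
        tree = scipy_linkage(squareform(1.0 - jac, checks=False), method="average")
        clusters = pd.Series(
            fcluster(tree, t=cut_height, criterion="distance"), index=labels
        )
    return ConservationResult(jaccard=jaccard, clusters=clusters, cut_height=cut_height)
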