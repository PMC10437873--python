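"""Spearman hierarchical clustering, PCA, and Kruskal-Wallis comparisons.

Correlations are always computed on untransformed abundances — Spearman
rank correlation is invariant to the strictly monotone log10(x + 0.5)
display transform anyway, so the choice is immaterial for rho but stated
here for clarity. Clustering uses the distance d = 1 - rho.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
import scipy.spatial.distance as ssd
import scipy.stats
from sklearn.decomposition import PCA as _SkPCA

from thermenz.abundance import AbundanceMatrix


class UndefinedCorrelationError(ValueError):
    """A constant vector makes Spearman rho undefined for its pairs."""


@dataclass
class CorrelationResult:
    labels: list[str]
    rho: np.ndarray  # symmetric, unit diagonal; NaN where undefined

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rho, index=self.labels, columns=self.labels)


@dataclass
class ClusterResult:
    labels: list[str]        # canonical (sorted) label order fed to linkage
    linkage: np.ndarray      # scipy linkage matrix over `labels`
    leaf_order: list[str]    # dendrogram leaf order for heatmap axes

    def to_newick(self) -> str:
        tree = sch.to_tree(self.linkage)

        def walk(node):
            if node.is_leaf():
                return self.labels[node.id]
            left, right = walk(node.get_left()), walk(node.get_right())
            return f"({left}:{node.dist:.6g},{right}:{node.dist:.6g})"

        return walk(tree) + ";"


@dataclass
class PcaResult:
    scores: pd.DataFrame                   # sample x component
    loadings: pd.DataFrame                 # feature x component
    explained_variance_fraction: np.ndarray


@dataclass
class KruskalResult:
    label: str
    H: float
    df: int
    pvalue: float


def _as_frame(matrix) -> pd.DataFrame:
    return matrix.data if isinstance(matrix, AbundanceMatrix) else pd.DataFrame(matrix)


def spearman_matrix(matrix, axis: str = "samples") -> CorrelationResult:
    """Pairwise Spearman rho (average ranks for ties) between the sample
    columns or the family rows of an abundance matrix."""
    df = _as_frame(matrix)
    if axis == "samples":
        vectors = df.to_numpy()            # columns are the vectors
        labels = list(df.columns)
    elif axis == "families":
        vectors = df.to_numpy().T
        labels = list(df.index)
    else:
        raise ValueError(f"axis must be 'samples' or 'families', got {axis!r}")
    if vectors.shape[1] < 2:
        raise ValueError("need at least two vectors to correlate")

    # Spearman = Pearson on average ranks; computed directly so a constant
    # vector yields NaN only for its own pairs (scipy.spearmanr collapses
    # the whole result in that case)
    ranks = np.apply_along_axis(scipy.stats.rankdata, 0, vectors)
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = np.corrcoef(ranks, rowvar=False)
    rho = np.asarray(rho, dtype=float)
    np.fill_diagonal(rho, 1.0)
    return CorrelationResult(labels=labels, rho=rho)


def cluster(corr: CorrelationResult, linkage: str = "complete") -> ClusterResult:
    """Agglomerative clustering on d = 1 - rho.

    Input order independence: labels are put in sorted order before
    linkage, so permuting the input matrix cannot change the tree (ties
    are broken by label order).
    """
    if linkage not in {"complete", "average", "single"}:
        raise ValueError(f"unsupported linkage {linkage!r}")
    rho = np.asarray(corr.rho, dtype=float)
    if np.isnan(rho).any():
        raise UndefinedCorrelationError(
            "correlation matrix contains undefined entries (constant vectors); "
            "apply a prevalence filter or drop constant profiles first"
        )
    order = np.argsort(corr.labels)
    labels = [corr.labels[i] for i in order]
    dist = 1.0 - rho[np.ix_(order, order)]
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)  # enforce exact symmetry
    Z = sch.linkage(ssd.squareform(dist, checks=False), method=linkage)
    leaves = sch.leaves_list(Z)
    return ClusterResult(labels=labels, linkage=Z,
                         leaf_order=[labels[i] for i in leaves])


def _log_half(x):
    return np.log10(x + 0.5)


def pca(
    matrix,
    transform=_log_half,
    center: bool = True,
    scale: bool = False,
    n_components: int | None = None,
) -> PcaResult:
    """PCA of sample profiles (samples as observations, families as
    features).

    The default input transform is the same log10(x + 0.5) used for the
    heatmaps; pass ``transform=None`` for raw abundances. The sign of each
    component is fixed so its largest-magnitude loading is positive.
    """
    df = _as_frame(matrix)
    X = df.to_numpy(dtype=float).T  # samples x families
    if X.shape[0] < 2:
        raise ValueError("PCA needs at least two samples")
    if transform is not None:
        X = transform(X)
    if scale:
        sd = X.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        X = X / sd
    if center:
        model = _SkPCA(n_components=n_components, svd_solver="full")
        scores = model.fit_transform(X)
        comps = model.components_
        evr = model.explained_variance_ratio_
    else:
        # sklearn always centers; uncentered PCA is a plain SVD projection
        U, s, Vt = np.linalg.svd(X, full_matrices=False)
        k = len(s) if n_components is None else min(n_components, len(s))
        scores = X @ Vt[:k].T
        comps = Vt[:k]
        evr = (s[:k] ** 2) / (s ** 2).sum()
    # deterministic sign: largest-|loading| positive per component
    for i in range(comps.shape[0]):
        j = np.argmax(np.abs(comps[i]))
        if comps[i, j] < 0:
            comps[i] = -comps[i]
            scores[:, i] = -scores[:, i]
    names = [f"PC{i + 1}" for i in range(comps.shape[0])]
    return PcaResult(
        scores=pd.DataFrame(scores, index=df.columns, columns=names),
        loadings=pd.DataFrame(comps.T, index=df.index, columns=names),
        explained_variance_fraction=np.asarray(evr),
    )


def kruskal_wallis(values, groups, label: str = "") -> KruskalResult:
    """Kruskal-Wallis H with tie correction; p from chi-square.

    Degenerate all-equal data yields H = 0, p = 1 (the tie-corrected
    denominator vanishes). A single group is an error.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    uniq = pd.unique(groups)
    if len(uniq) < 2:
        raise ValueError("Kruskal-Wallis needs at least two groups")
    samples = [values[groups == g] for g in uniq]
    if any(len(s) == 0 for s in samples):
        raise ValueError("every group must be non-empty")
    if np.all(values == values[0]):
        # all observations identical: the tie-corrected denominator vanishes
        H, p = 0.0, 1.0
    else:
        H, p = scipy.stats.kruskal(*samples)
    return KruskalResult(label=label, H=float(H), df=len(uniq) - 1, pvalue=float(p))
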