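"""Ordination and clustering of community profiles: covariance PCA and
agglomerative clustering on Euclidean distances, with an exact-subtree query
for "does this label set form its own cluster".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from sklearn.decomposition import PCA as _SKPCA

from mockbias.mock_design import CommunityProfile

log = logging.getLogger(__name__)

__all__ = [
    "ProfileMatrix",
    "DendrogramNode",
    "PCAResult",
    "pca",
    "hierarchical_cluster",
    "is_exclusive_cluster",
    "to_newick",
]

_ROW_SUM_TOL = 1e-6


@dataclass(frozen=True)
class ProfileMatrix:
    """Rows = tagged samples (platform/region/mock/replicate or "original"),
    columns = strains, values = fractions summing to 1 per row."""

    values: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.values
        if df.index.has_duplicates:
            raise ValueError("duplicate row ids")
        sums = df.to_numpy(dtype=float).sum(axis=1)
        bad = np.where(np.abs(sums - 1.0) > _ROW_SUM_TOL)[0]
        if bad.size:
            raise ValueError(
                f"rows do not sum to 1: {[df.index[i] for i in bad[:5]]}"
            )

    @classmethod
    def from_profiles(cls, profiles: Mapping[str, CommunityProfile]) -> "ProfileMatrix":
        """Stack profiles over the union of their strains (absent -> 0)."""
        frames = {rid: pd.Series(p.as_dict()) for rid, p in profiles.items()}
        df = pd.DataFrame(frames).T.fillna(0.0)
        return cls(df)

    @property
    def row_ids(self) -> list[str]:
        return list(self.values.index)


@dataclass(frozen=True)
class PCAResult:
    scores: pd.DataFrame          # rows x components
    loadings: pd.DataFrame        # components x strains
    explained_variance_ratio: np.ndarray


@dataclass(frozen=True)
class DendrogramNode:
    """Flattened dendrogram: scipy-convention merges over lexicographically
    sorted leaves (leaf k = sorted label k; internal node n+k = k-th merge)."""

    merges: tuple[tuple[int, int], ...]
    heights: tuple[float, ...]
    labels: tuple[str, ...]
    linkage: str

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    def node_leafsets(self) -> list[frozenset[str]]:
        """Leaf-label set of every node, leaves first then merges in order."""
        sets: list[frozenset[str]] = [frozenset((lab,)) for lab in self.labels]
        for a, b in self.merges:
            sets.append(sets[a] | sets[b])
        return sets


def pca(
    matrix: ProfileMatrix,
    n_components: int | None = None,
    *,
    scale: bool = False,
) -> PCAResult:
    """Covariance PCA of profile rows (columns mean-centered, unscaled by
    default). Components are sign-fixed so the largest-magnitude loading of
    each is positive.
    """
    X = matrix.values.to_numpy(dtype=float)
    n_rows, n_cols = X.shape
    if n_rows < 2:
        raise ValueError("PCA needs at least 2 rows")
    max_comp = min(n_rows - 1, n_cols)
    k = max_comp if n_components is None else n_components
    if not 1 <= k <= max_comp:
        raise ValueError(f"n_components must be in [1, {max_comp}]")
    centered = X - X.mean(axis=0)
    if scale:
        sd = centered.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        centered = centered / sd
    if not np.any(np.abs(centered) > 1e-12):
        log.warning("pca: matrix has zero variance; all scores are zero")
        scores = np.zeros((n_rows, k))
        loadings = np.zeros((k, n_cols))
        ratios = np.zeros(k)
    else:
        model = _SKPCA(n_components=k, svd_solver="full")
        scores = model.fit_transform(centered)
        loadings = model.components_
        ratios = model.explained_variance_ratio_
        # reproducible sign: largest-|loading| entry of each component positive
        for i in range(k):
            j = int(np.argmax(np.abs(loadings[i])))
            if loadings[i, j] < 0:
                loadings[i] = -loadings[i]
                scores[:, i] = -scores[:, i]
    comp_ids = [f"PC{i + 1}" for i in range(k)]
    return PCAResult(
        scores=pd.DataFrame(scores, index=matrix.values.index, columns=comp_ids),
        loadings=pd.DataFrame(loadings, index=comp_ids, columns=matrix.values.columns),
        explained_variance_ratio=np.asarray(ratios, dtype=float),
    )


_LINKAGES = ("average", "complete", "single", "ward")


def hierarchical_cluster(matrix: ProfileMatrix, linkage: str = "average") -> DendrogramNode:
    """Agglomerative clustering on pairwise Euclidean distances.

    Rows are processed in lexicographic row-id order so equal-distance merges
    resolve deterministically regardless of input order.
    """
    if linkage not in _LINKAGES:
        raise ValueError(f"linkage must be one of {_LINKAGES}")
    if len(matrix.row_ids) < 2:
        raise ValueError("clustering needs at least 2 rows")
    df = matrix.values.sort_index(kind="stable")
    Z = hierarchy.linkage(pdist(df.to_numpy(dtype=float)), method=linkage)
    merges = tuple((int(r[0]), int(r[1])) for r in Z)
    heights = tuple(float(r[2]) for r in Z)
    return DendrogramNode(
        merges=merges, heights=heights, labels=tuple(df.index), linkage=linkage
    )


def is_exclusive_cluster(tree: DendrogramNode, labels: Sequence[str] | set[str]) -> bool:
    """True iff some node's leaf set equals ``labels`` exactly (a leaf for a
    singleton, the root for the full set)."""
    query = frozenset(labels)
    unknown = query - set(tree.labels)
    if unknown:
        raise KeyError(f"unknown labels: {sorted(unknown)}")
    return query in tree.node_leafsets()


def to_newick(tree: DendrogramNode) -> str:
    """Newick serialization with merge heights as branch lengths."""
    n = tree.n_leaves
    heights = {i: 0.0 for i in range(n)}
    for k, h in enumerate(tree.heights):
        heights[n + k] = h
    children = {n + k: pair for k, pair in enumerate(tree.merges)}

    def render(node: int, parent_height: float) -> str:
        length = parent_height - heights[node]
        if node < n:
            label = tree.labels[node].replace(" ", "_").replace(",", "_")
            return f"{label}:{length:.6g}"
        a, b = children[node]
        return f"({render(a, heights[node])},{render(b, heights[node])}):{length:.6g}"

    root = n + len(tree.merges) - 1
    a, b = children[root]
    h = heights[root]
    return f"({render(a, h)},{render(b, h)});"
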