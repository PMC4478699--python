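"""Profile clustering and ordination.

Communities (or per-community transcript profiles of a taxon) are compared
as vectors of feature abundances using correlation distance,
``d(i, j) = 1 - r(i, j)`` with Pearson's r, clustered by unweighted
average-linkage agglomeration (UPGMA) and ordinated by principal component
analysis of the covariance (optionally correlation) matrix.

The UPGMA implementation is deliberately explicit about tie-breaking —
among equally close cluster pairs the pair whose sorted leaf-label tuple is
smallest merges first — so dendrograms are byte-identical across runs and
platforms.  The merge table uses the same layout as
``scipy.cluster.hierarchy.linkage`` output, which doubles as a cross-check
in the test-suite.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


def correlation_distance(profiles: pd.DataFrame) -> pd.DataFrame:
    """Pairwise 1 - Pearson correlation between the rows of ``profiles``.

    Rows are items (communities, taxa), columns are features.  Every row
    needs length >= 2 and nonzero variance; the offending item is named
    otherwise.  The result is symmetric with a zero diagonal, values in
    [0, 2].
    """
    X = profiles.to_numpy(dtype=float)
    if X.shape[1] < 2:
        raise ValueError("profiles need at least 2 features")
    variances = X.var(axis=1)
    for item, var in zip(profiles.index, variances):
        if var == 0:
            raise ValueError(f"item {item!r} has zero variance; correlation undefined")
    if not np.isfinite(X).all():
        raise ValueError("profiles contain non-finite values")
    corr = np.corrcoef(X)
    dist = 1.0 - corr
    dist = (dist + dist.T) / 2.0
    np.fill_diagonal(dist, 0.0)
    dist = np.clip(dist, 0.0, 2.0)
    return pd.DataFrame(dist, index=profiles.index, columns=profiles.index)


@dataclass
class DendrogramNode:
    """Binary merge-tree node; leaves carry a label, internal nodes a height."""

    height: float
    label: str | None = None
    left: "DendrogramNode | None" = None
    right: "DendrogramNode | None" = None

    @property
    def is_leaf(self) -> bool:
        return self.label is not None

    def leaves(self) -> list[str]:
        if self.is_leaf:
            return [self.label]
        return self.left.leaves() + self.right.leaves()

    def _newick(self, parent_height: float) -> str:
        # ultrametric branch lengths: each node sits at half its merge height
        branch = parent_height / 2.0 - self.height / 2.0
        if self.is_leaf:
            return f"{self.label}:{branch:.10g}"
        inner = f"({self.left._newick(self.height)},{self.right._newick(self.height)})"
        return f"{inner}:{branch:.10g}"

    def to_newick(self) -> str:
        if self.is_leaf:
            return f"{self.label};"
        inner = f"({self.left._newick(self.height)},{self.right._newick(self.height)})"
        return f"{inner};"


@dataclass
class Dendrogram:
    """UPGMA result: scipy-layout merge table plus a navigable tree."""

    merges: np.ndarray  # (n-1, 4): id_a, id_b, height, new cluster size
    labels: list[str]
    root: DendrogramNode

    def to_newick(self) -> str:
        return self.root.to_newick()

    @property
    def heights(self) -> np.ndarray:
        return self.merges[:, 2]


def _validate_distance(dist: pd.DataFrame) -> np.ndarray:
    D = dist.to_numpy(dtype=float)
    if D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.isfinite(D).all():
        raise ValueError("distance matrix contains non-finite values")
    if (np.abs(D - D.T) > 1e-12).any():
        raise ValueError("distance matrix must be symmetric within 1e-12")
    if (np.abs(np.diag(D)) > 1e-12).any():
        raise ValueError("distance matrix diagonal must be zero")
    if (D < 0).any():
        raise ValueError("distances must be non-negative")
    return (D + D.T) / 2.0


def average_linkage(dist: pd.DataFrame) -> Dendrogram:
    """Unweighted average-linkage (UPGMA) agglomeration.

    Repeatedly merges the closest pair of clusters; the distance between two
    clusters is the mean of all cross-cluster leaf-pair distances.  Exact
    distance ties are resolved toward the pair whose sorted leaf labels
    come first, making the merge sequence deterministic.
    """
    labels = [str(l) for l in dist.index]
    n = len(labels)
    if n < 2:
        raise ValueError("need at least 2 items to cluster")
    D = _validate_distance(dist)
    # active cluster state keyed by scipy-style ids (leaves 0..n-1)
    members: dict[int, list[int]] = {i: [i] for i in range(n)}
    keys: dict[int, tuple[str, ...]] = {i: (labels[i],) for i in range(n)}
    cdist: dict[tuple[int, int], float] = {
        (i, j): D[i, j] for i in range(n) for j in range(i + 1, n)
    }
    merges = np.zeros((n - 1, 4))
    nodes: dict[int, DendrogramNode] = {
        i: DendrogramNode(height=0.0, label=labels[i]) for i in range(n)
    }
    next_id = n
    last_height = 0.0
    for step in range(n - 1):
        best = min(
            cdist.items(),
            key=lambda kv: (kv[1], *sorted((keys[kv[0][0]], keys[kv[0][1]]))),
        )
        (ia, ib), height = best
        if height < last_height - 1e-12:
            raise RuntimeError("non-monotone merge heights in average linkage")
        last_height = max(last_height, height)
        size_a, size_b = len(members[ia]), len(members[ib])
        new_size = size_a + size_b
        merges[step] = (min(ia, ib), max(ia, ib), height, new_size)
        nodes[next_id] = DendrogramNode(height=height, left=nodes[ia], right=nodes[ib])
        members[next_id] = members[ia] + members[ib]
        keys[next_id] = tuple(sorted(keys[ia] + keys[ib]))
        for other in list(members):
            if other in (ia, ib, next_id):
                continue
            d_a = cdist.pop((min(ia, other), max(ia, other)))
            d_b = cdist.pop((min(ib, other), max(ib, other)))
            cdist[(other, next_id)] = (size_a * d_a + size_b * d_b) / new_size
        del cdist[(ia, ib)]
        del members[ia], members[ib], keys[ia], keys[ib]
        next_id += 1
    return Dendrogram(merges=merges, labels=labels, root=nodes[next_id - 1])


@dataclass
class PCAResult:
    scores: pd.DataFrame  # items x components
    explained_variance_ratio: np.ndarray
    loadings: pd.DataFrame  # variables x components


def pca_scores(profiles: pd.DataFrame, standardize: bool = False) -> PCAResult:
    """Principal component analysis of item profiles.

    Columns (variables) are mean-centred, optionally standardised to unit
    variance (useful when the variables carry different units, e.g. a
    geochemistry table).  Components come from the SVD of the centred
    matrix, ordered by decreasing eigenvalue; variance proportions sum to 1
    over all returned components.  The sign of each component is fixed so
    its largest-magnitude loading is positive.  Zero-variance variables are
    dropped (logged); at least two must remain.
    """
    X = profiles.to_numpy(dtype=float)
    if X.shape[0] < 2:
        raise ValueError("PCA needs at least 2 items")
    variances = X.var(axis=0)
    degenerate = variances == 0
    if degenerate.any():
        dropped = list(profiles.columns[degenerate])
        logger.info("dropping %d zero-variance variables: %s", len(dropped), dropped)
    if (~degenerate).sum() < 2:
        raise ValueError("PCA needs at least 2 non-degenerate variables")
    cols = profiles.columns[~degenerate]
    X = X[:, ~degenerate]
    Xc = X - X.mean(axis=0)
    if standardize:
        Xc = Xc / X.std(axis=0, ddof=1)
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    for j in range(Vt.shape[0]):
        pivot = np.argmax(np.abs(Vt[j]))
        if Vt[j, pivot] < 0:
            Vt[j] *= -1.0
            U[:, j] *= -1.0
    scores = U * S
    ratio = S**2 / (S**2).sum()
    comp_names = [f"PC{i + 1}" for i in range(len(S))]
    return PCAResult(
        scores=pd.DataFrame(scores, index=profiles.index, columns=comp_names),
        explained_variance_ratio=ratio,
        loadings=pd.DataFrame(Vt.T, index=cols, columns=comp_names),
    )
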