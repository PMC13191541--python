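"""Exploratory spectral statistics: accession means, distance structure,
hierarchical clustering, PERMANOVA, and one-vs-rest association maps.

PERMANOVA tests whether accession identity explains the multivariate spectral
structure.  Using Euclidean distances, the sum-of-squares decomposition
reduces to the classical ANOVA identities

    SS_total  = sum_i ||x_i - x_bar||^2
    SS_within = sum_g sum_{i in g} ||x_i - x_bar_g||^2
    F = (SS_between / (g - 1)) / (SS_within / (N - g))

which equal the distance-based forms SS_total = (1/N) sum_{i<j} d_ij^2 and
SS_within = sum_g (1/n_g) sum_{i<j in g} d_ij^2.  Significance comes from
whole-label permutations; the p-value uses the +1 correction so it is never
zero: p = (1 + #{F_perm >= F_obs}) / (1 + n_perm).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
from scipy.spatial.distance import squareform

from .calibration import SpectralDataset, WavelengthGrid

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Accession means and distances
# ---------------------------------------------------------------------------

def accession_means(dataset: SpectralDataset) -> pd.DataFrame:
    """Mean spectrum per accession (rows ordered lexicographically by label)."""
    if dataset.n == 0:
        raise ValueError("empty dataset")
    classes = dataset.classes
    means = np.vstack([dataset.X[dataset.labels == c].mean(axis=0) for c in classes])
    return pd.DataFrame(means, index=[str(c) for c in classes], columns=dataset.grid.values)


def euclidean_distance_matrix(rows: np.ndarray) -> np.ndarray:
    """Symmetric Euclidean distance matrix d(a,b) = sqrt(sum_j (x_aj - x_bj)^2)."""
    X = np.asarray(rows, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least 2 rows")
    sq = np.sum(X ** 2, axis=1)
    d2 = sq[:, None] + sq[None, :] - 2.0 * (X @ X.T)
    np.maximum(d2, 0.0, out=d2)
    d = np.sqrt(d2)
    np.fill_diagonal(d, 0.0)
    return 0.5 * (d + d.T)


# ---------------------------------------------------------------------------
# Hierarchical clustering
# ---------------------------------------------------------------------------

@dataclass
class DendrogramResult:
    """Agglomerative clustering of accession mean spectra."""

    linkage_matrix: np.ndarray   # scipy format: (child_a, child_b, height, size)
    leaf_order: list             # labels in left-to-right dendrogram order
    labels: list
    metric: str = "euclidean"
    method: str = "average"

    @property
    def merge_heights(self) -> np.ndarray:
        return self.linkage_matrix[:, 2]

    def to_newick(self) -> str:
        """Serialize the dendrogram as a Newick tree with branch lengths."""
        tree = sch.to_tree(self.linkage_matrix)

        def rec(node, parent_height: float) -> str:
            length = parent_height - node.dist
            if node.is_leaf():
                return f"{self.labels[node.id]}:{length:.6g}"
            left = rec(node.get_left(), node.dist)
            right = rec(node.get_right(), node.dist)
            return f"({left},{right}):{length:.6g}"

        return rec(tree, tree.dist) + ";"


def hierarchical_cluster(distance_matrix: np.ndarray, labels,
                         linkage: str = "average") -> DendrogramResult:
    """Agglomerative clustering of a distance matrix (default UPGMA linkage).

    Leaf order is the deterministic left-to-right traversal of the tree after
    the canonical child ordering (smaller cluster index first).
    """
    D = np.asarray(distance_matrix, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(D, D.T, atol=1e-10):
        raise ValueError("distance matrix must be symmetric")
    labels = [str(x) for x in labels]
    if len(labels) != D.shape[0]:
        raise ValueError("label count must match matrix size")
    Z = sch.linkage(squareform(D, checks=False), method=linkage)
    order = sch.leaves_list(Z)
    return DendrogramResult(linkage_matrix=Z, leaf_order=[labels[i] for i in order],
                            labels=labels, method=linkage)


# ---------------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------------

@dataclass
class PermanovaResult:
    F: float
    p: float
    n_perm: int
    group_sizes: dict
    seed: int
    ss_between: float = float("nan")
    ss_within: float = float("nan")


def _within_ss(sq_norm_total: float, group_sums: np.ndarray, sizes: np.ndarray) -> float:
    # SS_within = sum_i ||x_i||^2 - sum_g ||S_g||^2 / n_g
    return sq_norm_total - float(np.sum(np.sum(group_sums ** 2, axis=1) / sizes))


def permanova(X: np.ndarray, labels, n_perm: int = 999, seed: int = 42) -> PermanovaResult:
    """One-way PERMANOVA on Euclidean distances with whole-label permutations."""
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    classes, codes = np.unique(labels, return_inverse=True)
    g = len(classes)
    n = X.shape[0]
    sizes = np.bincount(codes).astype(float)
    if g < 2:
        raise ValueError("PERMANOVA requires at least 2 groups")
    if sizes.min() < 2:
        small = classes[np.argmin(sizes)]
        raise ValueError(f"every group needs >= 2 members; group {small!r} has {int(sizes.min())}")

    grand = X.mean(axis=0)
    ss_total = float(np.sum((X - grand) ** 2))
    sq_norm_total = float(np.sum(X ** 2))

    def group_sums_for(order_codes: np.ndarray) -> np.ndarray:
        sums = np.zeros((g, X.shape[1]))
        np.add.at(sums, order_codes, X)
        return sums

    obs_within = _within_ss(sq_norm_total, group_sums_for(codes), sizes)
    obs_between = ss_total - obs_within
    if obs_within <= 0:
        raise ValueError("zero within-group variance; pseudo-F is undefined")
    f_obs = (obs_between / (g - 1)) / (obs_within / (n - g))

    rng = np.random.default_rng(seed)
    # permuting labels == assigning shuffled rows to fixed-size groups
    bounds = np.concatenate([[0], np.cumsum(sizes.astype(int))])
    exceed = 0
    for _ in range(n_perm):
        shuffled = rng.permutation(n)
        sums = np.vstack([X[shuffled[bounds[k]:bounds[k + 1]]].sum(axis=0) for k in range(g)])
        w = _within_ss(sq_norm_total, sums, sizes)
        f_perm = ((ss_total - w) / (g - 1)) / (w / (n - g)) if w > 0 else np.inf
        if f_perm >= f_obs:
            exceed += 1
    p = (1 + exceed) / (1 + n_perm)
    logger.info("PERMANOVA: F=%.4f, p=%.4g (%d groups, N=%d, %d permutations)",
                f_obs, p, g, n, n_perm)
    return PermanovaResult(F=f_obs, p=p, n_perm=n_perm,
                           group_sizes={str(c): int(s) for c, s in zip(classes, sizes)},
                           seed=seed, ss_between=obs_between, ss_within=obs_within)


# ---------------------------------------------------------------------------
# One-vs-rest Pearson association mapping
# ---------------------------------------------------------------------------

@dataclass
class AssociationMap:
    """Pearson r between each band and each accession's one-vs-rest indicator.

    ``degenerate[c, j]`` marks cells where band j or indicator c was constant
    (r set to 0 there).
    """

    r: np.ndarray            # C x P
    r2: np.ndarray           # elementwise square
    labels: list
    grid: WavelengthGrid
    degenerate: np.ndarray   # C x P boolean


def ovr_association_map(X: np.ndarray, labels, grid: WavelengthGrid) -> AssociationMap:
    """Correlate each wavelength with binary accession membership (1 = target)."""
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if len(classes) < 2:
        raise ValueError("association map requires at least 2 accession labels")
    if X.shape[0] < 3:
        raise ValueError("association map requires N >= 3")

    Z = (labels[:, None] == classes[None, :]).astype(float)   # N x C indicators
    Xc = X - X.mean(axis=0)
    Zc = Z - Z.mean(axis=0)
    band_ss = np.sum(Xc ** 2, axis=0)
    ind_ss = np.sum(Zc ** 2, axis=0)
    degenerate = (ind_ss[:, None] == 0) | (band_ss[None, :] == 0)
    denom = np.sqrt(np.outer(ind_ss, band_ss))
    denom[degenerate] = 1.0
    r = (Zc.T @ Xc) / denom
    r[degenerate] = 0.0
    np.clip(r, -1.0, 1.0, out=r)
    return AssociationMap(r=r, r2=r ** 2, labels=[str(c) for c in classes],
                          grid=grid, degenerate=degenerate)


def max_association(amap: AssociationMap) -> tuple[str, float, float]:
    """Strongest single association: (accession, wavelength_nm, r^2 value).

    Ties broken by lower wavelength first, then lexicographic accession.
    """
    if amap.r2.size == 0:
        raise ValueError("empty association map")
    best = amap.r2.max()
    cs, js = np.nonzero(amap.r2 == best)
    # sort candidates by (wavelength, accession label)
    order = sorted(zip(js, cs), key=lambda t: (amap.grid.values[t[0]], amap.labels[t[1]]))
    j, c = order[0]
    return amap.labels[c], float(amap.grid.values[j]), float(best)
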