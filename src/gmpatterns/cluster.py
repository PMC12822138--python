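"""Unsupervised random-forest proximity clustering with composite
validity-index model selection.

The method: train a classification forest to separate the real subjects
from a synthetic "contrast" class built by independently resampling each
feature's marginal (destroying inter-feature dependence while preserving
marginals).  The fraction of trees in which two real subjects land in the
same terminal leaf while both are out of bag (OOB) is their proximity; its
complement, as sqrt(1 - proximity), is a dissimilarity that is embedded by
classical multidimensional scaling for inspection and fed to average-
linkage agglomerative clustering.  The number of clusters is chosen over
k = 2..8 by the composite (mean z-score) of the Dunn and Calinski-Harabasz
indices.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.tree import DecisionTreeClassifier

from .rois import N_ROIS

__all__ = [
    "ForestParams",
    "ForestFit",
    "ProximityMatrix",
    "ClusterSolution",
    "generate_contrast_data",
    "fit_proximity_forest",
    "compute_oob_proximity",
    "proximity_to_dissimilarity",
    "classical_mds",
    "cut_hierarchy",
    "canonicalize_labels",
    "dunn_index",
    "calinski_harabasz",
    "select_k_composite",
    "cluster_features",
    "stability_gap",
]

DEFAULT_K_RANGE = tuple(range(2, 9))


@dataclass(frozen=True)
class ForestParams:
    """Forest hyperparameters.  The study setting is ntree=6000, mtry=6,
    nodesize=3; desk-scale runs typically use ntree=1000."""

    ntree: int = 6000
    mtry: int = 6
    nodesize: int = 3
    seed: int = 0
    contrast_multiplier: float = 1.0

    def __post_init__(self) -> None:
        if self.ntree < 1:
            raise ValueError("ntree must be >= 1")
        if self.nodesize < 1:
            raise ValueError("nodesize must be >= 1")
        if self.mtry < 1:
            raise ValueError("mtry must be >= 1")
        if self.contrast_multiplier <= 0:
            raise ValueError("contrast_multiplier must be positive")


@dataclass
class ForestFit:
    """Trained real-vs-contrast forest, reduced to what proximity needs:
    per-tree terminal-leaf ids and OOB membership for the real rows."""

    leaf_ids: np.ndarray        # ntree x n_real, int32
    oob: np.ndarray             # ntree x n_real, bool
    importance: np.ndarray      # per-feature mean impurity decrease
    oob_error: float            # OOB misclassification rate, real class
    params: ForestParams

    @property
    def ntree(self) -> int:
        return self.leaf_ids.shape[0]

    @property
    def n(self) -> int:
        return self.leaf_ids.shape[1]


@dataclass
class ProximityMatrix:
    """OOB co-leaf frequencies with their per-pair denominators."""

    values: np.ndarray          # n x n, symmetric, diag 1, entries in [0,1]
    denominators: np.ndarray    # n x n trees where both subjects were OOB
    undefined_pairs: int        # off-diagonal pairs with zero denominator


@dataclass
class ClusterSolution:
    """Final clustering output.  Labels run 1..k, sorted descending by
    cluster size, so cluster 1 is always the largest."""

    labels: np.ndarray
    k: int
    dissimilarity: np.ndarray
    mds_coordinates: np.ndarray
    mds_eigenvalues: np.ndarray
    validity_table: pd.DataFrame
    importance: np.ndarray
    params: ForestParams
    subject_ids: np.ndarray | None = None

    def labels_series(self) -> pd.Series:
        idx = self.subject_ids if self.subject_ids is not None else np.arange(len(self.labels))
        return pd.Series(self.labels, index=idx, name="cluster")


# --------------------------------------------------------------------------
# contrast data and forest
# --------------------------------------------------------------------------

def _as_array(features) -> np.ndarray:
    X = features.to_numpy(dtype=float) if isinstance(features, pd.DataFrame) else np.asarray(features, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("features must be a 2-D array with at least 2 rows")
    if np.all(np.isnan(X), axis=0).any():
        raise ValueError("features contain an all-missing column")
    return X


def generate_contrast_data(features, seed_or_rng=0,
                           multiplier: float = 1.0) -> np.ndarray:
    """Synthetic contrast class: each column sampled independently with
    replacement from the corresponding real column's observed values.
    Marginals are preserved; inter-column dependence is destroyed."""
    X = _as_array(features)
    rng = (seed_or_rng if isinstance(seed_or_rng, np.random.Generator)
           else np.random.default_rng(seed_or_rng))
    n, p = X.shape
    m = max(1, int(round(multiplier * n)))
    out = np.empty((m, p))
    for j in range(p):
        col = X[:, j]
        col = col[np.isfinite(col)]
        if np.unique(col).size < 2:
            warnings.warn(f"contrast column {j} has < 2 distinct values "
                          "(uninformative)", stacklevel=2)
        out[:, j] = rng.choice(col, size=m, replace=True)
    return out


def fit_proximity_forest(features, contrast=None,
                         params: ForestParams = ForestParams()) -> ForestFit:
    """Train the real-vs-contrast classification forest.

    Each tree is grown on a bootstrap sample of the pooled (real +
    contrast) rows with ``mtry`` candidate features per split and terminal
    leaves of at least ``nodesize`` rows.  OOB membership of the real rows
    is recorded per tree; importance is the mean impurity decrease across
    trees.  All randomness derives from ``params.seed``.
    """
    X = _as_array(features)
    n, p = X.shape
    if params.mtry > p:
        raise ValueError(f"mtry={params.mtry} exceeds n_features={p}")
    rng = np.random.default_rng(params.seed)
    if contrast is None:
        contrast = generate_contrast_data(X, rng, params.contrast_multiplier)
    C = np.asarray(contrast, dtype=float)
    if C.shape[1] != p:
        raise ValueError("contrast data must share the feature columns")

    Xall = np.vstack([X, C])
    yall = np.concatenate([np.ones(n, dtype=int), np.zeros(len(C), dtype=int)])
    n_all = len(yall)

    leaf_ids = np.empty((params.ntree, n), dtype=np.int32)
    oob = np.empty((params.ntree, n), dtype=bool)
    importance = np.zeros(p)
    oob_votes = np.zeros(n)
    oob_counts = np.zeros(n)

    tree_seeds = rng.integers(0, 2**31 - 1, size=params.ntree)
    for t in range(params.ntree):
        t_rng = np.random.default_rng(tree_seeds[t])
        boot = t_rng.integers(0, n_all, size=n_all)
        tree = DecisionTreeClassifier(
            max_features=params.mtry,
            min_samples_leaf=params.nodesize,
            random_state=int(tree_seeds[t]),
        )
        tree.fit(Xall[boot], yall[boot])
        importance += tree.feature_importances_
        leaf_ids[t] = tree.apply(X).astype(np.int32)
        in_bag = np.zeros(n_all, dtype=bool)
        in_bag[boot] = True
        oob[t] = ~in_bag[:n]
        if oob[t].any():
            pred = tree.predict(X[oob[t]])
            oob_votes[oob[t]] += pred
            oob_counts[oob[t]] += 1

    importance /= params.ntree
    seen = oob_counts > 0
    oob_error = float(np.mean((oob_votes[seen] / oob_counts[seen]) < 0.5)) if seen.any() else float("nan")
    return ForestFit(leaf_ids=leaf_ids, oob=oob, importance=importance,
                     oob_error=oob_error, params=params)


def compute_oob_proximity(fit: ForestFit,
                          max_undefined_frac: float = 0.01) -> ProximityMatrix:
    """OOB proximity: proximity(i, j) = #(trees where i and j are both OOB
    and share a terminal leaf) / #(trees where both are OOB).

    The diagonal is forced to 1.  Pairs never jointly OOB are set to 0 and
    counted; more than ``max_undefined_frac`` of undefined pairs is an
    error (grow more trees).
    """
    ntree, n = fit.leaf_ids.shape
    O = fit.oob.astype(np.float32)
    den = O.T @ O  # trees where both OOB

    # sparse (tree, leaf) x subject incidence restricted to OOB rows
    rows, cols, tree_of = [], [], []
    for t in range(ntree):
        idx = np.flatnonzero(fit.oob[t])
        leaves = fit.leaf_ids[t, idx]
        # unique leaf ids within tree t, offset by tree
        _, leaf_code = np.unique(leaves, return_inverse=True)
        rows.append(leaf_code)
        cols.append(idx)
        tree_of.append(np.full(idx.size, t))
    offsets = np.cumsum([0] + [r.max(initial=-1) + 1 for r in rows[:-1]])
    row_idx = np.concatenate([r + o for r, o in zip(rows, offsets)])
    col_idx = np.concatenate(cols)
    M = sp.csr_matrix((np.ones(row_idx.size, dtype=np.float32),
                       (row_idx, col_idx)),
                      shape=(int(row_idx.max(initial=-1)) + 1, n))
    num = np.asarray((M.T @ M).todense())

    with np.errstate(invalid="ignore", divide="ignore"):
        prox = np.where(den > 0, num / np.maximum(den, 1), 0.0)
    undefined = int((np.triu(den == 0, k=1)).sum())
    np.fill_diagonal(prox, 1.0)
    prox = (prox + prox.T) / 2.0
    prox = np.clip(prox, 0.0, 1.0)
    n_pairs = n * (n - 1) // 2
    if n_pairs and undefined / n_pairs > max_undefined_frac:
        raise RuntimeError(
            f"{undefined}/{n_pairs} subject pairs were never jointly OOB; "
            "increase ntree")
    return ProximityMatrix(values=prox.astype(float),
                           denominators=np.asarray(den, dtype=float),
                           undefined_pairs=undefined)


def proximity_to_dissimilarity(prox: ProximityMatrix | np.ndarray,
                               sqrt_transform: bool = True) -> np.ndarray:
    """d = sqrt(1 - proximity) (the RF-clustering convention), or plain
    1 - proximity with ``sqrt_transform=False``."""
    P = prox.values if isinstance(prox, ProximityMatrix) else np.asarray(prox, dtype=float)
    D = 1.0 - P
    if sqrt_transform:
        D = np.sqrt(np.clip(D, 0.0, None))
    np.fill_diagonal(D, 0.0)
    return (D + D.T) / 2.0


# --------------------------------------------------------------------------
# embedding and clustering
# --------------------------------------------------------------------------

def classical_mds(dissimilarity: np.ndarray, m: int = 3
                  ) -> tuple[np.ndarray, np.ndarray, float]:
    """Torgerson's classical scaling.

    Double-centers the squared-dissimilarity matrix into a Gram matrix,
    eigendecomposes it, and returns coordinates on the top-``m`` positive
    eigenvectors (scaled by sqrt eigenvalue), the full eigenvalue spectrum
    (descending) and the negative-eigenvalue mass |sum(lam<0)| / sum|lam|.
    Coordinates are column-centered by construction.
    """
    D = np.asarray(dissimilarity, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("dissimilarity must be square")
    if not np.allclose(D, D.T, atol=1e-10) or not np.allclose(np.diag(D), 0, atol=1e-10):
        raise ValueError("dissimilarity must be symmetric with zero diagonal")
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D ** 2) @ J
    B = (B + B.T) / 2.0
    eigval, eigvec = np.linalg.eigh(B)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    pos = eigval > 1e-12 * max(eigval[0], 1.0)
    n_pos = int(pos.sum())
    if m > n_pos:
        warnings.warn(f"requested {m} MDS dimensions but only {n_pos} "
                      "positive eigenvalues; truncating", stacklevel=2)
        m = n_pos
    coords = eigvec[:, :m] * np.sqrt(eigval[:m])
    total = np.abs(eigval).sum()
    neg_mass = float(np.abs(eigval[eigval < 0]).sum() / total) if total > 0 else 0.0
    return coords, eigval, neg_mass


def cut_hierarchy(dissimilarity: np.ndarray, k: int) -> np.ndarray:
    """Average-linkage (UPGMA) agglomeration of the dissimilarity matrix,
    cut into k clusters.  Returns raw labels 1..k (merge order as produced
    by the linkage; ties resolved by the smallest pair index)."""
    D = np.asarray(dissimilarity, dtype=float)
    n = D.shape[0]
    if not (1 <= k <= n):
        raise ValueError(f"k={k} outside [1, {n}]")
    if not np.all(np.isfinite(D)):
        raise ValueError("dissimilarity contains non-finite values")
    if k == n:
        return np.arange(1, n + 1)
    Z = linkage(squareform(D, checks=False), method="average")
    return fcluster(Z, t=k, criterion="maxclust")


def canonicalize_labels(labels: np.ndarray) -> np.ndarray:
    """Relabel clusters 1..k in decreasing order of size (ties broken by
    first appearance), so cluster 1 is the largest."""
    labels = np.asarray(labels)
    uniq, first = np.unique(labels, return_index=True)
    sizes = np.array([(labels == u).sum() for u in uniq])
    order = np.lexsort((first, -sizes))
    mapping = {int(uniq[o]): r + 1 for r, o in enumerate(order)}
    return np.array([mapping[int(l)] for l in labels])


# --------------------------------------------------------------------------
# validity indices and model selection
# --------------------------------------------------------------------------

def dunn_index(dissimilarity: np.ndarray, labels: np.ndarray) -> float:
    """Minimum between-cluster distance over maximum within-cluster
    diameter.  +inf (flagged upstream) when every within-cluster diameter
    is zero."""
    D = np.asarray(dissimilarity, dtype=float)
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if uniq.size < 2:
        raise ValueError("Dunn index needs at least 2 clusters")
    masks = [labels == u for u in uniq]
    min_between = np.inf
    for a in range(len(uniq)):
        for b in range(a + 1, len(uniq)):
            min_between = min(min_between, D[np.ix_(masks[a], masks[b])].min())
    max_within = 0.0
    for m in masks:
        if m.sum() > 1:
            max_within = max(max_within, D[np.ix_(m, m)].max())
    if max_within == 0.0:
        return np.inf
    return float(min_between / max_within)


def calinski_harabasz(coords: np.ndarray, labels: np.ndarray) -> float:
    """Variance-ratio criterion about cluster centroids:
    (BSS / (k-1)) / (WSS / (n-k)).  +inf when the within-cluster scatter
    vanishes."""
    X = np.asarray(coords, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    labels = np.asarray(labels)
    n = X.shape[0]
    uniq = np.unique(labels)
    k = uniq.size
    if not (2 <= k <= n - 1):
        raise ValueError(f"Calinski-Harabasz needs 2 <= k <= n-1, got k={k}, n={n}")
    grand = X.mean(axis=0)
    bss = wss = 0.0
    for u in uniq:
        grp = X[labels == u]
        c = grp.mean(axis=0)
        bss += len(grp) * float(((c - grand) ** 2).sum())
        wss += float(((grp - c) ** 2).sum())
    if wss == 0.0:
        return np.inf
    return float((bss / (k - 1)) / (wss / (n - k)))


def composite_scores(dunn_values, ch_values) -> np.ndarray:
    """Mean of the two indices' z-scores across candidate k.

    z-scoring makes the composite exactly invariant to affine rescaling of
    either raw index.  Degenerate (non-finite) entries are excluded from
    the standardization and propagate as NaN."""
    out = []
    for col in (np.asarray(dunn_values, dtype=float),
                np.asarray(ch_values, dtype=float)):
        finite = np.where(np.isfinite(col), col, np.nan)
        mu, sd = np.nanmean(finite), np.nanstd(finite)
        out.append((finite - mu) / sd if sd > 0 else finite - mu)
    return np.mean(out, axis=0)


def select_k_composite(dissimilarity: np.ndarray,
                       coords: np.ndarray,
                       k_range: tuple[int, ...] = DEFAULT_K_RANGE,
                       ) -> tuple[int, pd.DataFrame, dict[int, np.ndarray]]:
    """Choose k by the composite of the two validity indices.

    For each candidate k the hierarchy is cut, the Dunn index is computed
    on the dissimilarity and Calinski-Harabasz on the embedding
    coordinates; each index is standardized to z-scores across candidates
    and the composite is their mean.  The argmax wins; ties break toward
    smaller k.  Degenerate (infinite) candidates are excluded from the
    standardization and can never win.
    """
    rows = []
    labels_by_k: dict[int, np.ndarray] = {}
    for k in k_range:
        labels = cut_hierarchy(dissimilarity, k)
        labels_by_k[k] = labels
        if np.unique(labels).size < 2:
            rows.append((k, np.nan, np.nan))
            continue
        rows.append((k, dunn_index(dissimilarity, labels),
                     calinski_harabasz(coords, labels)))
    table = pd.DataFrame(rows, columns=["k", "dunn", "calinski_harabasz"])
    table["composite"] = composite_scores(table["dunn"], table["calinski_harabasz"])
    valid = table.dropna(subset=["composite"])
    if valid.empty:
        raise RuntimeError("all candidate k degenerate; cannot select")
    best = valid.sort_values(["composite", "k"], ascending=[False, True]).iloc[0]
    return int(best["k"]), table, labels_by_k


def stability_gap(prox: ProximityMatrix | np.ndarray,
                  labels: np.ndarray) -> pd.DataFrame:
    """Per-cluster OOB-proximity stability: mean within-cluster proximity
    minus mean proximity to all other subjects.  This gap statistic is
    this package's definition of proximity-based cluster stability."""
    P = prox.values if isinstance(prox, ProximityMatrix) else np.asarray(prox)
    labels = np.asarray(labels)
    rows = []
    off_diag = ~np.eye(len(labels), dtype=bool)
    for u in np.unique(labels):
        m = labels == u
        within = P[np.ix_(m, m)][off_diag[np.ix_(m, m)]]
        between = P[np.ix_(m, ~m)]
        rows.append((int(u), int(m.sum()),
                     float(within.mean()) if within.size else np.nan,
                     float(between.mean()) if between.size else np.nan))
    df = pd.DataFrame(rows, columns=["cluster", "n", "mean_within", "mean_between"])
    df["gap"] = df["mean_within"] - df["mean_between"]
    return df


# --------------------------------------------------------------------------
# end-to-end
# --------------------------------------------------------------------------

def cluster_features(features, params: ForestParams = ForestParams(),
                     k_range: tuple[int, ...] = DEFAULT_K_RANGE,
                     mds_dims: int = 3, k: int | None = None,
                     sqrt_transform: bool = True) -> ClusterSolution:
    """Full clustering stage: contrast data, forest, OOB proximity,
    dissimilarity, classical MDS, hierarchy cut, composite-validity model
    selection (unless ``k`` is forced), canonical size-ordered labels."""
    subject_ids = (features.index.to_numpy()
                   if isinstance(features, pd.DataFrame) else None)
    X = _as_array(features)
    if X.shape[1] != N_ROIS:
        warnings.warn(f"expected {N_ROIS} features, got {X.shape[1]}",
                      stacklevel=2)
    fit = fit_proximity_forest(X, None, params)
    prox = compute_oob_proximity(fit)
    D = proximity_to_dissimilarity(prox, sqrt_transform=sqrt_transform)
    coords, eigval, _ = classical_mds(D, m=mds_dims)
    chosen, table, labels_by_k = select_k_composite(D, coords, k_range)
    if k is not None:
        chosen = k
        if k not in labels_by_k:
            labels_by_k[k] = cut_hierarchy(D, k)
    labels = canonicalize_labels(labels_by_k[chosen])
    return ClusterSolution(labels=labels, k=chosen, dissimilarity=D,
                           mds_coordinates=coords, mds_eigenvalues=eigval,
                           validity_table=table, importance=fit.importance,
                           params=params, subject_ids=subject_ids)
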