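"""Distances, Ward.D2 clustering with newick export, PCA, PLS-DA, and
rank-based confirmation tests.

PLS-DA follows the usual supervised workflow on centered and scaled data:
the number of components is chosen by 10-times-repeated 10-fold stratified
cross-validation on the accuracy metric, and features are ranked by VIP
(variable importance in projection).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
import scipy.stats
from scipy.spatial.distance import pdist, squareform
from sklearn.cross_decomposition import PLSRegression
from sklearn.model_selection import RepeatedStratifiedKFold

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------


@dataclass
class DistanceMatrix:
    ids: list[str]
    values: np.ndarray  # symmetric (n, n)
    kind: str = ""  # e.g. "frequency/cells", "exceptionality/mobile"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1] or v.shape[0] != len(self.ids):
            raise ValueError("distance matrix shape does not match ids")
        if not np.allclose(v, v.T, atol=1e-9):
            raise ValueError("distance matrix must be symmetric")
        self.values = v

    @property
    def n(self) -> int:
        return len(self.ids)

    def condensed(self) -> np.ndarray:
        return squareform(self.values, checks=False)


def euclidean_distance_matrix(profiles: pd.DataFrame, kind: str = "") -> DistanceMatrix:
    X = profiles.to_numpy(dtype=float)
    nan_rows = np.isnan(X).any(axis=1)
    if nan_rows.any():
        bad = [profiles.index[i] for i in np.flatnonzero(nan_rows)]
        raise ValueError(f"NaN values in profile rows: {bad}")
    if X.shape[0] < 2:
        raise ValueError("need at least 2 rows")
    return DistanceMatrix(list(profiles.index), squareform(pdist(X)), kind=kind)


# ---------------------------------------------------------------------------
# Ward.D2 hierarchical clustering
# ---------------------------------------------------------------------------


@dataclass
class Dendrogram:
    """Agglomerative merge tree (scipy linkage encoding) over named leaves."""

    linkage: np.ndarray  # (n-1, 4) scipy linkage matrix
    ids: list[str]

    def heights(self) -> np.ndarray:
        return self.linkage[:, 2]

    def cut(self, n_clusters: int) -> np.ndarray:
        return sch.fcluster(self.linkage, t=n_clusters, criterion="maxclust")

    def to_newick(self) -> str:
        tree = sch.to_tree(self.linkage)

        def walk(node, parent_height: float) -> str:
            length = parent_height - node.dist
            if node.is_leaf():
                return f"{self.ids[node.id]}:{length:.10g}"
            left = walk(node.left, node.dist)
            right = walk(node.right, node.dist)
            return f"({left},{right}):{length:.10g}"

        # root branch length 0
        return walk(tree, tree.dist) + ";"


def ward_cluster(D: DistanceMatrix) -> Dendrogram:
    """Ward.D2 agglomeration on a Euclidean distance matrix.

    Uses the Lance-Williams Ward update on the (unsquared) distances, i.e.
    the convention in which merge heights equal the square root of twice
    the increase in within-cluster sum of squares, and heights are
    non-decreasing along merges.
    """
    if D.n < 2:
        raise ValueError("need at least 2 observations")
    Z = sch.linkage(D.condensed(), method="ward")
    return Dendrogram(Z, list(D.ids))


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------


@dataclass
class PCAResult:
    scores: pd.DataFrame
    loadings: pd.DataFrame
    explained_variance_ratio: np.ndarray
    dropped_columns: list[str]


def pca(profiles: pd.DataFrame, center: bool = True, scale: bool = True) -> PCAResult:
    """PCA on (by default) centered and scaled data, via SVD.

    Zero-variance columns are dropped (logged) before scaling.  Component
    signs are fixed so the largest-magnitude loading of each component is
    positive; explained-variance fractions sum to 1 over all components.
    """
    if profiles.shape[0] < 3:
        raise ValueError("need at least 3 rows for PCA")
    X = profiles.to_numpy(dtype=float)
    sd = X.std(axis=0, ddof=1)
    keep = sd > 0
    dropped = [c for c, k in zip(profiles.columns, keep) if not k]
    if dropped:
        logger.info("PCA: dropping %d zero-variance columns", len(dropped))
    X = X[:, keep]
    if X.shape[1] == 0:
        raise ValueError("degenerate input: all columns constant")
    if center:
        X = X - X.mean(axis=0)
    if scale:
        X = X / X.std(axis=0, ddof=1)
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    # sign convention: largest-magnitude loading positive
    for a in range(Vt.shape[0]):
        j = np.argmax(np.abs(Vt[a]))
        if Vt[a, j] < 0:
            Vt[a] *= -1
            U[:, a] *= -1
    scores = U * S
    var = S**2
    ratio = var / var.sum()
    comp_names = [f"PC{a + 1}" for a in range(len(S))]
    cols = [c for c, k in zip(profiles.columns, keep) if k]
    return PCAResult(
        scores=pd.DataFrame(scores, index=profiles.index, columns=comp_names),
        loadings=pd.DataFrame(Vt.T, index=cols, columns=comp_names),
        explained_variance_ratio=ratio,
        dropped_columns=dropped,
    )


# ---------------------------------------------------------------------------
# PLS-DA
# ---------------------------------------------------------------------------


@dataclass
class PLSDAResult:
    n_components: int
    accuracy: pd.DataFrame  # index n, columns mean/sd over CV
    vip: pd.Series  # per-feature VIP, mean of squares = 1
    loadings: pd.DataFrame
    classes: list[str]
    class_means: pd.DataFrame  # per-class mean of each (raw) feature
    predictions: pd.Series


def _vip_scores(model: PLSRegression) -> np.ndarray:
    """VIP_j = sqrt(p * sum_a SSY_a * (w_ja / ||w_a||)^2 / sum_a SSY_a)."""
    T = model.x_scores_
    W = model.x_weights_
    Q = model.y_loadings_
    p, A = W.shape
    ssy = np.sum(T**2, axis=0) * np.sum(Q**2, axis=0)
    wnorm2 = np.sum(W**2, axis=0)
    inner = (W**2 / wnorm2) @ ssy
    return np.sqrt(p * inner / ssy.sum())


def plsda(
    profiles: pd.DataFrame,
    labels,
    n_grid=range(1, 11),
    folds: int = 10,
    repeats: int = 10,
    seed: int = 0,
) -> PLSDAResult:
    """PLS-DA with repeated stratified cross-validated component selection.

    The class membership is one-hot encoded and regressed on the centered,
    scaled feature matrix by PLS (NIPALS); a sample is assigned to the class
    with the largest predicted response.  The retained number of components
    maximizes mean CV accuracy (smallest n on ties).
    """
    y = pd.Series(list(labels), index=profiles.index)
    classes = sorted(y.unique())
    if len(classes) < 2:
        raise ValueError("PLS-DA needs at least 2 classes")
    min_class = int(y.value_counts().min())
    if min_class < folds:
        logger.warning(
            "smallest class has %d members; reducing folds from %d to %d",
            min_class, folds, max(2, min_class),
        )
        folds = max(2, min_class)
    X = profiles.to_numpy(dtype=float)
    Y = np.column_stack([(y == c).to_numpy(float) for c in classes])
    y_idx = np.array([classes.index(c) for c in y])
    max_comp = min(max(n_grid), X.shape[0] - 1 - X.shape[0] // folds, X.shape[1])
    grid = [n for n in n_grid if n <= max_comp]
    cv = RepeatedStratifiedKFold(n_splits=folds, n_repeats=repeats, random_state=seed)
    splits = list(cv.split(X, y_idx))
    acc = {n: [] for n in grid}
    for train, test in splits:
        for n in grid:
            m = PLSRegression(n_components=n, scale=True)
            m.fit(X[train], Y[train])
            pred = np.argmax(m.predict(X[test]), axis=1)
            acc[n].append(float(np.mean(pred == y_idx[test])))
    table = pd.DataFrame(
        {
            "n_components": grid,
            "mean_accuracy": [float(np.mean(acc[n])) for n in grid],
            "sd_accuracy": [float(np.std(acc[n])) for n in grid],
        }
    ).set_index("n_components")
    best = table["mean_accuracy"].round(12)
    n_best = int(best.index[np.argmax(best.to_numpy())])  # first max = smallest n
    final = PLSRegression(n_components=n_best, scale=True)
    final.fit(X, Y)
    vip = pd.Series(_vip_scores(final), index=profiles.columns, name="VIP")
    pred = np.argmax(final.predict(X), axis=1)
    class_means = pd.DataFrame(
        {c: profiles[y == c].mean(axis=0) for c in classes}
    )
    return PLSDAResult(
        n_components=n_best,
        accuracy=table,
        vip=vip,
        loadings=pd.DataFrame(
            final.x_loadings_,
            index=profiles.columns,
            columns=[f"comp{a + 1}" for a in range(n_best)],
        ),
        classes=classes,
        class_means=class_means,
        predictions=pd.Series([classes[i] for i in pred], index=profiles.index),
    )


def top_discriminant(result: PLSDAResult, n: int = 10) -> pd.DataFrame:
    """Top-``n`` features by VIP, ties broken lexicographically.

    Each feature is annotated with the class in which its mean frequency is
    highest, reproducing the split into "high frequency" vs "low frequency"
    discriminant sets for a two-class comparison.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    if n > len(result.vip):
        logger.warning("n=%d > %d features; clamping", n, len(result.vip))
        n = len(result.vip)
    order = sorted(result.vip.index, key=lambda f: (-result.vip[f], f))[:n]
    rows = []
    for feat in order:
        means = result.class_means.loc[feat]
        rows.append(
            {
                "feature": feat,
                "vip": float(result.vip[feat]),
                "high_in": means.idxmax(),
            }
        )
    return pd.DataFrame(rows, columns=["feature", "vip", "high_in"])


# ---------------------------------------------------------------------------
# Mann-Whitney confirmation test
# ---------------------------------------------------------------------------


def mann_whitney(values_a, values_b) -> float:
    """Two-sided Mann-Whitney-Wilcoxon p-value.

    Exact enumeration of all C(n_a + n_b, n_a) group assignments when both
    groups have <= 8 members (ties handled by the 1/2 convention on U);
    otherwise the normal approximation with tie correction.
    """
    a = np.asarray(list(values_a), dtype=float)
    b = np.asarray(list(values_b), dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    if len(a) <= 8 and len(b) <= 8:
        pooled = np.concatenate([a, b])
        n, na = len(pooled), len(a)
        mu = na * (n - na) / 2.0

        def u_stat(idx_a: tuple[int, ...]) -> float:
            mask = np.zeros(n, dtype=bool)
            mask[list(idx_a)] = True
            xa, xb = pooled[mask], pooled[~mask]
            gt = (xa[:, None] > xb[None, :]).sum()
            eq = (xa[:, None] == xb[None, :]).sum()
            return gt + 0.5 * eq

        u_obs = u_stat(tuple(range(na)))
        dev_obs = abs(u_obs - mu)
        total = comb(n, na)
        hits = sum(
            1
            for idx in combinations(range(n), na)
            if abs(u_stat(idx) - mu) >= dev_obs - 1e-12
        )
        return hits / total
    res = scipy.stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return float(min(res.pvalue, 1.0))


def t_test(values_a, values_b) -> float:
    """Welch two-sample t-test (two-sided), offered alongside Mann-Whitney."""
    res = scipy.stats.ttest_ind(list(values_a), list(values_b), equal_var=False)
    return float(res.pvalue)
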