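"""Per-probeset relevance scoring and total feature rankings.

Each ranker consumes a groups x features matrix of (typically z-scored)
fold changes and binary 0/1 labels, and emits a :class:`FeatureRanking`: a
permutation of all feature indices, best first, plus the relevance score each
feature was ranked by.  Implemented rankers:

* ``GOLUB``   — signal-to-noise ratio |mu1 - mu0| / (sd1 + sd0)
* ``SVM``     — |weight| of a linear soft-margin SVM
* ``SVM_RFE`` — recursive feature elimination driven by linear-SVM weights
* ``PAM``     — nearest-shrunken-centroids standardized centroid distance
* ``PCA``     — |loading| on the first principal component (unsupervised)
* ``PLSDA``   — |weight| on the first PLS component against a +/-1 response

Ties are broken by feature index (stable), so every ranking is deterministic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from sklearn.cross_decomposition import PLSRegression
from sklearn.decomposition import PCA
from sklearn.svm import SVC

METHODS = ("GOLUB", "SVM", "SVM_RFE", "PAM", "PCA", "PLSDA")


@dataclass
class FeatureRanking:
    """Total ordering of all features by one method, best first."""

    method: str
    ranks: np.ndarray   # permutation of 0..P-1
    scores: np.ndarray  # relevance along `ranks`, non-increasing (up to ties)

    def __post_init__(self) -> None:
        self.ranks = np.asarray(self.ranks, dtype=np.intp)
        self.scores = np.asarray(self.scores, dtype=float)
        if self.ranks.shape != self.scores.shape:
            raise ValueError("ranks and scores must have equal length")
        if not np.array_equal(np.sort(self.ranks), np.arange(self.ranks.size)):
            raise ValueError("ranks is not a permutation of 0..P-1")

    def top(self, size: int) -> np.ndarray:
        return self.ranks[:size]

    def positions(self) -> np.ndarray:
        """Rank position (0 = best) per feature index."""
        pos = np.empty(self.ranks.size, dtype=np.intp)
        pos[self.ranks] = np.arange(self.ranks.size)
        return pos


def _ranking_from_scores(scores: np.ndarray, method: str) -> FeatureRanking:
    scores = np.asarray(scores, dtype=float)
    # descending score, ties by ascending feature index
    order = np.lexsort((np.arange(scores.size), -scores))
    return FeatureRanking(method=method, ranks=order, scores=scores[order])


def _check_binary(y) -> np.ndarray:
    y = np.asarray(y)
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError(f"labels must contain exactly 2 classes, got {classes.tolist()}")
    return y


def golub_scores(X, y) -> np.ndarray:
    """Signed signal-to-noise ratio (mu1 - mu0) / (sd1 + sd0) per feature."""
    X = np.asarray(X, dtype=float)
    y = _check_binary(y)
    classes = np.unique(y)
    groups = [X[y == c] for c in classes]
    for c, g in zip(classes, groups):
        if g.shape[0] < 2:
            raise ValueError(f"class {c!r} has fewer than 2 profiles; SD undefined")
    mu0, mu1 = groups[0].mean(axis=0), groups[1].mean(axis=0)
    sd0, sd1 = groups[0].std(axis=0, ddof=1), groups[1].std(axis=0, ddof=1)
    denom = sd0 + sd1
    denom = np.where(denom == 0.0, np.finfo(float).tiny, denom)
    return (mu1 - mu0) / denom


def golub_rank(X, y) -> FeatureRanking:
    return _ranking_from_scores(np.abs(golub_scores(X, y)), "GOLUB")


def _linear_svm_weights(X, y, C: float) -> np.ndarray:
    model = SVC(kernel="linear", C=C)
    model.fit(X, y)
    return model.coef_.ravel()


def svm_weight_rank(X, y, C: float = 1.0) -> FeatureRanking:
    X = np.asarray(X, dtype=float)
    y = _check_binary(y)
    return _ranking_from_scores(np.abs(_linear_svm_weights(X, y, C)), "SVM")


def rfe_schedule(n_features: int, halve_above: int = 10) -> list[int]:
    """Sizes visited by the elimination schedule, starting at ``n_features``.

    While more than ``halve_above`` features survive, keep ceil(n/2) of them
    (never dropping below ``halve_above`` in one step); from ``halve_above``
    on, eliminate one feature per iteration down to 1.
    """
    if halve_above < 1:
        raise ValueError("halve_above must be >= 1 (schedule would not terminate)")
    sizes = [n_features]
    n = n_features
    while n > 1:
        if n > halve_above:
            half = math.ceil(n / 2)
            n = half if half >= halve_above else halve_above
        else:
            n -= 1
        sizes.append(n)
    return sizes


def svm_rfe_rank(X, y, C: float = 1.0, halve_above: int = 10) -> FeatureRanking:
    """Recursive feature elimination with a linear SVM.

    The ranking is the reverse elimination order; features eliminated in the
    same batch are ordered by their |weight| at elimination time.
    """
    X = np.asarray(X, dtype=float)
    y = _check_binary(y)
    P = X.shape[1]
    sizes = rfe_schedule(P, halve_above=halve_above)
    active = np.arange(P)
    eliminated: list[int] = []  # worst first
    for next_size in sizes[1:]:
        w = np.abs(_linear_svm_weights(X[:, active], y, C))
        # ascending |w|, ties by ascending feature index
        order = np.lexsort((active, w))
        n_drop = active.size - next_size
        eliminated.extend(active[order[:n_drop]].tolist())
        active = np.sort(active[order[n_drop:]])
    eliminated.extend(active.tolist())  # the single survivor, best of all
    ranks = np.array(eliminated[::-1], dtype=np.intp)
    scores = np.arange(P, 0, -1, dtype=float)  # P down to 1: elimination order
    return FeatureRanking(method="SVM_RFE", ranks=ranks, scores=scores)


# ---------------------------------------------------------------------------
# Nearest shrunken centroids (PAM)
# ---------------------------------------------------------------------------

@dataclass
class PamStatistics:
    """Sufficient statistics of the nearest-shrunken-centroids model.

    ``d`` holds the standardized centroid distances d_kj = (x̄_kj − x̄_j) /
    (m_k (s_j + s0)) with m_k = sqrt(1/n_k − 1/n) and s0 the median of the
    pooled within-class SDs s_j.
    """

    classes: np.ndarray
    priors: np.ndarray
    overall_centroid: np.ndarray
    centroids: np.ndarray   # K x P
    s: np.ndarray           # pooled within-class SD per feature
    s0: float
    m: np.ndarray           # per-class m_k
    d: np.ndarray           # K x P

    def shrunken_d(self, delta: float) -> np.ndarray:
        return np.sign(self.d) * np.maximum(np.abs(self.d) - delta, 0.0)

    def shrunken_centroids(self, delta: float) -> np.ndarray:
        dprime = self.shrunken_d(delta)
        return self.overall_centroid + self.m[:, None] * (self.s + self.s0) * dprime


def pam_statistics(X, y) -> PamStatistics:
    X = np.asarray(X, dtype=float)
    y = _check_binary(y)
    classes, counts = np.unique(y, return_counts=True)
    n, P = X.shape
    K = classes.size
    if n - K < 1:
        raise ValueError("need at least one more profile than classes for the pooled SD")
    centroids = np.vstack([X[y == c].mean(axis=0) for c in classes])
    overall = X.mean(axis=0)
    ss = np.zeros(P)
    for k, c in enumerate(classes):
        resid = X[y == c] - centroids[k]
        ss += (resid ** 2).sum(axis=0)
    s = np.sqrt(ss / (n - K))
    s0 = float(np.median(s))
    if s0 == 0.0 and np.all(s == 0.0):
        raise ValueError("all features have zero within-class variance")
    m = np.sqrt(1.0 / counts - 1.0 / n)
    denom = m[:, None] * (s + s0)
    d = (centroids - overall) / denom
    return PamStatistics(
        classes=classes, priors=counts / n, overall_centroid=overall,
        centroids=centroids, s=s, s0=s0, m=m, d=d,
    )


def pam_rank(X, y, delta: float = 0.0) -> FeatureRanking:
    stats = pam_statistics(X, y)
    scores = np.abs(stats.shrunken_d(delta)).max(axis=0)
    return _ranking_from_scores(scores, "PAM")


# ---------------------------------------------------------------------------
# Loading-based variants
# ---------------------------------------------------------------------------

def pca_loading_rank(X) -> FeatureRanking:
    """Rank by |loading| on the first principal component (label-free)."""
    X = np.asarray(X, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("need >= 2 profiles")
    if np.allclose(X, X[0]):
        raise ValueError("constant matrix has no principal axis")
    pca = PCA(n_components=1, svd_solver="full")
    pca.fit(X)
    return _ranking_from_scores(np.abs(pca.components_[0]), "PCA")


def plsda_loading_rank(X, y) -> FeatureRanking:
    """Rank by |weight| on the first PLS component against the +/-1 label."""
    X = np.asarray(X, dtype=float)
    y = _check_binary(y)
    if X.shape[0] < 2:
        raise ValueError("need >= 2 profiles")
    classes = np.unique(y)
    target = np.where(y == classes[1], 1.0, -1.0)
    pls = PLSRegression(n_components=1, scale=False)
    pls.fit(X, target)
    return _ranking_from_scores(np.abs(pls.x_weights_[:, 0]), "PLSDA")


#: method name -> callable(X, y, **kwargs) -> FeatureRanking
RANKERS = {
    "GOLUB": lambda X, y, **kw: golub_rank(X, y),
    "SVM": lambda X, y, C=1.0, **kw: svm_weight_rank(X, y, C=C),
    "SVM_RFE": lambda X, y, C=1.0, halve_above=10, **kw: svm_rfe_rank(
        X, y, C=C, halve_above=halve_above),
    "PAM": lambda X, y, delta=0.0, **kw: pam_rank(X, y, delta=delta),
    "PCA": lambda X, y, **kw: pca_loading_rank(X),
    "PLSDA": lambda X, y, **kw: plsda_loading_rank(X, y),
}


def rank_features(method: str, X, y, **kwargs) -> FeatureRanking:
    if method not in RANKERS:
        raise ValueError(f"unknown ranking method {method!r}; expected one of {METHODS}")
    return RANKERS[method](X, y, **kwargs)


def write_ranking(ranking: FeatureRanking, probeset_ids: list[str], path) -> None:
    """Serialize a ranking as tab-delimited rank / probeset_id / method / score."""
    import pandas as pd

    pd.DataFrame({
        "rank": np.arange(1, ranking.ranks.size + 1),
        "probeset_id": [probeset_ids[i] for i in ranking.ranks],
        "method": ranking.method,
        "score": ranking.scores,
    }).to_csv(path, sep="\t", index=False)
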