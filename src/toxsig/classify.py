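"""Binary compound-class classifiers emitting confidence scores in [0, 1].

Six classifier kinds are supported: linear SVM, k-nearest neighbors, PAM
(nearest shrunken centroids), Gaussian naive Bayes, random forest, and
Golub-style weighted voting.  Every kind emits, for each treatment-group
profile, a confidence in [0, 1] interpreted as the estimated probability of
the positive class (label 1):

* SVM decision values pass through the logistic map 1/(1+exp(-x)).
* Weighted-voting prediction strength v in [-1, 1] maps affinely to (v+1)/2.
* KNN confidence is the fraction of positively labeled nearest neighbors.
* PAM, naive Bayes, and random forest emit native posteriors/vote fractions.

Inputs are expected to be z-score standardized signature fold-change
matrices (standardization statistics fitted on the training profiles only;
see :func:`toxsig.expression.zscore_fit_apply`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
from scipy.special import expit
from sklearn.ensemble import RandomForestClassifier
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

from .scoring import PamStatistics, golub_scores, pam_statistics

KINDS = ("SVM", "KNN", "PAM", "NAIVE_BAYES", "RANDOM_FOREST", "WEIGHTED_VOTING")

#: hyperparameter grids searched in the inner cross-validation loop; values
#: are listed in ascending order and AUC ties resolve toward the earlier
#: (smaller) value.  The PAM shrinkage grid is data-driven (see `pam_delta_grid`).
DEFAULT_GRIDS: dict[str, dict[str, list]] = {
    "SVM": {"C": [0.01, 0.1, 1.0, 10.0, 100.0]},
    "KNN": {"n_neighbors": [1, 3, 5]},
    "PAM": {"delta": None},  # placeholder: resolved per training set
    "NAIVE_BAYES": {},
    "RANDOM_FOREST": {"max_features": ["sqrt", 1.0 / 3.0]},
    "WEIGHTED_VOTING": {},
}


@dataclass(frozen=True)
class ClassifierSpec:
    """One classifier kind plus its hyperparameters and seed."""

    kind: str
    hyperparameters: dict[str, Any] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown classifier kind {self.kind!r}; expected one of {KINDS}")


@dataclass
class PredictionResult:
    """Confidence of one classifier for one treatment group."""

    group_id: str
    classifier: str
    confidence: float

    @property
    def predicted_positive(self) -> bool:
        return self.confidence >= 0.5


def pam_delta_grid(X, y, n: int = 10) -> list[float]:
    """Evenly spaced shrinkage thresholds from 0 to max |d| on the training set."""
    stats = pam_statistics(X, y)
    top = float(np.abs(stats.d).max())
    return np.linspace(0.0, top, n).tolist()


class TrainedModel:
    """A fitted binary classifier; ``predict_confidence`` maps profiles to [0,1]."""

    def __init__(self, spec: ClassifierSpec, n_features: int):
        self.spec = spec
        self.n_features = n_features

    def _check(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != self.n_features:
            raise ValueError(
                f"feature mismatch: model was trained on {self.n_features} "
                f"signature features, got {X.shape[1]}"
            )
        return X

    def predict_confidence(self, X) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError


class _SklearnModel(TrainedModel):
    def __init__(self, spec, n_features, estimator, positive_index):
        super().__init__(spec, n_features)
        self.estimator = estimator
        self.positive_index = positive_index

    def predict_confidence(self, X) -> np.ndarray:
        X = self._check(X)
        if self.spec.kind == "SVM":
            d = self.estimator.decision_function(X)
            if self.positive_index == 0:
                d = -d
            return expit(d)
        proba = self.estimator.predict_proba(X)
        return proba[:, self.positive_index]


class _WeightedVotingModel(TrainedModel):
    """Golub weighted voting: each feature casts a signal-to-noise-weighted
    vote relative to the midpoint of its class means; the prediction strength
    (|V_win| - |V_lose|) / (|V_win| + |V_lose|) in [-1, 1] is rescaled to [0, 1].
    """

    def __init__(self, spec, weights, midpoints):
        super().__init__(spec, weights.size)
        self.weights = weights
        self.midpoints = midpoints

    def predict_confidence(self, X) -> np.ndarray:
        X = self._check(X)
        votes = self.weights * (X - self.midpoints)
        v_pos = np.where(votes > 0, votes, 0.0).sum(axis=1)
        v_neg = -np.where(votes < 0, votes, 0.0).sum(axis=1)
        total = v_pos + v_neg
        strength = np.zeros(X.shape[0])  # all-zero votes: abstain at 0.5
        nz = total > 0
        strength[nz] = (v_pos[nz] - v_neg[nz]) / total[nz]
        return (strength + 1.0) / 2.0


class _PamModel(TrainedModel):
    def __init__(self, spec, stats: PamStatistics, delta: float):
        super().__init__(spec, stats.centroids.shape[1])
        self.stats = stats
        self.delta = delta
        self.shrunken = stats.shrunken_centroids(delta)

    def predict_confidence(self, X) -> np.ndarray:
        X = self._check(X)
        scale = self.stats.s + self.stats.s0
        # discriminant score per class: standardized distance minus 2 log prior
        delta_k = np.stack([
            (((X - self.shrunken[k]) / scale) ** 2).sum(axis=1)
            - 2.0 * np.log(self.stats.priors[k])
            for k in range(self.stats.classes.size)
        ], axis=1)
        delta_k -= delta_k.min(axis=1, keepdims=True)
        post = np.exp(-0.5 * delta_k)
        post /= post.sum(axis=1, keepdims=True)
        positive = int(np.flatnonzero(self.stats.classes == 1)[0])
        return post[:, positive]


class _MirroredModel(TrainedModel):
    """Confidence complement of an inner model (exact label-swap symmetry)."""

    def __init__(self, inner: TrainedModel):
        super().__init__(inner.spec, inner.n_features)
        self.inner = inner

    def predict_confidence(self, X) -> np.ndarray:
        return 1.0 - self.inner.predict_confidence(X)


def train(spec: ClassifierSpec, X, y) -> TrainedModel:
    """Fit one classifier on z-scored signature features; labels are 0/1."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if X.ndim != 2 or X.shape[1] == 0:
        raise ValueError("empty signature: X must be 2-D with >= 1 feature")
    classes = np.unique(y)
    if classes.size != 2 or not np.all(np.isin(classes, [0, 1])):
        raise ValueError(f"labels must contain both classes 0 and 1, got {classes.tolist()}")
    # canonical label orientation: the first profile's class is coded 0, so a
    # fit with complemented labels reuses the identical underlying problem and
    # label-swap symmetry (confidence -> 1 - confidence) holds exactly
    if y[0] == 1:
        return _MirroredModel(train(spec, X, 1 - y))
    hp = spec.hyperparameters
    if spec.kind == "SVM":
        est = SVC(kernel="linear", C=float(hp.get("C", 1.0)))
        est.fit(X, y)
        return _SklearnModel(spec, X.shape[1], est, int(np.flatnonzero(est.classes_ == 1)[0]))
    if spec.kind == "KNN":
        k = min(int(hp.get("n_neighbors", 3)), X.shape[0])
        est = KNeighborsClassifier(n_neighbors=k)
        est.fit(X, y)
        return _SklearnModel(spec, X.shape[1], est, int(np.flatnonzero(est.classes_ == 1)[0]))
    if spec.kind == "NAIVE_BAYES":
        est = GaussianNB()
        est.fit(X, y)
        return _SklearnModel(spec, X.shape[1], est, int(np.flatnonzero(est.classes_ == 1)[0]))
    if spec.kind == "RANDOM_FOREST":
        est = RandomForestClassifier(
            n_estimators=int(hp.get("n_estimators", 500)),
            max_features=hp.get("max_features", "sqrt"),
            random_state=spec.seed,
        )
        est.fit(X, y)
        return _SklearnModel(spec, X.shape[1], est, int(np.flatnonzero(est.classes_ == 1)[0]))
    if spec.kind == "PAM":
        stats = pam_statistics(X, y)
        return _PamModel(spec, stats, float(hp.get("delta", 0.0)))
    # WEIGHTED_VOTING
    weights = golub_scores(X, y)  # signed: positive weight votes for class 1
    classes_present = np.unique(y)
    mu0 = X[y == classes_present[0]].mean(axis=0)
    mu1 = X[y == classes_present[1]].mean(axis=0)
    return _WeightedVotingModel(spec, weights, (mu0 + mu1) / 2.0)


def weighted_voting_fit_predict(X_train, y_train, X_new) -> np.ndarray:
    """Convenience wrapper: fit weighted voting and score new profiles."""
    model = train(ClassifierSpec(kind="WEIGHTED_VOTING"), X_train, y_train)
    return model.predict_confidence(X_new)


def pam_classify(X_train, y_train, X_new, delta: float = 0.0) -> np.ndarray:
    """Convenience wrapper: fit the shrunken-centroid classifier and score."""
    model = train(ClassifierSpec(kind="PAM", hyperparameters={"delta": delta}),
                  X_train, y_train)
    return model.predict_confidence(X_new)


def grid_points(kind: str, X, y, grid: dict[str, list] | None = None):
    """Enumerate hyperparameter settings for one kind, most regularized first."""
    base = dict(DEFAULT_GRIDS[kind]) if grid is None else dict(grid)
    if kind == "PAM" and base.get("delta") is None:
        base["delta"] = pam_delta_grid(X, y)
    if not base:
        return [{}]
    names = sorted(base)
    points = [{}]
    for name in names:
        points = [dict(p, **{name: v}) for v in base[name] for p in points]
    return points
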