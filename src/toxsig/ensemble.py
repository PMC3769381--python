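"""Stage 1: bootstrap ensemble feature selection and consensus signatures.

The engine draws class-stratified 90% subsamples ("bootstraps") of the
training profiles, ranks all probesets on every subsample with each selector
of the chosen ensemble, evaluates out-of-bag ROC across a grid of signature
sizes, locates the optimal size with a smoothing spline, quantifies selection
stability with the Kuncheva index, and finally aggregates all n x m rankings
into one consensus signature by ascending rank sums.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import make_smoothing_spline

from . import classify, scoring
from .expression import zscore_fit_apply

logger = logging.getLogger(__name__)

DEFAULT_SIZE_GRID = (2, 5, 10, 15, 20, 30, 40, 60, 80, 100)

#: the three selector ensembles evaluated in the study
ENSEMBLES = {
    "full": ("GOLUB", "SVM", "SVM_RFE", "PAM"),
    "svm_only": ("SVM", "SVM_RFE"),
    "projection": ("PCA", "PLSDA"),
}

#: selector -> classifier kind used to judge its rankings out-of-bag; each
#: ranking is scored with its natural decision rule
OOB_CLASSIFIER = {
    "SVM": "SVM",
    "SVM_RFE": "SVM",
    "PAM": "PAM",
    "GOLUB": "WEIGHTED_VOTING",
    "PCA": "WEIGHTED_VOTING",
    "PLSDA": "WEIGHTED_VOTING",
}


# ---------------------------------------------------------------------------
# Bootstrap plan
# ---------------------------------------------------------------------------

@dataclass
class BootstrapPlan:
    """Class-stratified 90% subsamples without replacement.

    ``assignments[b]`` is an ``(in_bag, out_of_bag)`` pair of index arrays;
    the two sets are disjoint and jointly cover the training set.
    """

    n_bootstraps: int
    in_bag_fraction: float
    seed: int
    assignments: list[tuple[np.ndarray, np.ndarray]]


def _stratified_quotas(counts: np.ndarray, total_in: int) -> np.ndarray:
    """Per-class in-bag quotas by largest remainder, summing to ``total_in``."""
    n = counts.sum()
    exact = counts * total_in / n
    quotas = np.floor(exact).astype(int)
    remainder = exact - quotas
    shortfall = total_in - quotas.sum()
    for k in np.argsort(-remainder)[:shortfall]:
        quotas[k] += 1
    return quotas


def draw_bootstraps(y, n_bootstraps: int = 25, in_bag_fraction: float = 0.9,
                    seed: int = 0) -> BootstrapPlan:
    """Draw the subsampling plan used by Stage 1.

    In-bag size is round(in_bag_fraction x n), stratified by class; the
    complementary profiles form the out-of-bag set of that bootstrap.
    """
    y = np.asarray(y)
    n = y.size
    if n < 10:
        raise ValueError(f"training set too small for subsampling ({n} < 10 profiles)")
    classes, counts = np.unique(y, return_counts=True)
    if np.any(counts < 2):
        raise ValueError("every class needs >= 2 training profiles")
    total_in = round(in_bag_fraction * n)
    quotas = _stratified_quotas(counts, total_in)
    if np.any(quotas == counts):
        logger.info("some class is fully in-bag; its out-of-bag set will be empty")
    rng = np.random.default_rng(seed)
    assignments = []
    for _ in range(n_bootstraps):
        in_bag: list[np.ndarray] = []
        for c, q in zip(classes, quotas):
            members = np.flatnonzero(y == c)
            in_bag.append(rng.permutation(members)[:q])
        in_idx = np.sort(np.concatenate(in_bag))
        oob_idx = np.setdiff1d(np.arange(n), in_idx)
        assignments.append((in_idx, oob_idx))
    return BootstrapPlan(n_bootstraps=n_bootstraps, in_bag_fraction=in_bag_fraction,
                         seed=seed, assignments=assignments)


# ---------------------------------------------------------------------------
# Kuncheva stability index
# ---------------------------------------------------------------------------

def kuncheva_index(A, B, P: int) -> float:
    """Chance-corrected similarity of two equal-size feature subsets.

    KI = (r P - k^2) / (k (P - k)) for |A| = |B| = k and |A n B| = r.
    Equals 1 for identical subsets, -1 for disjoint subsets that each hold
    half of the P features, and 0 in expectation for independent draws.
    """
    A, B = set(A), set(B)
    k = len(A)
    if len(B) != k:
        raise ValueError(f"subsets must have equal size, got {k} and {len(B)}")
    if k == 0 or k >= P:
        raise ValueError(f"subset size must satisfy 0 < k < P, got k={k}, P={P}")
    r = len(A & B)
    return (r * P - k * k) / (k * (P - k))


def mean_kuncheva(subsets, P: int) -> float:
    """Mean Kuncheva index over all unordered pairs of equal-size subsets."""
    subsets = [set(s) for s in subsets]
    if len(subsets) < 2:
        raise ValueError("need >= 2 subsets")
    sizes = {len(s) for s in subsets}
    if len(sizes) != 1:
        raise ValueError(f"subsets have mixed sizes: {sorted(sizes)}")
    vals = [kuncheva_index(a, b, P)
            for i, a in enumerate(subsets) for b in subsets[i + 1:]]
    return float(np.mean(vals))


# ---------------------------------------------------------------------------
# Out-of-bag performance and spline optimum
# ---------------------------------------------------------------------------

@dataclass
class SizePerformanceCurve:
    """Mean out-of-bag AUC per evaluated signature size for one selector."""

    method: str
    sizes: list[int]
    mean_roc: list[float]
    optimum_size: int | None = None


@dataclass
class StabilityResult:
    """Mean pairwise Kuncheva index of the bootstrap signatures, per size."""

    method: str
    sizes: list[int]
    per_size_KI: list[float]


def bootstrap_rankings(X, y, plan: BootstrapPlan, method: str,
                       **ranker_kwargs) -> list[scoring.FeatureRanking]:
    """Rank all features on the z-scored in-bag data of every bootstrap."""
    X = np.asarray(X, dtype=float)
    rankings = []
    for in_idx, _ in plan.assignments:
        Xin, _ = zscore_fit_apply(X[in_idx])
        rankings.append(scoring.rank_features(method, Xin, y[in_idx], **ranker_kwargs))
    return rankings


def evaluate_oob(X, y, plan: BootstrapPlan, rankings: list[scoring.FeatureRanking],
                 sizes, method: str) -> SizePerformanceCurve:
    """Mean out-of-bag AUC of the selector's paired classifier per size.

    For each bootstrap and size the classifier paired with the selector is
    trained on the in-bag top-``size`` features (z-scored on in-bag) and
    scored on the out-of-bag profiles.  Bootstraps whose out-of-bag set lacks
    a class contribute no AUC and are excluded from the mean.
    """
    from .evaluate import auc  # local import to avoid a cycle

    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    sizes = sorted(int(s) for s in sizes)
    if sizes[0] < 2 or sizes[-1] > X.shape[1]:
        raise ValueError(f"sizes must lie in [2, n_features], got {sizes}")
    kind = OOB_CLASSIFIER[method]
    mean_roc = []
    for size in sizes:
        aucs = []
        for (in_idx, oob_idx), ranking in zip(plan.assignments, rankings):
            if oob_idx.size == 0 or np.unique(y[oob_idx]).size < 2:
                logger.debug("bootstrap with one-class out-of-bag set skipped at size %d", size)
                continue
            feats = ranking.top(size)
            Xin, Xoob = zscore_fit_apply(X[np.ix_(in_idx, feats)],
                                         X[np.ix_(oob_idx, feats)])
            model = classify.train(classify.ClassifierSpec(kind=kind), Xin, y[in_idx])
            aucs.append(auc(model.predict_confidence(Xoob), y[oob_idx]))
        mean_roc.append(float(np.mean(aucs)) if aucs else float("nan"))
    return SizePerformanceCurve(method=method, sizes=sizes, mean_roc=mean_roc)


def spline_optimum(curve: SizePerformanceCurve) -> int | None:
    """Signature size maximizing a cubic smoothing spline through the curve.

    The spline (smoothing parameter by generalized cross-validation) is
    evaluated on every integer size between the smallest and largest grid
    point; flat stretches resolve toward the smaller size (parsimony).  With
    fewer than 4 points the raw argmax is used instead; with no defined
    points at all (every bootstrap had a one-class out-of-bag set) the
    optimum is undefined and None is returned.
    """
    x = np.asarray(curve.sizes, dtype=float)
    yv = np.asarray(curve.mean_roc, dtype=float)
    ok = np.isfinite(yv)
    x, yv = x[ok], yv[ok]
    if x.size == 0:
        logger.warning("performance curve for %s has no defined points; "
                       "no size optimum", curve.method)
        return None
    if x.size < 4:
        logger.warning("only %d curve points; using raw argmax instead of a spline", x.size)
        return int(x[np.argmax(yv)])
    if np.allclose(yv, yv[0]):
        return int(x[0])
    if x.size == 4:  # GCV smoothing needs >= 5 points; interpolate instead
        from scipy.interpolate import CubicSpline

        spline = CubicSpline(x, yv)
    else:
        spline = make_smoothing_spline(x, yv)
    grid = np.arange(int(x[0]), int(x[-1]) + 1)
    return int(grid[np.argmax(spline(grid))])


def stability_by_size(rankings: list[scoring.FeatureRanking], sizes, P: int) -> list[float]:
    return [mean_kuncheva([set(r.top(int(s))) for r in rankings], P) for s in sizes]


# ---------------------------------------------------------------------------
# Consensus signature
# ---------------------------------------------------------------------------

@dataclass
class ConsensusSignature:
    """Rank-sum aggregated signature with provenance."""

    task: str
    duration_days: int | None
    probeset_ids: list[str]
    size: int
    methods: tuple[str, ...]
    n_bootstraps: int
    seed: int
    rank_sums: list[float] = field(default_factory=list)
    feature_indices: np.ndarray | None = None

    def __post_init__(self) -> None:
        if len(set(self.probeset_ids)) != len(self.probeset_ids):
            raise ValueError("signature probesets must be unique")
        if self.size != len(self.probeset_ids):
            raise ValueError("size must equal the number of probesets")


def consensus_order(rankings: list[scoring.FeatureRanking]) -> tuple[np.ndarray, np.ndarray]:
    """Feature order by ascending rank sum over all rankings (ties by index)."""
    if not rankings:
        raise ValueError("no rankings given")
    P = rankings[0].ranks.size
    if any(r.ranks.size != P for r in rankings):
        raise ValueError("rankings cover different feature universes")
    rank_sums = np.zeros(P)
    for r in rankings:
        rank_sums += r.positions() + 1  # 1-based ranks
    order = np.lexsort((np.arange(P), rank_sums))
    return order, rank_sums


def consensus_rank(rankings: list[scoring.FeatureRanking], size: int,
                   probeset_ids: list[str], task: str = "",
                   duration_days: int | None = None, seed: int = 0,
                   methods: tuple[str, ...] = (), n_bootstraps: int = 0) -> ConsensusSignature:
    order, rank_sums = consensus_order(rankings)
    top = order[:size]
    return ConsensusSignature(
        task=task, duration_days=duration_days,
        probeset_ids=[probeset_ids[i] for i in top], size=size,
        methods=methods, n_bootstraps=n_bootstraps, seed=seed,
        rank_sums=rank_sums[top].tolist(), feature_indices=top,
    )


# ---------------------------------------------------------------------------
# Stage-1 orchestration
# ---------------------------------------------------------------------------

@dataclass
class Stage1Config:
    """Tunables of the signature-inference stage (defaults = study settings)."""

    n_bootstraps: int = 25
    in_bag_fraction: float = 0.90
    methods: tuple[str, ...] = ENSEMBLES["full"]
    size_grid: tuple[int, ...] = DEFAULT_SIZE_GRID
    seed: int = 0
    consensus_size: int | None = None  # None: median of the per-method optima
    svm_C: float = 1.0
    pam_delta: float = 0.0
    evaluate_performance: bool = True  # skip OOB curves/KI when a fixed size is given


@dataclass
class Stage1Result:
    consensus: ConsensusSignature
    curves: dict[str, SizePerformanceCurve]
    stability: dict[str, StabilityResult]
    plan: BootstrapPlan
    rankings: dict[str, list[scoring.FeatureRanking]]


def run_stage1(X, y, probeset_ids: list[str], config: Stage1Config | None = None,
               task: str = "", duration_days: int | None = None) -> Stage1Result:
    """Run the full Stage-1 pipeline on one training set.

    ``X`` is the groups x probesets fold-change matrix of the training
    profiles (raw; z-scoring happens per bootstrap), ``y`` the 0/1 task labels.
    """
    config = config or Stage1Config()
    if not config.methods:
        raise ValueError("empty selector ensemble")
    unknown = [m for m in config.methods if m not in scoring.METHODS]
    if unknown:
        raise ValueError(f"unknown selector(s) {unknown}")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    P = X.shape[1]
    sizes = [s for s in config.size_grid if 2 <= s <= min(100, P - 1)]
    if not sizes:
        raise ValueError("size grid has no entry within [2, min(100, P-1)]")

    plan = draw_bootstraps(y, config.n_bootstraps, config.in_bag_fraction, config.seed)
    ranker_kwargs = {"C": config.svm_C, "delta": config.pam_delta}
    rankings = {m: bootstrap_rankings(X, y, plan, m, **ranker_kwargs)
                for m in config.methods}

    curves: dict[str, SizePerformanceCurve] = {}
    stability: dict[str, StabilityResult] = {}
    optima = []
    if config.evaluate_performance:
        for m in config.methods:
            curve = evaluate_oob(X, y, plan, rankings[m], sizes, m)
            curve.optimum_size = spline_optimum(curve)
            curves[m] = curve
            if curve.optimum_size is not None:
                optima.append(curve.optimum_size)
            stability[m] = StabilityResult(
                method=m, sizes=sizes,
                per_size_KI=stability_by_size(rankings[m], sizes, P))

    if config.consensus_size is not None:
        size = int(config.consensus_size)
    elif optima:
        size = int(round(float(np.median(optima))))
    elif config.evaluate_performance:
        # every curve was undefined (tiny training set => one-class
        # out-of-bag sets); fall back to the middle of the size grid
        size = int(round(float(np.median(sizes))))
        logger.warning("no size optimum could be estimated; falling back to "
                       "the size-grid median %d", size)
    else:
        raise ValueError("consensus_size must be set when performance evaluation is off")
    size = max(2, min(size, P))

    all_rankings = [r for m in config.methods for r in rankings[m]]
    consensus = consensus_rank(
        all_rankings, size, probeset_ids, task=task, duration_days=duration_days,
        seed=config.seed, methods=tuple(config.methods), n_bootstraps=config.n_bootstraps)
    logger.info("stage 1 done: consensus signature of size %d from %d rankings",
                size, len(all_rankings))
    return Stage1Result(consensus=consensus, curves=curves, stability=stability,
                        plan=plan, rankings=rankings)


def write_signature(sig: ConsensusSignature, path) -> None:
    """Serialize as tab-delimited rank / probeset_id / rank_sum."""
    import pandas as pd

    pd.DataFrame({
        "rank": np.arange(1, sig.size + 1),
        "probeset_id": sig.probeset_ids,
        "rank_sum": sig.rank_sums if sig.rank_sums else [math.nan] * sig.size,
    }).to_csv(path, sep="\t", index=False)
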