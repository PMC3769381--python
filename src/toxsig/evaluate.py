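"""Nested cross-validation, AUC, signature comparison, and projections.

Evaluation follows a stratified nested 3x3 cross-validation: signatures are
inferred (or a fixed published signature applied) and hyperparameters tuned
strictly inside each outer training fold, and performance is measured on the
held-out outer fold in terms of rank-based AUC.  By default folds group all
treatment groups of one compound together, so no compound contributes to both
a training and a test fold through its other sex or dose group.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.decomposition import PCA

from . import classify
from .ensemble import ConsensusSignature, Stage1Config, run_stage1
from .expression import GroupProfile, profiles_to_matrix, task_labels, zscore_fit_apply

logger = logging.getLogger(__name__)


def auc(scores, labels) -> float:
    """Rank-based (Mann-Whitney) area under the ROC curve; ties count 1/2."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC undefined: both classes must be present")
    r = rankdata(scores)
    u = r[labels == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


# ---------------------------------------------------------------------------
# Fold construction
# ---------------------------------------------------------------------------

@dataclass
class CVPlan:
    """Outer/inner fold structure over treatment-group profiles."""

    outer_folds: int = 3
    inner_folds: int = 3
    grouping: str = "by_compound"  # or "by_group"
    seed: int = 0
    assignments: list[np.ndarray] = field(default_factory=list)  # outer test index sets

    def splits(self):
        n = sum(len(a) for a in self.assignments)
        for test_idx in self.assignments:
            train_idx = np.setdiff1d(np.arange(n), test_idx)
            yield train_idx, test_idx


def _grouped_stratified_folds(units: list, unit_labels: list[int], n_folds: int,
                              rng: np.random.Generator) -> dict:
    """Assign units (compounds or single groups) to folds, stratified by label."""
    fold_of: dict = {}
    for label in sorted(set(unit_labels)):
        members = [u for u, l in zip(units, unit_labels) if l == label]
        members = [members[i] for i in rng.permutation(len(members))]
        # start each class at a rotating fold so small classes spread out
        offset = rng.integers(n_folds)
        for i, u in enumerate(members):
            fold_of[u] = int((i + offset) % n_folds)
    return fold_of


def make_cv_plan(profiles: list[GroupProfile], y, outer_folds: int = 3,
                 inner_folds: int = 3, grouping: str = "by_compound",
                 seed: int = 0) -> CVPlan:
    """Build the outer fold partition (stratified; compound-grouped by default)."""
    y = np.asarray(y, dtype=int)
    rng = np.random.default_rng(seed)
    if grouping == "by_compound":
        compounds = sorted({p.compound for p in profiles})
        comp_label = {c: int(y[[i for i, p in enumerate(profiles)
                                if p.compound == c][0]]) for c in compounds}
        fold_of_comp = _grouped_stratified_folds(
            compounds, [comp_label[c] for c in compounds], outer_folds, rng)
        fold_of = np.array([fold_of_comp[p.compound] for p in profiles])
    elif grouping == "by_group":
        fold_of = np.empty(len(profiles), dtype=int)
        assign = _grouped_stratified_folds(
            list(range(len(profiles))), y.tolist(), outer_folds, rng)
        for i, f in assign.items():
            fold_of[i] = f
    else:
        raise ValueError(f"unknown grouping {grouping!r}")
    assignments = [np.flatnonzero(fold_of == f) for f in range(outer_folds)]
    for f, test_idx in enumerate(assignments):
        train_y = np.delete(y, test_idx)
        if np.unique(train_y).size < 2:
            raise ValueError(f"outer fold {f}: training set lost a class; "
                             "classes too small to stratify")
    return CVPlan(outer_folds=outer_folds, inner_folds=inner_folds,
                  grouping=grouping, seed=seed, assignments=assignments)


def _inner_folds(profiles_subset, y_subset, n_folds, grouping, seed):
    plan = make_cv_plan(profiles_subset, y_subset, outer_folds=n_folds,
                        inner_folds=n_folds, grouping=grouping, seed=seed)
    return list(plan.splits())


# ---------------------------------------------------------------------------
# Nested cross-validation
# ---------------------------------------------------------------------------

@dataclass
class EvaluationReport:
    task: str
    duration_days: int | None
    classifier: str
    signature_id: str
    per_fold_auc: list[float]
    mean_auc: float
    predictions: list[classify.PredictionResult]
    fold_signatures: list[ConsensusSignature] | None = None


def _tune_and_fit(kind: str, X_train, y_train, profiles_train, grouping: str,
                  inner_folds: int, seed: int, grids=None):
    """Inner grid search by mean inner-fold AUC; ties take the earlier point."""
    points = classify.grid_points(kind, X_train, y_train,
                                  None if grids is None else grids.get(kind))
    best_point, best_score = points[0], -np.inf
    if len(points) > 1:
        splits = _inner_folds(profiles_train, y_train, inner_folds, grouping, seed)
        for point in points:
            fold_aucs = []
            for tr, te in splits:
                if np.unique(y_train[tr]).size < 2 or np.unique(y_train[te]).size < 2:
                    continue
                Xtr, Xte = zscore_fit_apply(X_train[tr], X_train[te])
                model = classify.train(
                    classify.ClassifierSpec(kind=kind, hyperparameters=point, seed=seed),
                    Xtr, y_train[tr])
                fold_aucs.append(auc(model.predict_confidence(Xte), y_train[te]))
            score = float(np.mean(fold_aucs)) if fold_aucs else -np.inf
            if score > best_score:
                best_point, best_score = point, score
    Xtr_std, _ = zscore_fit_apply(X_train)
    spec = classify.ClassifierSpec(kind=kind, hyperparameters=best_point, seed=seed)
    return classify.train(spec, Xtr_std, y_train), best_point


def _signature_indices(signature, probeset_ids) -> np.ndarray:
    """Map a fixed signature (probeset IDs) onto matrix columns, dropping strays."""
    index = {p: i for i, p in enumerate(probeset_ids)}
    wanted = signature.probeset_ids if isinstance(signature, ConsensusSignature) else signature
    found = [index[p] for p in wanted if p in index]
    missing = len(wanted) - len(found)
    if not found:
        raise ValueError("no signature probeset is present in the dataset")
    if missing:
        logger.warning("%d of %d signature probesets absent from the dataset; "
                       "using the intersection", missing, len(wanted))
    return np.asarray(found, dtype=np.intp)


def nested_cv(profiles: list[GroupProfile], task: str, probeset_ids: list[str],
              classifiers=classify.KINDS, plan: CVPlan | None = None,
              signature_source: str = "stage1", fixed_signature=None,
              stage1_config: Stage1Config | None = None, grids=None,
              seed: int = 0, signature_id: str | None = None,
              duration_days: int | None = None) -> dict[str, EvaluationReport]:
    """Nested 3x3 cross-validated evaluation of one task.

    With ``signature_source='stage1'`` the full Stage-1 pipeline runs on every
    outer training fold (the held-out fold never influences the signature);
    with ``'fixed'`` the supplied probeset list is used in every fold.
    """
    selected, y = task_labels(profiles, task)
    X = profiles_to_matrix(selected)
    if min(np.bincount(y)) < 3:
        raise ValueError("need >= 3 profiles per class for 3-fold stratification")
    if plan is None:
        plan = make_cv_plan(selected, y, seed=seed)
    if signature_source not in ("stage1", "fixed"):
        raise ValueError("signature_source must be 'stage1' or 'fixed'")
    if signature_source == "fixed" and fixed_signature is None:
        raise ValueError("fixed_signature required when signature_source='fixed'")

    fold_signatures: list[ConsensusSignature | None] = []
    fold_features: list[np.ndarray] = []
    for f, (train_idx, _) in enumerate(plan.splits()):
        if signature_source == "stage1":
            cfg = stage1_config or Stage1Config()
            # fold-local seed derived only from the root seed and fold index,
            # so the signature depends on the training profiles alone
            fold_cfg = Stage1Config(**{**cfg.__dict__, "seed": stage1_seed(seed, f)})
            res = run_stage1(X[train_idx], y[train_idx], probeset_ids, fold_cfg,
                             task=task, duration_days=duration_days)
            fold_signatures.append(res.consensus)
            fold_features.append(res.consensus.feature_indices)
        else:
            fold_signatures.append(None)
            fold_features.append(_signature_indices(fixed_signature, probeset_ids))

    reports = {}
    sig_id = signature_id or (f"stage1[{task}]" if signature_source == "stage1" else "fixed")
    for kind in classifiers:
        per_fold, predictions = [], []
        for f, (train_idx, test_idx) in enumerate(plan.splits()):
            feats = fold_features[f]
            X_train, X_test = X[np.ix_(train_idx, feats)], X[np.ix_(test_idx, feats)]
            model, _ = _tune_and_fit(
                kind, X_train, y[train_idx], [selected[i] for i in train_idx],
                plan.grouping, plan.inner_folds, seed)
            _, X_test_std = zscore_fit_apply(X_train, X_test)
            conf = model.predict_confidence(X_test_std)
            predictions.extend(
                classify.PredictionResult(selected[i].group_id, kind, float(c))
                for i, c in zip(test_idx, conf))
            if np.unique(y[test_idx]).size == 2:
                per_fold.append(auc(conf, y[test_idx]))
            else:
                logger.warning("outer fold %d has one class only; AUC skipped", f)
        reports[kind] = EvaluationReport(
            task=task, duration_days=duration_days, classifier=kind,
            signature_id=sig_id, per_fold_auc=per_fold,
            mean_auc=float(np.mean(per_fold)) if per_fold else float("nan"),
            predictions=predictions,
            fold_signatures=fold_signatures if signature_source == "stage1" else None)
    return reports


def stage1_seed(root_seed: int, fold_index: int) -> int:
    """Deterministic per-fold Stage-1 seed (independent of fold membership)."""
    return int(np.random.SeedSequence([root_seed, 101 + fold_index])
               .generate_state(1)[0] % (2 ** 31))


def evaluate_fixed_signature(profiles, task, probeset_ids, signature,
                             classifiers=classify.KINDS, plan=None, seed: int = 0,
                             signature_id: str = "fixed",
                             duration_days: int | None = None):
    """Nested-CV evaluation of an externally supplied probeset list."""
    return nested_cv(profiles, task, probeset_ids, classifiers=classifiers,
                     plan=plan, signature_source="fixed", fixed_signature=signature,
                     seed=seed, signature_id=signature_id, duration_days=duration_days)


def signature_overlap(signatures: dict[str, list[str]]) -> pd.DataFrame:
    """Symmetric matrix of pairwise intersection counts (Venn counts)."""
    names = list(signatures)
    sets = {n: set(signatures[n]) for n in names}
    mat = pd.DataFrame(0, index=names, columns=names, dtype=int)
    for a in names:
        for b in names:
            mat.loc[a, b] = len(sets[a] & sets[b])
    return mat


# ---------------------------------------------------------------------------
# Undefined-compound classification
# ---------------------------------------------------------------------------

def classify_undefined(train_profiles: list[GroupProfile],
                       undef_profiles: list[GroupProfile], task: str,
                       probeset_ids: list[str], signature,
                       classifiers=classify.KINDS, seed: int = 0):
    """Score undefined-class treatment groups with models trained on the
    defined compounds only, then call each compound by majority vote.

    Returns ``(predictions, calls)`` where ``calls`` maps compound ->
    positive-class name, negative-class name, or "ambiguous".  Votes at
    confidence exactly 0.5 abstain.
    """
    from .expression import TASKS

    selected, y = task_labels(train_profiles, task)
    if any(p.class_label == "UNDEF" for p in selected):
        raise AssertionError("undefined profiles leaked into the training set")
    feats = _signature_indices(signature, probeset_ids)
    X_train = profiles_to_matrix(selected)[:, feats]
    X_new = profiles_to_matrix(undef_profiles)[:, feats]
    predictions: list[classify.PredictionResult] = []
    for kind in classifiers:
        model, _ = _tune_and_fit(kind, X_train, y, selected, "by_compound", 3, seed)
        _, X_new_std = zscore_fit_apply(X_train, X_new)
        conf = model.predict_confidence(X_new_std)
        predictions.extend(
            classify.PredictionResult(p.group_id, kind, float(c))
            for p, c in zip(undef_profiles, conf))
    pos_name = "+".join(TASKS[task][0])
    neg_name = "+".join(TASKS[task][1])
    group_compound = {p.group_id: p.compound for p in undef_profiles}
    calls = {}
    for compound in sorted({p.compound for p in undef_profiles}):
        votes = [r.confidence for r in predictions
                 if group_compound[r.group_id] == compound]
        n_pos = sum(v > 0.5 for v in votes)
        n_neg = sum(v < 0.5 for v in votes)
        if n_pos > n_neg:
            calls[compound] = pos_name
        elif n_neg > n_pos:
            calls[compound] = neg_name
        else:
            calls[compound] = "ambiguous"
    return predictions, calls


def pca_project_groups(profiles: list[GroupProfile], probeset_ids: list[str],
                       signature) -> pd.DataFrame:
    """Project group fold-change vectors, restricted to a signature, onto the
    top-2 principal components (column-centered), with metadata for plotting."""
    if len(profiles) < 3:
        raise ValueError("need >= 3 profiles for a 2-D projection")
    feats = _signature_indices(signature, probeset_ids)
    if feats.size < 2:
        raise ValueError("signature must contain >= 2 probesets present in the data")
    X = profiles_to_matrix(profiles)[:, feats]
    coords = PCA(n_components=2, svd_solver="full").fit_transform(X)
    return pd.DataFrame({
        "group_id": [p.group_id for p in profiles],
        "compound": [p.compound for p in profiles],
        "class": [p.class_label for p in profiles],
        "sex": [p.sex for p in profiles],
        "duration_days": [p.duration_days for p in profiles],
        "pc1": coords[:, 0],
        "pc2": coords[:, 1],
    })


def predictions_table(reports: dict[str, EvaluationReport],
                      truth: dict[str, str] | None = None) -> pd.DataFrame:
    """Flatten per-classifier predictions into one tab-friendly table."""
    rows = []
    for kind, rep in reports.items():
        for pr in rep.predictions:
            rows.append({
                "group_id": pr.group_id, "classifier": kind,
                "confidence": pr.confidence,
                "predicted_positive": pr.predicted_positive,
                "truth": truth.get(pr.group_id, "") if truth else "",
            })
    return pd.DataFrame(rows)
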