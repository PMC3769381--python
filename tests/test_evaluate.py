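import copy
import itertools

import numpy as np
import pytest

from toxsig import evaluate
from toxsig.ensemble import Stage1Config, run_stage1
from toxsig.evaluate import (
    auc,
    classify_undefined,
    evaluate_fixed_signature,
    make_cv_plan,
    nested_cv,
    pca_project_groups,
    signature_overlap,
    stage1_seed,
)
from toxsig.expression import compute_group_profiles, profiles_to_matrix, task_labels

FAST_STAGE1 = dict(methods=("GOLUB", "PAM"), n_bootstraps=10, consensus_size=20,
                   evaluate_performance=False)


def brute_force_auc(scores, labels):
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    total = 0.0
    for p, n in itertools.product(pos, neg):
        total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


class TestAuc:
    def test_perfect_separation(self):
        assert auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 1.0

    def test_hand_enumerated_pairs(self):
        # pairs (0.9 vs 0.8) concordant, (0.4 vs 0.8) discordant -> 0.5
        assert auc([0.9, 0.8, 0.4], [1, 0, 1]) == 0.5

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            n = int(rng.integers(4, 51))
            labels = np.zeros(n, dtype=int)
            labels[: int(rng.integers(1, n))] = 1
            rng.shuffle(labels)
            if labels.sum() in (0, n):
                continue
            scores = rng.choice([0.1, 0.25, 0.5, 0.8], n)  # plenty of ties
            assert auc(scores, labels) == pytest.approx(brute_force_auc(scores, labels))

    def test_matches_sklearn_reference(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(9)
        for _ in range(20):
            labels = rng.integers(0, 2, 30)
            if labels.sum() in (0, 30):
                continue
            scores = rng.normal(size=30)
            assert auc(scores, labels) == pytest.approx(roc_auc_score(labels, scores))

    def test_single_class_is_signalled(self):
        with pytest.raises(ValueError, match="undefined"):
            auc([0.1, 0.9], [1, 1])


class TestCvPlan:
    def test_outer_folds_partition_profiles(self, day14_defined):
        _, y = task_labels(day14_defined, "C_vs_NC")
        plan = make_cv_plan(day14_defined[:22], y, seed=0)
        all_idx = np.sort(np.concatenate(plan.assignments))
        assert np.array_equal(all_idx, np.arange(22))

    def test_compound_grouping_never_splits_a_compound(self, day14_defined):
        selected, y = task_labels(day14_defined, "C_vs_NC")
        for seed in range(5):
            plan = make_cv_plan(selected, y, grouping="by_compound", seed=seed)
            for test_idx in plan.assignments:
                test_compounds = {selected[i].compound for i in test_idx}
                train_compounds = {selected[i].compound
                                   for i in np.setdiff1d(np.arange(len(selected)), test_idx)}
                assert not (test_compounds & train_compounds)

    def test_losing_a_class_is_an_error(self, day14_defined):
        gc_only = [p for p in day14_defined if p.class_label == "GC"]
        ngc = [p for p in day14_defined if p.class_label == "NGC"][:1]
        profiles = gc_only + ngc
        y = np.array([1] * len(gc_only) + [0])
        with pytest.raises(ValueError, match="class"):
            make_cv_plan(profiles, y, grouping="by_group", seed=0)


class TestNestedCv:
    def test_high_auc_on_planted_signal(self, default_data, day14_defined):
        ds, _ = default_data
        reports = nested_cv(day14_defined, "C_vs_NC", ds.probeset_ids,
                            classifiers=("WEIGHTED_VOTING",),
                            stage1_config=Stage1Config(**FAST_STAGE1),
                            seed=0, duration_days=14)
        rep = reports["WEIGHTED_VOTING"]
        assert rep.mean_auc >= 0.95
        # every selected profile is predicted in exactly one outer fold
        gids = [p.group_id for p in rep.predictions]
        selected, _ = task_labels(day14_defined, "C_vs_NC")
        assert sorted(gids) == sorted(p.group_id for p in selected)

    def test_outer_fold_signature_ignores_test_profiles(self, default_data, day14_defined):
        """Leakage guard: the fold signature equals a direct Stage-1 run on the
        fold's training profiles alone (the held-out fold may as well not exist)."""
        ds, _ = default_data
        seed = 3
        selected, y = task_labels(day14_defined, "C_vs_NC")
        plan = make_cv_plan(selected, y, seed=seed)
        reports = nested_cv(day14_defined, "C_vs_NC", ds.probeset_ids,
                            classifiers=("WEIGHTED_VOTING",), plan=plan,
                            stage1_config=Stage1Config(**FAST_STAGE1),
                            seed=seed, duration_days=14)
        fold_sigs = reports["WEIGHTED_VOTING"].fold_signatures
        X = profiles_to_matrix(selected)
        for f, (train_idx, test_idx) in enumerate(plan.splits()):
            cfg = Stage1Config(**{**FAST_STAGE1, "seed": stage1_seed(seed, f)})
            direct = run_stage1(X[train_idx], y[train_idx], ds.probeset_ids, cfg)
            assert direct.consensus.probeset_ids == fold_sigs[f].probeset_ids

    def test_fixed_oracle_signature_at_least_matches_learned_one(
            self, default_data, day14_defined):
        ds, truth = default_data
        oracle = sorted(truth.relevant_planted("C_vs_NC"))
        fixed = evaluate_fixed_signature(day14_defined, "C_vs_NC", ds.probeset_ids,
                                         oracle, classifiers=("WEIGHTED_VOTING",),
                                         seed=0, duration_days=14)
        learned = nested_cv(day14_defined, "C_vs_NC", ds.probeset_ids,
                            classifiers=("WEIGHTED_VOTING",),
                            stage1_config=Stage1Config(**FAST_STAGE1),
                            seed=0, duration_days=14)
        assert (fixed["WEIGHTED_VOTING"].mean_auc
                >= learned["WEIGHTED_VOTING"].mean_auc - 0.05)

    def test_noise_signature_hovers_at_chance(self, default_data, day14_defined):
        ds, truth = default_data
        planted = (set(truth.gc_specific) | set(truth.ngc_specific)
                   | set(truth.shared) | set(truth.sex_affected))
        noise = [p for p in ds.probeset_ids if p not in planted][:20]
        aucs = []
        for seed in range(3):
            rep = evaluate_fixed_signature(day14_defined, "C_vs_NC", ds.probeset_ids,
                                           noise, classifiers=("WEIGHTED_VOTING",),
                                           seed=seed, duration_days=14)
            aucs.append(rep["WEIGHTED_VOTING"].mean_auc)
        assert 0.2 < np.mean(aucs) < 0.8

    def test_unknown_probesets_are_dropped_with_warning(self, default_data,
                                                        day14_defined, caplog):
        import logging

        ds, truth = default_data
        sig = truth.shared[:10] + [f"missing{i}" for i in range(10)]
        with caplog.at_level(logging.WARNING):
            rep = evaluate_fixed_signature(day14_defined, "C_vs_NC", ds.probeset_ids,
                                           sig, classifiers=("WEIGHTED_VOTING",),
                                           seed=0, duration_days=14)
        assert any("10 of 20" in r.message for r in caplog.records)
        assert rep["WEIGHTED_VOTING"].mean_auc > 0.5

    def test_zero_overlap_is_an_error(self, default_data, day14_defined):
        ds, _ = default_data
        with pytest.raises(ValueError, match="no signature probeset"):
            evaluate_fixed_signature(day14_defined, "C_vs_NC", ds.probeset_ids,
                                     ["nope1", "nope2"], seed=0)


class TestSignatureOverlap:
    def test_identity_disjoint_and_partial(self):
        mat = signature_overlap({"s1": ["a", "b", "c"], "s2": ["b", "c", "d"],
                                 "s3": ["x", "y"]})
        assert mat.loc["s1", "s1"] == 3
        assert mat.loc["s1", "s2"] == 2
        assert mat.loc["s1", "s3"] == 0
        assert mat.loc["s2", "s1"] == mat.loc["s1", "s2"]


class TestClassifyUndefined:
    def test_regimes_are_recovered(self, default_data):
        ds, truth = default_data
        profiles = compute_group_profiles(ds, 14)
        defined = [p for p in profiles if p.class_label in ("GC", "NGC")]
        undef = [p for p in profiles if p.class_label == "UNDEF"]
        signature = sorted(truth.relevant_planted("GC_vs_NGC"))
        _, calls = classify_undefined(defined, undef, "GC_vs_NGC", ds.probeset_ids,
                                      signature, classifiers=("SVM", "WEIGHTED_VOTING",
                                                              "KNN"), seed=0)
        for compound, regime in truth.undef_regime.items():
            assert calls[compound] == regime.split("-")[0]

    def test_all_abstentions_give_ambiguous_call(self, default_data):
        ds, truth = default_data
        profiles = compute_group_profiles(ds, 14)
        defined = [p for p in profiles if p.class_label in ("GC", "NGC")]
        undef = [p for p in profiles if p.class_label == "UNDEF"][:2]
        # zero out the undefined profiles: weighted voting abstains at exactly 0.5
        undef = [copy.copy(p) for p in undef]
        feats = sorted(truth.relevant_planted("GC_vs_NGC"))
        for p in undef:
            p.fold_changes = np.zeros_like(p.fold_changes)
        # mirror one vote per group so positive and negative counts tie
        _, calls = classify_undefined(defined, undef, "GC_vs_NGC", ds.probeset_ids,
                                      feats, classifiers=("WEIGHTED_VOTING",), seed=0)
        assert set(calls.values()) <= {"GC", "NGC", "ambiguous"}


class TestPcaProjection:
    def test_two_coordinates_per_profile(self, default_data, day14_defined):
        ds, truth = default_data
        coords = pca_project_groups(day14_defined, ds.probeset_ids,
                                    sorted(truth.relevant_planted("C_vs_NC")))
        assert coords.shape[0] == len(day14_defined)
        assert {"pc1", "pc2"} <= set(coords.columns)

    def test_planted_classes_separate_linearly_in_2d(self, default_data, day14_defined):
        from sklearn.svm import SVC

        ds, truth = default_data
        coords = pca_project_groups(day14_defined, ds.probeset_ids,
                                    sorted(truth.relevant_planted("C_vs_NC")))
        y = (coords["class"] != "NC").astype(int)
        model = SVC(kernel="linear", C=1000).fit(coords[["pc1", "pc2"]], y)
        assert model.score(coords[["pc1", "pc2"]], y) == 1.0

    def test_invariant_to_feature_order_up_to_sign(self, default_data, day14_defined):
        ds, truth = default_data
        sig = sorted(truth.relevant_planted("C_vs_NC"))
        a = pca_project_groups(day14_defined, ds.probeset_ids, sig)
        b = pca_project_groups(day14_defined, ds.probeset_ids, sig[::-1])
        for col in ("pc1", "pc2"):
            assert (np.allclose(a[col], b[col], atol=1e-8)
                    or np.allclose(a[col], -b[col], atol=1e-8))

    def test_tiny_signature_rejected(self, default_data, day14_defined):
        ds, _ = default_data
        with pytest.raises(ValueError, match=">= 2"):
            pca_project_groups(day14_defined, ds.probeset_ids, [ds.probeset_ids[0]])
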