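"""Fold-plan integrity, the F1 metric against an independent oracle, the
epoch-selection protocol, and the end-to-end task runner."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import f1_score as sk_f1

from ramancnn.cv import (
    FoldPlan,
    TrainConfig,
    confusion_counts,
    f1_score,
    make_fold_plan,
    run_task,
    train_with_epoch_selection,
)
from ramancnn.dataset import ConfigError
from ramancnn.nn import AnnSpec, ModelSpec, build_ann
from ramancnn.simulate import CohortConfig, PeakSpec, generate_cohort


def _check_plan_integrity(plan: FoldPlan, patients_by_class: dict[int, set]):
    all_patients = set().union(*patients_by_class.values())
    test_cover = []
    for fold in plan.folds:
        tr = set(fold["train_patients"])
        va = set(fold["val_patients"])
        te = set(fold["test_patients"])
        assert tr & va == set() and tr & te == set() and va & te == set()
        assert tr | va | te == all_patients
        test_cover.extend(te)
    # every patient in exactly one test fold
    assert sorted(test_cover) == sorted(all_patients)
    # stratification: per-class test counts within +/-1 of n_class / k
    for cls, members in patients_by_class.items():
        per_fold = [len(set(f["test_patients"]) & members) for f in plan.folds]
        ideal = len(members) / plan.k
        assert all(abs(n - ideal) <= 1 for n in per_fold)


class TestFoldPlan:
    def test_twelve_patients_six_folds_forced_split(self, small_cohort):
        plan = make_fold_plan(small_cohort, "disease_superficial", k=6, seed=0)
        for fold in plan.folds:
            assert len(fold["test_patients"]) == 2
            conditions = {p[:1] for p in fold["test_patients"]}
            assert conditions == {"O", "H"}  # one OA + one control each

    def test_study_cohort_plan_integrity(self):
        cfg = CohortConfig(spectra_per_patient=(1, 1), n_points=11,
                           peaks=(PeakSpec(1000.0, 30.0, 1.0),),
                           noise_sd=0.0, baseline_scale=0.0,
                           cosmic_ray_rate=0.0, seed=0)
        ds = generate_cohort(cfg)  # 45 + 19 patients
        plan = make_fold_plan(ds, "disease_superficial", k=6, seed=4)
        by_class = {
            1: {p for p in ds.patients() if p.startswith("OA")},
            0: {p for p in ds.patients() if p.startswith("H")},
        }
        _check_plan_integrity(plan, by_class)

    def test_plan_deterministic_and_seed_sensitive(self, small_cohort):
        a = make_fold_plan(small_cohort, "disease_superficial", seed=1)
        b = make_fold_plan(small_cohort, "disease_superficial", seed=1)
        c = make_fold_plan(small_cohort, "disease_superficial", seed=2)
        assert a.to_json() == b.to_json()
        assert a.to_json() != c.to_json()

    def test_json_round_trip(self, small_cohort):
        plan = make_fold_plan(small_cohort, "disease_superficial", seed=3)
        back = FoldPlan.from_json(plan.to_json())
        assert back.folds == plan.folds

    def test_too_few_patients_in_class_rejected(self, small_cohort):
        with pytest.raises(ConfigError, match="fewer than"):
            make_fold_plan(small_cohort, "disease_superficial", k=8)


class TestF1Score:
    def test_hand_computed_case(self):
        # TP=3, FP=1, FN=2 -> precision 0.75, recall 0.6, F1 = 2/3
        truth = [1, 1, 1, 1, 1, 0, 0, 0]
        pred = [1, 1, 1, 0, 0, 1, 0, 0]
        assert f1_score(pred, truth) == pytest.approx(2 / 3)

    def test_perfect_and_degenerate(self):
        assert f1_score([1, 0, 1], [1, 0, 1]) == 1.0
        assert f1_score([0, 0, 0], [1, 0, 1]) == 0.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            f1_score([1, 0], [1])

    @settings(max_examples=200, deadline=None)
    @given(st.lists(st.tuples(st.integers(0, 1), st.integers(0, 1)),
                    min_size=1, max_size=60))
    def test_matches_sklearn_oracle(self, pairs):
        pred, truth = zip(*pairs)
        ours = f1_score(list(pred), list(truth))
        ref = sk_f1(list(truth), list(pred), pos_label=1, zero_division=0)
        assert ours == pytest.approx(ref)

    def test_confusion_counts_sum(self):
        rng = np.random.default_rng(0)
        pred, truth = rng.integers(0, 2, 30), rng.integers(0, 2, 30)
        c = confusion_counts(pred, truth)
        assert c["tp"] + c["fp"] + c["fn"] + c["tn"] == 30


class TestEpochSelection:
    @staticmethod
    def _separable_toy(n=120, seed=0):
        rng = np.random.default_rng(seed)
        y = rng.integers(0, 2, n)
        x = rng.normal(0, 0.3, (n, 2)) + np.stack([y * 2.0 - 1.0, 1.0 - 2.0 * y], axis=1)
        return x, y

    def test_separable_task_reaches_perfect_validation(self):
        x, y = self._separable_toy()
        xv, yv = self._separable_toy(40, seed=1)
        cfg = TrainConfig(epochs=60, learning_rate=1e-2, batch_size=8, seed=0)
        model, hist = train_with_epoch_selection(
            lambda s: build_ann(AnnSpec(dropout_rate=0.0), 2, seed=s),
            (x, y, xv, yv), cfg,
        )
        assert max(hist["phase1_val_f1"]) == 1.0
        assert 1 <= hist["best_epoch"] <= 60

    def test_best_epoch_is_earliest_argmax(self):
        x, y = self._separable_toy()
        xv, yv = self._separable_toy(40, seed=1)
        cfg = TrainConfig(epochs=30, learning_rate=1e-2, batch_size=8, seed=0)
        _, hist = train_with_epoch_selection(
            lambda s: build_ann(AnnSpec(dropout_rate=0.0), 2, seed=s),
            (x, y, xv, yv), cfg,
        )
        curve = np.asarray(hist["phase1_val_f1"])
        assert hist["best_epoch"] == int(np.argmax(curve)) + 1

    def test_histories_reproducible_for_seed(self):
        x, y = self._separable_toy()
        xv, yv = self._separable_toy(40, seed=1)
        cfg = TrainConfig(epochs=10, learning_rate=1e-2, batch_size=8, seed=5)
        runs = [
            train_with_epoch_selection(
                lambda s: build_ann(AnnSpec(), 2, seed=s), (x, y, xv, yv), cfg
            )[1]
            for _ in range(2)
        ]
        assert runs[0] == runs[1]

    def test_early_stop_on_perfect_selects_same_epoch(self):
        x, y = self._separable_toy()
        xv, yv = self._separable_toy(40, seed=1)
        cfg = TrainConfig(epochs=40, learning_rate=1e-2, batch_size=8, seed=2)
        _, full = train_with_epoch_selection(
            lambda s: build_ann(AnnSpec(dropout_rate=0.0), 2, seed=s),
            (x, y, xv, yv), cfg,
        )
        _, quick = train_with_epoch_selection(
            lambda s: build_ann(AnnSpec(dropout_rate=0.0), 2, seed=s),
            (x, y, xv, yv), cfg, stop_when_perfect=True,
        )
        assert full["best_epoch"] == quick["best_epoch"]
        assert len(quick["phase1_val_f1"]) <= len(full["phase1_val_f1"])

    def test_empty_training_fold_rejected(self):
        cfg = TrainConfig(epochs=2)
        with pytest.raises(ValueError, match="empty"):
            train_with_epoch_selection(
                lambda s: build_ann(AnnSpec(), 2, seed=s),
                (np.empty((0, 2)), np.empty(0, dtype=int), np.empty((0, 2)),
                 np.empty(0, dtype=int)),
                cfg,
            )


class TestRunTask:
    def test_structure_and_leakage_guards(self, small_cohort):
        cfg = TrainConfig(epochs=2, batch_size=8, seed=0)
        spec = ModelSpec(n_blocks=2, hidden_filters=4, kernel_size=3)
        report, artifacts = run_task(
            small_cohort, "disease_superficial", "raw", cfg,
            model_spec=spec, return_artifacts=True,
        )
        assert len(report.per_fold_f1) == 6
        assert report.mean_f1 == pytest.approx(np.mean(report.per_fold_f1))
        assert report.sd_f1 == pytest.approx(np.std(report.per_fold_f1))
        assert len(report.per_fold_macro_f1) == 6
        assert report.mean_macro_f1 == pytest.approx(np.mean(report.per_fold_macro_f1))
        sub, _ = small_cohort.for_task("disease_superficial")
        n_total = len(sub)
        for art in artifacts:
            # standardizer fitted on strictly fewer spectra than exist
            assert art.stats.n_fitted < n_total
            assert art.stats.n_fitted + len(art.y_test) < n_total  # val held out too

    def test_deterministic_reports(self, small_cohort):
        cfg = TrainConfig(epochs=2, batch_size=8, seed=3)
        spec = ModelSpec(n_blocks=2, hidden_filters=4, kernel_size=3)
        a = run_task(small_cohort, "disease_superficial", "raw", cfg, model_spec=spec)
        b = run_task(small_cohort, "disease_superficial", "raw", cfg, model_spec=spec)
        assert a.to_json() == b.to_json()

    def test_unknown_method_rejected(self, small_cohort):
        with pytest.raises(ConfigError):
            run_task(small_cohort, "disease_superficial", "bogus", TrainConfig())
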