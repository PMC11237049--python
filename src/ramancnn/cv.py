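"""Patient-grouped stratified cross-validation and the training protocol.

Folds are built over patients, never spectra, so no donor contributes to
more than one of train/validation/test within a fold — the grouping that
prevents identity leakage in small clinical cohorts.  Training follows a
two-phase epoch-selection protocol: train for the full epoch budget while
monitoring validation F1, pick the best epoch (earliest on ties), then
retrain from scratch on train+validation for exactly that many epochs and
evaluate once on the held-out test patients.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from typing import Callable, Sequence

import numpy as np

from .dataset import ConfigError, SpectralDataset, patient_labels
from .nn import Adam, ModelSpec, build_resnet, softmax_cross_entropy
from .preprocess import (
    DEFAULT_CHANNEL_METHODS,
    StandardizationStats,
    fit_standardizer,
    manual_pipeline,
    stack_dataset,
    standardize,
)

logger = logging.getLogger(__name__)

METHODS = ("raw", "preprocessed", "multichannel")


# ---------------------------------------------------------------------------
# fold plan
# ---------------------------------------------------------------------------

@dataclass
class FoldPlan:
    """k patient-grouped, class-stratified train/val/test partitions."""

    folds: list[dict]  # {"train_patients", "val_patients", "test_patients"}
    task: str
    seed: int
    k: int

    def to_json(self) -> str:
        return json.dumps(
            {"task": self.task, "seed": self.seed, "k": self.k, "folds": self.folds},
            indent=2,
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "FoldPlan":
        d = json.loads(text)
        return cls(folds=d["folds"], task=d["task"], seed=d["seed"], k=d["k"])


def make_fold_plan(
    dataset: SpectralDataset,
    task: str,
    k: int = 6,
    seed: int = 0,
    val_fraction: float = 0.2,
) -> FoldPlan:
    """Partition patients into k stratified test groups; within each fold the
    remaining patients are split 80/20 into train/validation, also by patient
    and per class.  Deterministic for a given seed."""
    labels = patient_labels(dataset, task)
    rng = np.random.default_rng(seed)
    by_class: dict[int, list[str]] = {0: [], 1: []}
    for pid in sorted(labels):
        by_class[labels[pid]].append(pid)
    for cls, pids in by_class.items():
        if len(pids) < k:
            raise ConfigError(
                f"class {cls} has {len(pids)} patients, fewer than k={k} folds"
            )
    test_groups: list[list[str]] = [[] for _ in range(k)]
    for cls in (0, 1):
        pids = np.array(by_class[cls])
        rng.shuffle(pids)
        for fold_idx, chunk in enumerate(np.array_split(pids, k)):
            test_groups[fold_idx].extend(chunk.tolist())
    folds = []
    for fold_idx in range(k):
        test = set(test_groups[fold_idx])
        train: list[str] = []
        val: list[str] = []
        for cls in (0, 1):
            rest = np.array([p for p in by_class[cls] if p not in test])
            rng.shuffle(rest)
            n = rest.size
            n_val = int(round(val_fraction * n))
            n_val = min(max(n_val, 1), n - 1) if n >= 2 else 0
            val.extend(rest[:n_val].tolist())
            train.extend(rest[n_val:].tolist())
        folds.append(
            {
                "train_patients": sorted(train),
                "val_patients": sorted(val),
                "test_patients": sorted(test),
            }
        )
    return FoldPlan(folds=folds, task=task, seed=seed, k=k)


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def f1_score(predictions: Sequence[int], truths: Sequence[int], positive_class: int = 1) -> float:
    """Binary F1 = 2PR/(P+R); 0 when precision + recall = 0."""
    pred = np.asarray(predictions)
    true = np.asarray(truths)
    if pred.shape != true.shape or pred.size == 0:
        raise ValueError("predictions and truths must be equal-length and non-empty")
    tp = int(np.sum((pred == positive_class) & (true == positive_class)))
    fp = int(np.sum((pred == positive_class) & (true != positive_class)))
    fn = int(np.sum((pred != positive_class) & (true == positive_class)))
    denom = 2 * tp + fp + fn
    return 2 * tp / denom if denom else 0.0


def confusion_counts(predictions, truths, positive_class: int = 1) -> dict[str, int]:
    pred = np.asarray(predictions)
    true = np.asarray(truths)
    return {
        "tp": int(np.sum((pred == positive_class) & (true == positive_class))),
        "fp": int(np.sum((pred == positive_class) & (true != positive_class))),
        "fn": int(np.sum((pred != positive_class) & (true == positive_class))),
        "tn": int(np.sum((pred != positive_class) & (true != positive_class))),
    }


def permutation_f1_band(
    truths: np.ndarray,
    predictions: np.ndarray,
    n_permutations: int = 2000,
    seed: int = 0,
    alpha: float = 0.01,
) -> tuple[float, float]:
    """Two-sided (1-alpha) band of F1 under random label/prediction pairing.

    Shuffling the predictions against the truths simulates a classifier with
    the observed marginal prediction rate but no real association.
    """
    rng = np.random.default_rng(seed)
    pred = np.asarray(predictions).copy()
    null = np.empty(n_permutations)
    for i in range(n_permutations):
        rng.shuffle(pred)
        null[i] = f1_score(pred, truths)
    lo, hi = np.quantile(null, [alpha / 2, 1 - alpha / 2])
    return float(lo), float(hi)


# ---------------------------------------------------------------------------
# training protocol
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TrainConfig:
    """Optimisation settings; defaults are the study protocol."""

    epochs: int = 100
    learning_rate: float = 1e-4
    betas: tuple[float, float] = (0.5, 0.999)
    batch_size: int = 4
    val_batch_size: int = 1
    test_batch_size: int = 1
    seed: int = 0

    def validate(self) -> None:
        if self.epochs < 1:
            raise ConfigError("epochs must be >= 1")
        if self.learning_rate <= 0:
            raise ConfigError("learning rate must be positive")
        if min(self.batch_size, self.val_batch_size, self.test_batch_size) < 1:
            raise ConfigError("batch sizes must be >= 1")


def _train_epochs(model, x, y, config: TrainConfig, n_epochs: int,
                  shuffle_rng: np.random.Generator,
                  x_val=None, y_val=None, stop_at_val_f1: float | None = None) -> dict:
    opt = Adam(model.params(), lr=config.learning_rate, betas=config.betas)
    losses: list[float] = []
    val_f1: list[float] = []
    n = len(y)
    for _ in range(n_epochs):
        order = shuffle_rng.permutation(n)
        total, batches = 0.0, 0
        for i in range(0, n, config.batch_size):
            b = order[i : i + config.batch_size]
            logits = model.forward(x[b], train=True)
            loss, dlogits = softmax_cross_entropy(logits, y[b])
            opt.zero_grad()
            model.backward(dlogits)
            opt.step()
            total += loss
            batches += 1
        losses.append(total / max(batches, 1))
        if x_val is not None and len(y_val):
            preds = model.predict(x_val, batch_size=max(config.val_batch_size, 64))
            val_f1.append(f1_score(preds, y_val))
            if stop_at_val_f1 is not None and val_f1[-1] >= stop_at_val_f1:
                break
    return {"loss": losses, "val_f1": val_f1}


def train_with_epoch_selection(
    model_factory: Callable[[int], object],
    fold_data: tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray],
    config: TrainConfig,
    stop_when_perfect: bool = False,
) -> tuple[object, dict]:
    """Two-phase protocol: epoch selection on validation F1, then retrain on
    train+validation for the selected number of epochs.

    ``model_factory(seed)`` must return a fresh model; it is called with the
    same derived seed in both phases so the retrained model starts from the
    identical initialisation.

    ``stop_when_perfect`` ends phase 1 as soon as validation F1 reaches 1.0;
    since no later epoch can exceed a perfect score and ties resolve to the
    earliest epoch, the selected epoch — and hence the returned model — is
    identical to the full-budget run.
    """
    config.validate()
    x_tr, y_tr, x_val, y_val = fold_data
    if len(y_tr) == 0:
        raise ValueError("empty training fold")
    ss = np.random.SeedSequence(config.seed)
    init_seed, shuf1, shuf2 = (int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(3))
    model = model_factory(init_seed)
    phase1 = _train_epochs(model, x_tr, y_tr, config, config.epochs,
                           np.random.default_rng(shuf1), x_val, y_val,
                           stop_at_val_f1=1.0 if stop_when_perfect else None)
    val_curve = np.asarray(phase1["val_f1"])
    best_epoch = int(np.argmax(val_curve)) + 1  # earliest argmax, 1-based
    x_full = np.concatenate([x_tr, x_val])
    y_full = np.concatenate([y_tr, y_val])
    model2 = model_factory(init_seed)
    phase2 = _train_epochs(model2, x_full, y_full, config, best_epoch,
                           np.random.default_rng(shuf2))
    history = {
        "phase1_loss": phase1["loss"],
        "phase1_val_f1": phase1["val_f1"],
        "best_epoch": best_epoch,
        "phase2_loss": phase2["loss"],
    }
    return model2, history


# ---------------------------------------------------------------------------
# full task runner
# ---------------------------------------------------------------------------

@dataclass
class EvalReport:
    """Per-fold and aggregate F1 for one task/method combination.

    ``per_fold_f1`` is the binary F1 of the positive class; macro-averaged
    F1 over both classes is emitted alongside.
    """

    task: str
    method: str
    per_fold_f1: list[float]
    mean_f1: float
    sd_f1: float
    confusions: list[dict]
    best_epochs: list[int] = field(default_factory=list)
    per_fold_macro_f1: list[float] = field(default_factory=list)
    mean_macro_f1: float = float("nan")

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)


@dataclass
class FoldArtifacts:
    """Trained model and fold data needed for post-hoc attribution."""

    model: object
    stats: StandardizationStats
    x_test: np.ndarray  # standardised (N, C, W)
    y_test: np.ndarray
    y_pred: np.ndarray
    history: dict


def task_representation(
    subset: SpectralDataset,
    method: str,
    channel_methods: Sequence[str] = DEFAULT_CHANNEL_METHODS,
) -> np.ndarray:
    """(N, C, W) input stack for a task subset under a given representation."""
    if method == "raw":
        return subset.intensity_matrix()[:, None, :]
    if method == "preprocessed":
        return np.stack([manual_pipeline(s).intensities for s in subset])[:, None, :]
    if method == "multichannel":
        return stack_dataset(subset, channel_methods)
    raise ConfigError(f"unknown method {method!r}; expected one of {METHODS}")


def run_task(
    dataset: SpectralDataset,
    task: str,
    method: str,
    config: TrainConfig,
    model_spec: ModelSpec | None = None,
    fold_plan: FoldPlan | None = None,
    k: int = 6,
    channel_methods: Sequence[str] = DEFAULT_CHANNEL_METHODS,
    return_artifacts: bool = False,
    stop_when_perfect: bool = False,
) -> EvalReport | tuple[EvalReport, list[FoldArtifacts]]:
    """Run the full grouped-CV protocol for one task and representation."""
    config.validate()
    subset, y = dataset.for_task(task)
    if len(subset) == 0:
        raise ConfigError(f"dataset has no spectra for task {task!r}")
    x = task_representation(subset, method, channel_methods)
    n, c, w = x.shape
    if model_spec is None:
        model_spec = ModelSpec(in_channels=c, input_length=w)
    elif model_spec.in_channels != c or model_spec.input_length != w:
        from dataclasses import replace as _replace
        model_spec = _replace(model_spec, in_channels=c, input_length=w)
    model_spec.validate()
    if fold_plan is None:
        fold_plan = make_fold_plan(dataset, task, k=k, seed=config.seed)
    pids = np.array([s.patient_id for s in subset])
    per_fold_f1: list[float] = []
    per_fold_macro: list[float] = []
    confusions: list[dict] = []
    best_epochs: list[int] = []
    artifacts: list[FoldArtifacts] = []
    ss = np.random.SeedSequence(config.seed)
    fold_seeds = [int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(len(fold_plan.folds))]
    for fold_idx, fold in enumerate(fold_plan.folds):
        tr = np.isin(pids, fold["train_patients"])
        va = np.isin(pids, fold["val_patients"])
        te = np.isin(pids, fold["test_patients"])
        stats = fit_standardizer(x[tr])
        assert stats.n_fitted == int(tr.sum())  # no test/val leakage into stats
        x_std = standardize(x, stats)
        from dataclasses import replace as _replace
        fold_config = _replace(config, seed=fold_seeds[fold_idx])
        factory = lambda seed: build_resnet(model_spec, seed=seed)  # noqa: E731
        model, history = train_with_epoch_selection(
            factory, (x_std[tr], y[tr], x_std[va], y[va]), fold_config,
            stop_when_perfect=stop_when_perfect,
        )
        y_pred = model.predict(x_std[te], batch_size=max(config.test_batch_size, 64))
        fold_f1 = f1_score(y_pred, y[te])
        per_fold_f1.append(fold_f1)
        per_fold_macro.append(
            (fold_f1 + f1_score(y_pred, y[te], positive_class=0)) / 2.0
        )
        confusions.append(confusion_counts(y_pred, y[te]))
        best_epochs.append(history["best_epoch"])
        logger.info("%s/%s fold %d: F1=%.4f (best epoch %d)",
                    task, method, fold_idx, fold_f1, history["best_epoch"])
        if return_artifacts:
            artifacts.append(
                FoldArtifacts(model=model, stats=stats, x_test=x_std[te],
                              y_test=y[te], y_pred=np.asarray(y_pred), history=history)
            )
    report = EvalReport(
        task=task,
        method=method,
        per_fold_f1=per_fold_f1,
        mean_f1=float(np.mean(per_fold_f1)),
        sd_f1=float(np.std(per_fold_f1)),
        confusions=confusions,
        best_epochs=best_epochs,
        per_fold_macro_f1=per_fold_macro,
        mean_macro_f1=float(np.mean(per_fold_macro)),
    )
    return (report, artifacts) if return_artifacts else report
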