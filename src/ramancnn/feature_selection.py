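"""Reduced-feature classification on importance-ranked wavenumber subsets.

Given a cross-fold feature ranking, progressively smaller wavenumber subsets
are fed to three classical classifiers — the small dense ANN (with the same
100-epoch / validation epoch-selection protocol as the CNN), a decision tree
and an RBF support vector machine (scikit-learn defaults, frozen here:
SVC(C=1, kernel='rbf', gamma='scale'); DecisionTreeClassifier with Gini and
unlimited depth) — under the identical patient-grouped 6-fold protocol,
producing an F1-versus-feature-count curve.

The classical classifiers consume the manually pre-processed single-spectrum
representation by default (W-length feature vectors), matching the
per-wavenumber nature of the ranking; raw intensities are available via
``representation='raw'``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
import numpy as np
import pandas as pd
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .attribution import FeatureRanking
from .cv import FoldPlan, TrainConfig, f1_score, make_fold_plan, train_with_epoch_selection
from .dataset import ConfigError, SpectralDataset
from .nn import AnnSpec, build_ann
from .preprocess import fit_standardizer, manual_pipeline, standardize

logger = logging.getLogger(__name__)

DEFAULT_SIZES = (1, 2, 3, 5, 10, 20, 50, 100, 300, 1015)
CLASSIFIERS = ("ann", "dt", "svm")
REPRESENTATIONS = ("raw", "manual_preprocessed")


@dataclass
class SubsetExperiment:
    """Configuration of one F1-vs-feature-count sweep."""

    sizes: tuple[int, ...] = DEFAULT_SIZES
    classifiers: tuple[str, ...] = CLASSIFIERS
    representation: str = "manual_preprocessed"
    ann_spec: AnnSpec = field(default_factory=AnnSpec)
    train_config: TrainConfig = field(default_factory=TrainConfig)

    def validate(self, n_features_total: int) -> None:
        sizes = tuple(s for s in self.sizes if s <= n_features_total)
        if any(s < 1 for s in self.sizes):
            raise ConfigError("subset sizes must be >= 1")
        if tuple(sorted(sizes)) != sizes:
            raise ConfigError("subset sizes must be sorted ascending")
        if self.representation not in REPRESENTATIONS:
            raise ConfigError(f"representation must be one of {REPRESENTATIONS}")
        for c in self.classifiers:
            if c not in CLASSIFIERS:
                raise ConfigError(f"unknown classifier {c!r}")


def _single_spectrum_table(dataset: SpectralDataset, representation: str) -> np.ndarray:
    if representation == "raw":
        return dataset.intensity_matrix()
    if representation == "manual_preprocessed":
        return np.stack([manual_pipeline(s).intensities for s in dataset])
    raise ConfigError(f"unknown representation {representation!r}")


def build_subset(
    dataset: SpectralDataset,
    ranking: FeatureRanking,
    n_features: int,
    representation: str = "manual_preprocessed",
    task: str | None = None,
) -> tuple[np.ndarray, np.ndarray | None, np.ndarray]:
    """Select the top-n ranked wavenumber columns of a single-spectrum table.

    Returns (feature table, labels or None, selected grid indices).  Columns
    appear in ranking order.  Standardisation is fold-dependent and therefore
    happens inside the CV loop, not here.
    """
    w = ranking.scores.size
    if not 1 <= n_features <= w:
        raise ValueError(f"n_features must be in [1, {w}], got {n_features}")
    if task is not None:
        dataset, y = dataset.for_task(task)
    else:
        y = None
    table = _single_spectrum_table(dataset, representation)
    if table.shape[1] != w:
        raise ValueError("ranking length does not match the dataset grid")
    cols = ranking.order[:n_features]
    return table[:, cols], y, cols


def _fit_eval_classical(name: str, x_tr, y_tr, x_te, seed: int):
    if name == "svm":
        clf = SVC()  # frozen defaults: RBF kernel, C=1, gamma='scale'
    elif name == "dt":
        clf = DecisionTreeClassifier(random_state=seed)  # Gini, unlimited depth
    else:
        raise ConfigError(f"not a classical classifier: {name!r}")
    clf.fit(x_tr, y_tr)
    return clf.predict(x_te)


def evaluate_subset_curve(
    dataset: SpectralDataset,
    ranking: FeatureRanking,
    task: str,
    experiment: SubsetExperiment | None = None,
    fold_plan: FoldPlan | None = None,
) -> pd.DataFrame:
    """F1 mean +/- sd per (classifier, subset size) under grouped k-fold CV."""
    experiment = experiment or SubsetExperiment()
    subset, y = dataset.for_task(task)
    table = _single_spectrum_table(subset, experiment.representation)
    n, w = table.shape
    experiment.validate(w)
    sizes = tuple(s for s in experiment.sizes if s <= w)
    if fold_plan is None:
        fold_plan = make_fold_plan(dataset, task, seed=experiment.train_config.seed)
    pids = np.array([s.patient_id for s in subset])
    ss = np.random.SeedSequence(experiment.train_config.seed)
    fold_seeds = [int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(len(fold_plan.folds))]
    rows = []
    for size in sizes:
        cols = ranking.order[:size]
        for clf_name in experiment.classifiers:
            per_fold = []
            for fold_idx, fold in enumerate(fold_plan.folds):
                tr = np.isin(pids, fold["train_patients"])
                va = np.isin(pids, fold["val_patients"])
                te = np.isin(pids, fold["test_patients"])
                x = table[:, cols]
                stats = fit_standardizer(x[tr][:, None, :])
                x_std = standardize(x[:, None, :], stats)[:, 0, :]
                if clf_name == "ann":
                    cfg = replace(experiment.train_config, seed=fold_seeds[fold_idx])
                    factory = lambda seed: build_ann(experiment.ann_spec, size, seed=seed)  # noqa: E731
                    model, _ = train_with_epoch_selection(
                        factory, (x_std[tr], y[tr], x_std[va], y[va]), cfg
                    )
                    y_pred = model.predict(x_std[te])
                else:
                    # classical models take the full training fold (no epoch
                    # selection), matching library-default training
                    trval = tr | va
                    y_pred = _fit_eval_classical(
                        clf_name, x_std[trval], y[trval], x_std[te], fold_seeds[fold_idx]
                    )
                per_fold.append(f1_score(y_pred, y[te]))
            rows.append(
                {
                    "n_features": size,
                    "classifier": clf_name,
                    "mean_f1": float(np.mean(per_fold)),
                    "sd_f1": float(np.std(per_fold)),
                    "per_fold_f1": list(per_fold),
                }
            )
            logger.info("%s n=%d: F1 %.4f +/- %.4f", clf_name, size,
                        rows[-1]["mean_f1"], rows[-1]["sd_f1"])
    return pd.DataFrame(rows)
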