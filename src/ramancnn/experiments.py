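"""Desk-scale validation experiments over the full pipeline.

These functions define the package's standard self-validation suite: each
one generates a synthetic cohort under a named scenario, runs the complete
protocol (channel bank, patient-grouped 6-fold CV with epoch selection,
Integrated-Gradients ranking) and measures a quantity with a known expected
behaviour — classification F1 under strong and null class effects,
completeness of the attribution, recovery of a planted band, and the
few-feature classification claim.

Problem sizes are fixed here once (see docs/methods.md): the strong and
null cohorts keep the study's 45+19 patient split with 3-4 spectra per
patient on one cartilage layer; the planted-truth cohorts use 8+8 patients
with 12-14 (single-band) or 8-10 (two-band) spectra each.  The CNN is the
2-block/16-filter desk-scale residual network; optimisation follows the
study protocol (Adam, learning rate 1e-4, betas (0.5, 0.999), batch 4)
with reduced epoch budgets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .attribution import FeatureRanking, aggregate_importance, attribute_fold, integrated_gradients
from .cv import EvalReport, FoldArtifacts, TrainConfig, f1_score, make_fold_plan, run_task
from .dataset import SpectralDataset
from .feature_selection import SubsetExperiment, evaluate_subset_curve
from .nn import AnnSpec
from .nn.resnet import SMALL_SPEC
from .simulate import CohortConfig, generate_cohort, ground_truth_bands, scenario_config

TASK = "disease_superficial"

#: cohort-shape overrides per scenario (sizes chosen for single-CPU runtimes)
SCENARIO_COHORT_KW = {
    "strong": dict(layers=("superficial",), spectra_per_patient=(3, 4)),
    "null": dict(layers=("superficial",), spectra_per_patient=(3, 4)),
    "single_band": dict(n_positive_patients=8, n_control_patients=8,
                        layers=("superficial",), spectra_per_patient=(12, 14)),
    "two_band": dict(n_positive_patients=8, n_control_patients=8,
                     layers=("superficial",), spectra_per_patient=(8, 10)),
}

#: epoch budgets per scenario (phase 1 may stop early once validation F1 is
#: perfect; the selected epoch is unchanged by that shortcut)
SCENARIO_EPOCHS = {"strong": 20, "null": 8, "single_band": 40, "two_band": 40}


@dataclass
class ScenarioRun:
    """Everything one scenario run produces."""

    scenario: str
    seed: int
    config: CohortConfig
    dataset: SpectralDataset
    report: EvalReport
    artifacts: list[FoldArtifacts]
    ranking: FeatureRanking | None = None
    bands: list[tuple[int, int]] = field(default_factory=list)


def run_scenario(
    scenario: str,
    seed: int,
    with_attribution: bool = False,
    n_steps: int = 50,
) -> ScenarioRun:
    """Generate the scenario cohort and run the full multichannel protocol."""
    cfg = scenario_config(scenario, seed=seed, **SCENARIO_COHORT_KW[scenario])
    dataset = generate_cohort(cfg)
    train_cfg = TrainConfig(epochs=SCENARIO_EPOCHS[scenario], batch_size=4, seed=seed)
    report, artifacts = run_task(
        dataset, TASK, "multichannel", train_cfg, model_spec=SMALL_SPEC,
        return_artifacts=True, stop_when_perfect=True,
    )
    run = ScenarioRun(
        scenario=scenario, seed=seed, config=cfg, dataset=dataset,
        report=report, artifacts=artifacts, bands=ground_truth_bands(cfg),
    )
    if with_attribution:
        maps = []
        for art in artifacts:
            maps.extend(attribute_fold(art.model, art.x_test, art.y_test, n_steps=n_steps))
        run.ranking = aggregate_importance(
            maps,
            provenance={"scenario": scenario, "seed": seed, "task": TASK,
                        "aggregation": "sum |IG| over channels, samples, folds"},
        )
    return run


def pooled_null_f1_band(
    artifacts: list[FoldArtifacts],
    n_permutations: int = 2000,
    seed: int = 0,
    alpha: float = 0.01,
) -> tuple[float, float]:
    """Permutation band for the across-fold mean F1 under no association.

    Within each fold the predictions are shuffled against the truths,
    preserving both marginals; the statistic is the mean of per-fold F1.
    """
    rng = np.random.default_rng(seed)
    preds = [art.y_pred.copy() for art in artifacts]
    truths = [art.y_test for art in artifacts]
    null = np.empty(n_permutations)
    for i in range(n_permutations):
        vals = []
        for p, t in zip(preds, truths):
            rng.shuffle(p)
            vals.append(f1_score(p, t))
        null[i] = float(np.mean(vals))
    lo, hi = np.quantile(null, [alpha / 2, 1 - alpha / 2])
    return float(lo), float(hi)


def completeness_residuals(
    run: ScenarioRun,
    n_inputs: int = 50,
    n_steps: int = 300,
) -> np.ndarray:
    """Relative completeness residuals of IG on trained fold models.

    Test inputs are drawn fold by fold (each attributed with that fold's
    model) until ``n_inputs`` spectra are used; the residual is normalised
    by |F(x) - F(x')|.
    """
    rels: list[float] = []
    for art in run.artifacts:
        model = art.model
        for i in range(art.x_test.shape[0]):
            if len(rels) >= n_inputs:
                return np.asarray(rels)
            x = art.x_test[i]
            target = int(art.y_test[i])
            amap = integrated_gradients(model, x, target_class=target, n_steps=n_steps)
            f_x = float(model.forward(x[None], train=False)[0, target])
            f_ref = float(model.forward(np.zeros_like(x)[None], train=False)[0, target])
            rels.append(amap.completeness_residual / (abs(f_x - f_ref) + 1e-12))
    return np.asarray(rels)


def band_recovery_hit(run: ScenarioRun, k: int = 10) -> bool:
    """True when every top-k ranked index lies in a planted band."""
    if run.ranking is None:
        raise ValueError("run has no ranking; call run_scenario(with_attribution=True)")
    top = run.ranking.order[:k]
    return all(any(lo <= i <= hi for lo, hi in run.bands) for i in top)


def band_recovery_experiment(seeds=(0, 1, 2, 3, 4), n_steps: int = 16) -> list[bool]:
    """Planted-band recovery across independent cohorts and trainings."""
    return [
        band_recovery_hit(run_scenario("single_band", seed, with_attribution=True,
                                       n_steps=n_steps))
        for seed in seeds
    ]


def few_feature_f1(run: ScenarioRun, n_features: int = 3,
                   classifiers: tuple[str, ...] = ("svm", "ann")) -> dict[str, float]:
    """Mean F1 of classical models on the top-n IG-ranked wavenumbers,
    under the same patient-grouped fold plan as the CNN run."""
    if run.ranking is None:
        raise ValueError("run has no ranking")
    experiment = SubsetExperiment(
        sizes=(n_features,),
        classifiers=classifiers,
        ann_spec=AnnSpec(),
        train_config=TrainConfig(epochs=100, batch_size=4, seed=run.seed),
    )
    plan = make_fold_plan(run.dataset, TASK, seed=run.seed)
    curve = evaluate_subset_curve(run.dataset, run.ranking, TASK, experiment, plan)
    return {row["classifier"]: float(row["mean_f1"]) for _, row in curve.iterrows()}
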