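"""Train the multi-channel CNN with patient-grouped 6-fold cross-validation
on a strongly separable synthetic disease task and report per-fold F1.

Uses the desk-scale residual network (2 blocks, 16 filters) and a reduced
epoch budget so the example runs in a few minutes on one CPU; the full-scale
protocol (6 blocks, 100 filters, 100 epochs) is the library default.
"""

from ramancnn import TrainConfig, generate_cohort, run_task, scenario_config
from ramancnn.nn.resnet import SMALL_SPEC

cohort = generate_cohort(
    scenario_config("strong", seed=1, layers=("superficial",), spectra_per_patient=(3, 4))
)
config = TrainConfig(epochs=20, batch_size=4, seed=1)
report = run_task(cohort, "disease_superficial", "multichannel", config,
                  model_spec=SMALL_SPEC, stop_when_perfect=True)

print(f"task={report.task} method={report.method}")
for i, (f1, conf) in enumerate(zip(report.per_fold_f1, report.confusions)):
    print(f"  fold {i}: F1={f1:.3f}  (tp={conf['tp']} fp={conf['fp']} fn={conf['fn']} tn={conf['tn']})")
print(f"mean F1 = {report.mean_f1:.3f} +/- {report.sd_f1:.3f}")
# With a factor-2 class effect at the 830 and 1330 cm^-1 bands and low
# noise, every fold should classify held-out patients nearly perfectly;
# the mean F1 is the figure comparable across methods (raw / preprocessed /
# multichannel).
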