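"""Generate a synthetic Raman cartilage cohort and write it to CSV.

The default scenario mirrors the study population: 45 osteoarthritic and 19
healthy donors, 15-20 spectra per donor per cartilage layer on a 1015-point
fingerprint-region grid, with Gaussian biomarker peaks on a random
fluorescence background plus noise and occasional cosmic-ray spikes.
"""

import numpy as np

from ramancnn import generate_cohort, scenario_config, write_spectra_table

config = scenario_config("default", seed=1)
cohort = generate_cohort(config)
path = write_spectra_table(cohort, "cohort.csv")

sub, y = cohort.for_task("disease_superficial")
print(f"wrote {path}: {len(cohort)} spectra from {len(cohort.patients())} patients")
print(f"disease task (superficial layer): {int(y.sum())} OA vs {int((1 - y).sum())} healthy spectra")
print(f"grid: {cohort.grid[0]:.0f}-{cohort.grid[-1]:.0f} cm^-1, {cohort.n_points} points")
print(f"mean intensity at 1330 cm^-1 (collagen band), OA/healthy: "
      f"{np.mean([s.intensities[np.argmin(np.abs(cohort.grid - 1330))] for s in sub if s.condition == 'OA']):.2f} / "
      f"{np.mean([s.intensities[np.argmin(np.abs(cohort.grid - 1330))] for s in sub if s.condition == 'Healthy']):.2f} a.u.")
# The OA/healthy ratio at the collagen band reflects the planted class
# effect; everything else (background, noise) is class-independent.
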