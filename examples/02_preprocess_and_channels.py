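"""Pre-process one spectrum two ways: the manual 4-step pipeline and the
8-channel baseline-correction bank the CNN consumes.

The manual pipeline (5th-order polynomial background subtraction, rubberband
hull subtraction, wavelet denoising, vector normalisation) produces one
cleaned spectrum; the channel bank instead stacks the raw spectrum with
seven differently baseline-corrected variants, leaving the choice of
correction to the network.
"""

import numpy as np

from ramancnn import channel_bank, generate_cohort, manual_pipeline, scenario_config

cohort = generate_cohort(scenario_config("default", seed=3))
spectrum = cohort[0]

clean = manual_pipeline(spectrum)
print(f"manual pipeline: ||y|| = {np.linalg.norm(clean.intensities):.6f} (vector-normalised)")
print(f"  raw intensity range: [{spectrum.intensities.min():.2f}, {spectrum.intensities.max():.2f}] a.u.")
print(f"  cleaned range:       [{clean.intensities.min():.4f}, {clean.intensities.max():.4f}]")

bank = channel_bank(spectrum)
print(f"\nchannel bank: {bank.channels.shape[0]} x {bank.channels.shape[1]} stack")
for name, row in zip(bank.channel_names, bank.channels):
    print(f"  {name:16s} mean {row.mean():+8.3f}  sd {row.std():7.3f}")
# Channel 0 is the untouched raw spectrum (large mean: fluorescence);
# the corrected channels are centred near zero because each baseline
# estimate removes the smooth background in its own way.
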