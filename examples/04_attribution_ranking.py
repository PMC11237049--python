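"""Rank wavenumbers by Integrated-Gradients importance and check the top
ranks against the planted discriminative band.

A single-band cohort plants class signal only at 1330 cm^-1 (collagen
CH2 wagging/twisting); after training, the cross-fold aggregated |IG|
ranking should concentrate on exactly that band.
"""

from ramancnn import top_k
from ramancnn.experiments import band_recovery_hit, run_scenario

run = run_scenario("single_band", seed=2, with_attribution=True, n_steps=50)
grid = run.dataset.grid

print(f"CNN mean F1 on the planted task: {run.report.mean_f1:.3f}")
(lo, hi), = run.bands
print(f"planted band: indices {lo}-{hi} ({grid[lo]:.0f}-{grid[hi]:.0f} cm^-1)")

table = top_k(run.ranking, grid, k=10)
print("\ntop-10 wavenumbers by aggregated |IG|:")
for _, row in table.iterrows():
    inside = lo <= row["index"] <= hi
    print(f"  #{int(row['rank']):2d}  {row['wavenumber']:7.1f} cm^-1  "
          f"score {row['score']:.3f}  {'IN BAND' if inside else 'outside'}")
print(f"\nall top-10 inside the planted band: {band_recovery_hit(run)}")
# A hit means the end-to-end pipeline (channel bank -> CNN -> IG -> ranking)
# attributes the decision to the wavenumbers that actually carry the signal.
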