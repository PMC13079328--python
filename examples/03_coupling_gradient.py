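"""Lesion burden vs EPVS counts across distance bins.

Fits one negative binomial model per 5 mm distance bin with lesion
log-volume as the predictor.  With distance-decay coupling switched on
in the generator, the coefficient profile decreases from the nearest bin
to the farthest: lesion burden predicts nearby EPVS counts strongly and
distal counts weakly or negatively.
"""

from pvspatial import per_bin_wml_coefficients, run_metrics
from pvspatial.synthetic import GroupConfig, SimulationConfig, simulate_cohort

cfg = SimulationConfig(groups=[GroupConfig("G", 80)], grid_shape=(64, 64, 64))
sim = simulate_cohort(cfg, seed=3)
metrics = run_metrics(sim)
frame = per_bin_wml_coefficients(metrics, sim.manifest)

print("NB coefficient of ln(WML volume) per distance bin:")
for _, row in frame.iterrows():
    bar = "#" * max(0, int(20 * (row["coefficient"] + 0.5)))
    print(f"  {row['bin']:>7}: {row['coefficient']:+.3f}  {bar}")
print("\nA decreasing profile is the signature of near-lesion EPVS clustering.")
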