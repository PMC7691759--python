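"""Estimate the annual genetic gain from check-relative yields.

Runs the pipeline on a compact simulated dataset with a known injected
trend, then reports the recovered slope of check-relative yield (GYC)
on trial series for each environment class.
"""

from metgains import PipelineConfig, SimConfig, run_pipeline

sim = SimConfig(n_series=8, sites_per_class=(4, 4, 1), entries_per_trial=30,
                n_subblocks=5, trend_pct_per_year=1.8)
report = run_pipeline(PipelineConfig(sim=sim, seed=2))

print(f"{report.n_trials_retained}/{report.n_trials_in} trials passed the "
      "repeatability filter")
for cls, g in report.gains.items():
    print(f"{cls:>6}: {g['slope_pct']:+.2f} %/yr  ({g['slope_kg']:+.1f} kg/ha/yr), "
          f"R2 = {g['r2']:.2f}, n = {g['n']} HYL points")
print()
print("The generator injected 1.8 %/yr; recovered slopes estimate it from "
      "the top-decile lines' yields relative to the constant checks.")
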