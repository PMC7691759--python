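"""Fit one alpha-lattice trial and decide whether to keep it.

The single-site model has fixed replicates, random sub-blocks within
replicates and (for variance components) random genotypes.  Entry-mean
repeatability H2 = s2_g / (s2_g + s2_e / r) below 0.05 flags a trial as
uninformative.
"""

from metgains import SimConfig, filter_trials, fit_single_trial, generate_met

plots, _ = generate_met(SimConfig(n_series=1, sites_per_class=(1, 0, 0), seed=3))
summary = fit_single_trial(plots)

print(f"trial {summary.trial_id}: mean yield {summary.mean_yield:.2f} t/ha")
print(f"  sigma2_g  = {summary.sigma2_g:.4f} (t/ha)^2   genetic variance")
print(f"  sigma2_sb = {summary.sigma2_sb:.4f} (t/ha)^2   sub-block variance")
print(f"  sigma2_e  = {summary.sigma2_e:.4f} (t/ha)^2   residual variance")
print(f"  repeatability = {summary.repeatability:.3f}  ({summary.repeatability_basis} basis)")
kept = filter_trials([summary], threshold=0.05)
print("retained for the multi-environment stage" if kept else "discarded (< 0.05)")
print()
print("top adjusted entry means (GLS, t/ha):")
print(summary.adjusted_entry_means.sort_values(ascending=False).head(3).to_string())
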