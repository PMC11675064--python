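"""Bin-wise mixed models: recover the cursor-visibility effect.

For each 10-mm bin the model  x ~ cue * distortion + (1 | subject)  is fit
and the biased - unbiased difference estimated per distortion level with
Bonferroni-adjusted p-values, then compared against the trajectory-level
threshold 0.05 / n_bins.
"""

import warnings

import reachbias as rb

pop = rb.PopulationParams(cursor_bias_w=(0.5, 0.5))
records = rb.simulate_experiment(8, population=pop, seed=3,
                                 simulate_fillers=False)
binned = rb.preprocess_records(records)

traj = "D"
with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    contrasts, runs = rb.analyze_trajectory(binned[binned.trajectory == traj])

n_bins = contrasts.bin_index.max()
print(f"trajectory {traj}: {n_bins} bins, "
      f"threshold alpha = {rb.adjusted_alpha(n_bins):.4f}")
print()
print("late-bin (final third) biased - unbiased estimates, mm:")
late = contrasts[contrasts.bin_index > 2 * n_bins / 3]
print(late.groupby("distortion")["estimate"].mean().round(2).to_string())
print()
print("significance runs (start-end bin):")
for r in runs:
    print(f"  {r.distortion:+3d} deg: bins {r.start_bin}-{r.end_bin}")
print()
print("Positive estimates at nonzero distortions mean cursor-visible trials")
print("deviate more (compensate less) than cursor-hidden ones; near zero at")
print("0 deg, where the cursor carries no conflicting information.")
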