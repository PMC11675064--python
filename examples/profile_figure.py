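"""Profile curves and a publication-style figure for one trajectory.

Draws, per distortion level, the cohort-mean lateral deviation of biased
(red) and unbiased (blue) trials along the movement, with shaded bands over
significant runs, and writes the plotted values as CSV.
"""

import warnings
from pathlib import Path

import reachbias as rb

out_dir = Path("scratch")
out_dir.mkdir(exist_ok=True)

pop = rb.PopulationParams(cursor_bias_w=(0.5, 0.5))
records = rb.simulate_experiment(8, population=pop, seed=3,
                                 simulate_fillers=False)
binned = rb.preprocess_records(records)
sub = binned[binned.trajectory == "A"]

with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    contrasts, runs = rb.analyze_trajectory(sub)
profiles = rb.build_profiles(sub)

fig_path = out_dir / "trajectory_A.svg"
csv_path = out_dir / "trajectory_A_profiles.csv"
rb.render_trajectory_figure(profiles, runs, fig_path)
profiles.to_csv(csv_path, index=False)

print(f"wrote {fig_path} and {csv_path}")
print()
print("per-bin curve values (first rows):")
print(profiles.head(6).to_string(index=False))
print()
print("Each curve is the across-subject mean of per-subject bin means; the")
print("gap between red and blue curves is the effect the models test.")
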