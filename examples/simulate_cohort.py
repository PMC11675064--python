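"""Simulate a small synthetic cohort and look at the raw sample table.

Every trial records two streams: the mouse (hand) path and the drawn line,
which is the mouse path rotated by the trial's distortion angle about the
start position.
"""

import numpy as np

import reachbias as rb

pop = rb.PopulationParams(cursor_bias_w=(0.5, 0.5))
records = rb.simulate_experiment(3, population=pop, seed=42,
                                 simulate_fillers=False)
frame = rb.records_to_frame(records)

print(f"experimental trial records: {len(records)} "
      f"({len(records) // 3} per subject)")
print(f"hit rate: {np.mean([r.hit for r in records]):.3f}")
print()
print(frame.head(6).to_string(index=False))

rec = records[0]
origin = rec.mouse.xy[0]
residual = np.abs(
    rec.line.xy - rb.apply_distortion(rec.mouse.xy, rec.spec.distortion, origin)
).max()
print()
print(f"line stream == distorted mouse stream, max residual {residual:.2e} mm")
print("The per-sample time stamps are uneven (time-driven recording), so")
print("spatial spacing varies with movement speed.")
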