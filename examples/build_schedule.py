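"""Generate and validate one session's trial plan.

The plan fully crosses 4 trajectories x 5 distortions x 2 cue conditions
x 4 repetitions (160 experimental trials) and chains them with 1-2 random
filler trials per gap.
"""

import reachbias as rb

sched = rb.build_schedule(seed=7, config={"filler_total": 303})
exp = sched.experimental
fillers = [t for t in sched.trials if t.role == "filler"]
types = {(t.distortion, t.cue) for t in exp}

print(f"total trials:        {len(sched.trials)}")
print(f"experimental trials: {len(exp)}")
print(f"filler trials:       {len(fillers)}")
print(f"condition types:     {len(types)}")
print(f"violations:          {rb.validate_schedule(sched)}")
print()
print(sched.to_frame().head(8).to_string(index=False))
print()
print("Each row is one planned trial; experimental rows carry a trajectory")
print("label (A-D) while fillers only connect dots between them.")
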