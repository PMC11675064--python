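"""Randomized trial plans for the line-drawing experiment.

A session fully crosses 4 trajectories x 5 distortions x 2 visual-input
conditions x 4 repetitions = 160 experimental trials, presented in random
order.  Consecutive experimental trials are separated by one or two filler
trials whose purpose is to mask the design and suppress adaptation; fillers
get a random distortion and cue and are excluded from analysis.  Because
every trial starts on the dot where the previous one ended, fillers also
serve as connecting moves: each gap's filler path chains the previous
experimental end dot to the next experimental start dot.

The realized session of the original design had 303 fillers (463 trials in
total); that count is one random realization, not a design rule, so by
default each gap independently receives 1 or 2 fillers.  An exact filler
total in [159, 318] can be requested instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .geometry import CUE_CONDITIONS, DISTORTION_LEVELS, EXPERIMENTAL_PAIRS, TRAJECTORIES

__all__ = ["TrialSpec", "TrialSchedule", "build_schedule", "validate_schedule"]

_DOTS = (1, 2, 3, 4, 5, 6)
_N_GAPS = 159  # between 160 experimental trials


@dataclass(frozen=True)
class TrialSpec:
    """One planned trial: dot pair, condition labels and role."""

    index: int
    role: str  # "experimental" or "filler"
    start_dot: int
    end_dot: int
    trajectory: str | None  # A-D for experimental trials, None for fillers
    distortion: int  # degrees, one of DISTORTION_LEVELS
    cue: str  # "biased" (cursor visible) or "unbiased"
    block: int  # 1 or 2 (session halves separated by a rest phase)


@dataclass(frozen=True)
class TrialSchedule:
    trials: tuple[TrialSpec, ...]
    seed: int

    @property
    def experimental(self) -> tuple[TrialSpec, ...]:
        return tuple(t for t in self.trials if t.role == "experimental")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "index": [t.index for t in self.trials],
                "role": [t.role for t in self.trials],
                "start_dot": [t.start_dot for t in self.trials],
                "end_dot": [t.end_dot for t in self.trials],
                "trajectory": [t.trajectory or "" for t in self.trials],
                "distortion": [t.distortion for t in self.trials],
                "cue": [t.cue for t in self.trials],
                "block": [t.block for t in self.trials],
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _filler_path(rng, prev_end: int, next_start: int, n_fillers: int) -> list[tuple[int, int]]:
    """Dot pairs for the fillers chaining prev_end to next_start."""
    if n_fillers == 1:
        if prev_end == next_start or (prev_end, next_start) in EXPERIMENTAL_PAIRS:
            raise ValueError("single filler cannot chain this gap")
        return [(prev_end, next_start)]
    # two fillers through an intermediate dot that makes neither leg an
    # experimental pair nor a zero-length move
    candidates = [
        m
        for m in _DOTS
        if m != prev_end
        and m != next_start
        and (prev_end, m) not in EXPERIMENTAL_PAIRS
        and (m, next_start) not in EXPERIMENTAL_PAIRS
    ]
    m = int(rng.choice(candidates))
    return [(prev_end, m), (m, next_start)]


def build_schedule(seed: int, config: dict | None = None) -> TrialSchedule:
    """Generate a full session plan, deterministic in ``seed``.

    ``config`` keys (optional):

    - ``n_reps``: repetitions per (trajectory, distortion, cue) cell,
      default 4 (i.e. 160 experimental trials);
    - ``filler_total``: exact filler count in [159, 318]; default None
      (each gap independently gets 1 or 2 fillers);
    - ``max_retries``: orderings to try before giving up when the filler
      constraint is infeasible for a drawn order (default 50).
    """
    config = dict(config or {})
    n_reps = int(config.get("n_reps", 4))
    filler_total = config.get("filler_total")
    max_retries = int(config.get("max_retries", 50))
    rng = np.random.default_rng(seed)

    cells = [
        (traj, d, cue)
        for traj in TRAJECTORIES
        for d in DISTORTION_LEVELS
        for cue in CUE_CONDITIONS
    ]
    n_exp = n_reps * len(cells)
    n_gaps = n_exp - 1

    for _attempt in range(max_retries):
        order = cells * n_reps  # explicit multiset of condition cells
        order = [order[i] for i in rng.permutation(len(order))]

        # per-gap filler counts; gaps whose endpoints coincide need 2 fillers
        exp_defs = [TRAJECTORIES[traj] for traj, _, _ in order]
        forced = np.array(
            [
                exp_defs[i].end_dot == exp_defs[i + 1].start_dot
                or (exp_defs[i].end_dot, exp_defs[i + 1].start_dot) in EXPERIMENTAL_PAIRS
                for i in range(n_gaps)
            ]
        )
        if filler_total is None:
            counts = rng.integers(1, 3, size=n_gaps)
            counts[forced] = 2
        else:
            filler_total = int(filler_total)
            if not (n_gaps <= filler_total <= 2 * n_gaps):
                raise ValueError(
                    f"filler_total must lie in [{n_gaps}, {2 * n_gaps}]"
                )
            n_double = filler_total - n_gaps
            if n_double < int(forced.sum()):
                continue  # this ordering forces too many double gaps; redraw
            counts = np.ones(n_gaps, dtype=int)
            counts[forced] = 2
            free = np.flatnonzero(~forced)
            extra = rng.choice(free, size=n_double - int(forced.sum()), replace=False)
            counts[extra] = 2
        break
    else:
        raise RuntimeError("could not draw a schedule satisfying the filler constraint")

    trials: list[TrialSpec] = []
    idx = 0
    for i, ((traj, dist, cue), tdef) in enumerate(zip(order, exp_defs)):
        trials.append(
            TrialSpec(idx, "experimental", tdef.start_dot, tdef.end_dot,
                      traj, dist, cue, block=1)
        )
        idx += 1
        if i < n_gaps:
            nxt = exp_defs[i + 1]
            for (a, b) in _filler_path(rng, tdef.end_dot, nxt.start_dot, int(counts[i])):
                trials.append(
                    TrialSpec(
                        idx, "filler", a, b, None,
                        int(rng.choice(DISTORTION_LEVELS)),
                        str(rng.choice(CUE_CONDITIONS)),
                        block=1,
                    )
                )
                idx += 1

    half = len(trials) // 2
    trials = [replace(t, block=1 if t.index < half else 2) for t in trials]
    return TrialSchedule(tuple(trials), seed=int(seed))


def validate_schedule(s: TrialSchedule, n_reps: int = 4) -> list[str]:
    """Check every design invariant; returns a list of violation messages.

    An empty list means the schedule is valid: correct experimental count,
    exact condition balance, experimental trials on the four defined dot
    pairs, fillers on other pairs, 1-2 fillers per gap, and the chaining
    rule (each trial starts on the previous trial's end dot).
    """
    violations: list[str] = []
    exp = [t for t in s.trials if t.role == "experimental"]
    n_expected = n_reps * len(TRAJECTORIES) * len(DISTORTION_LEVELS) * len(CUE_CONDITIONS)
    if len(exp) != n_expected:
        violations.append(f"experimental trial count {len(exp)} != {n_expected}")

    counts: dict[tuple, int] = {}
    for t in exp:
        counts[(t.trajectory, t.distortion, t.cue)] = (
            counts.get((t.trajectory, t.distortion, t.cue), 0) + 1
        )
    for traj in TRAJECTORIES:
        for d in DISTORTION_LEVELS:
            for cue in CUE_CONDITIONS:
                c = counts.get((traj, d, cue), 0)
                if c != n_reps:
                    violations.append(
                        f"combination ({traj}, {d:+d}, {cue}) count {c} != {n_reps}"
                    )

    for t in s.trials:
        if t.start_dot == t.end_dot:
            violations.append(f"trial {t.index}: start dot equals end dot")
        pair = (t.start_dot, t.end_dot)
        if t.role == "experimental":
            tdef = TRAJECTORIES.get(t.trajectory or "")
            if tdef is None or pair != (tdef.start_dot, tdef.end_dot):
                violations.append(
                    f"trial {t.index}: experimental pair {pair} does not match "
                    f"trajectory {t.trajectory}"
                )
        else:
            if pair in EXPERIMENTAL_PAIRS:
                violations.append(
                    f"trial {t.index}: filler uses experimental pair {pair}"
                )
        if t.distortion not in DISTORTION_LEVELS:
            violations.append(f"trial {t.index}: distortion {t.distortion} invalid")
        if t.cue not in CUE_CONDITIONS:
            violations.append(f"trial {t.index}: cue {t.cue!r} invalid")

    for prev, nxt in zip(s.trials, s.trials[1:]):
        if nxt.start_dot != prev.end_dot:
            violations.append(
                f"trial {nxt.index}: starts on dot {nxt.start_dot}, previous "
                f"trial ended on dot {prev.end_dot}"
            )

    exp_positions = [i for i, t in enumerate(s.trials) if t.role == "experimental"]
    for a, b in zip(exp_positions, exp_positions[1:]):
        n_fill = b - a - 1
        if not 1 <= n_fill <= 2:
            violations.append(
                f"gap after experimental trial at position {a}: {n_fill} fillers"
            )
    return violations
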