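"""Synthetic participants for the distorted reaching task.

The task has no published participant model, so the generator implements the
minimal closed-loop controller that reproduces the two features the analysis
pipeline needs to be able to recover:

1. *Distortion compensation*: the controller steers the mouse toward the
   position whose distorted line lands on the target, so mouse paths curve
   by the compensation angle while line paths stay close to straight.
2. *A cursor-visibility effect of tunable size*: when the cursor is visible
   ("biased" trials), the commanded heading is pulled toward the naive,
   cursor-aimed direction (straight at the target), degrading compensation.
   With the cursor hidden the pull is zero.  At zero distortion the two
   headings coincide, so the cursor has no effect — matching the design's
   control condition.  The pull saturates with the remaining distance to
   the compensated aim point, ``b_eff = cursor_bias_w * err / (err +
   bias_taper)``: far from the goal the cursor dominates at its full
   weight, but close in the line feedback wins, because the task cannot end
   until the *line* hits the target.  A constant-weight pull instead has a
   stalling equilibrium between the two aim points (the headings become
   antiparallel there), which would leave strongly biased distorted trials
   unable to finish at all.

On top of the headings the controller has first-order smoothing (``gain``),
feedback delay (index lag), step-length variability (so spatial sample
spacing is uneven, as with time-driven recording), per-step Gaussian motor
noise, and a subject-level lateral aim offset that gives the cohort true
between-subject variance for the mixed model's random intercept.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .geometry import (
    DotLayout,
    apply_distortion,
    build_default_layout,
    required_mouse_position,
)
from .schedule import TrialSchedule, TrialSpec, build_schedule

__all__ = [
    "ParticipantParams",
    "PopulationParams",
    "RawTrajectory",
    "TrialRecord",
    "simulate_trial",
    "simulate_experiment",
    "records_to_frame",
    "frame_to_records",
]


@dataclass(frozen=True)
class ParticipantParams:
    """Controller parameters for one synthetic participant.

    gain
        Fraction of the commanded heading blended into the running heading
        per step (1 = no smoothing).
    cursor_bias_w
        Attraction toward the cursor-aimed (uncompensated) heading, applied
        only on biased (cursor-visible) trials.
    bias_taper
        Distance scale (mm) of the cursor pull's saturation: the effective
        weight is ``cursor_bias_w * err / (err + bias_taper)`` where err is
        the remaining distance to the compensated aim point.
    noise_sd
        Isotropic Gaussian motor noise per step, mm.
    delay
        Feedback lag, in steps, of the position the controller reacts to.
    speed_mean, speed_cv
        Step length distribution: Normal(speed_mean, speed_cv * speed_mean),
        truncated at zero.  Units mm per step.
    hit_radius
        Distance (mm) of the line tip from the target that registers a hit.
    lateral_offset
        Subject-specific rightward shift (mm) of the aim point; the
        realization of the cohort's random intercept.
    """

    gain: float = 0.6
    cursor_bias_w: float = 0.4
    bias_taper: float = 50.0
    noise_sd: float = 0.8
    delay: int = 2
    speed_mean: float = 8.0
    speed_cv: float = 0.4
    hit_radius: float = 5.0
    lateral_offset: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.gain <= 1.0:
            raise ValueError("gain must lie in [0, 1]")
        if not 0.0 <= self.cursor_bias_w <= 1.0:
            raise ValueError("cursor_bias_w must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.speed_mean <= 0:
            raise ValueError("speed_mean must be positive")
        if self.hit_radius <= 0:
            raise ValueError("hit_radius must be positive")
        if self.delay < 0:
            raise ValueError("delay must be non-negative")
        if self.bias_taper < 0:
            raise ValueError("bias_taper must be non-negative")


@dataclass(frozen=True)
class PopulationParams:
    """Cohort-level distributions the per-subject parameters are drawn from.

    Scalar fields are uniform ranges ``(low, high)``; ``subject_offset_sd``
    is the SD of the Normal lateral aim offset (the true random-intercept
    scale the mixed model should recover).
    """

    gain: tuple[float, float] = (0.5, 0.7)
    cursor_bias_w: tuple[float, float] = (0.3, 0.6)
    noise_sd: tuple[float, float] = (0.5, 1.0)
    speed_mean: tuple[float, float] = (6.0, 10.0)
    speed_cv: tuple[float, float] = (0.3, 0.5)
    delay: int = 2
    hit_radius: float = 5.0
    subject_offset_sd: float = 2.0

    def draw(self, rng: np.random.Generator) -> ParticipantParams:
        u = lambda lohi: float(rng.uniform(*lohi))
        return ParticipantParams(
            gain=u(self.gain),
            cursor_bias_w=u(self.cursor_bias_w),
            noise_sd=u(self.noise_sd),
            delay=self.delay,
            speed_mean=u(self.speed_mean),
            speed_cv=u(self.speed_cv),
            hit_radius=self.hit_radius,
            lateral_offset=float(rng.normal(0.0, self.subject_offset_sd)),
        )


@dataclass(frozen=True)
class RawTrajectory:
    """Time-stamped 2-D samples of one stream (mouse or line)."""

    t_ms: np.ndarray  # shape (n,), strictly increasing
    xy: np.ndarray  # shape (n, 2), mm

    def __post_init__(self) -> None:
        t = np.asarray(self.t_ms, dtype=float)
        xy = np.asarray(self.xy, dtype=float)
        if t.ndim != 1 or xy.shape != (t.size, 2):
            raise ValueError("t_ms must be (n,), xy must be (n, 2)")
        if t.size < 2:
            raise ValueError("a trajectory needs at least 2 samples")
        if not np.all(np.diff(t) > 0):
            raise ValueError("timestamps must be strictly increasing")
        object.__setattr__(self, "t_ms", t)
        object.__setattr__(self, "xy", xy)

    def __len__(self) -> int:
        return self.t_ms.size


@dataclass(frozen=True)
class TrialRecord:
    """One simulated (or imported) trial: both streams plus labels."""

    subject_id: str
    spec: TrialSpec
    mouse: RawTrajectory
    line: RawTrajectory
    hit: bool


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    return v / n if n > 0 else v


def simulate_trial(
    params: ParticipantParams,
    spec: TrialSpec,
    layout: DotLayout,
    rng: np.random.Generator,
    dt_ms: float = 16.0,
    step_cap_factor: float = 10.0,
) -> TrialRecord:
    """Run the closed-loop controller for one trial.

    Per step the controller blends the corrective heading (toward the mouse
    position whose distorted line hits the target) with the naive heading
    (straight at the target) using the distance-saturating cursor-bias
    weight, smooths it with the previous heading via ``gain``, and takes a
    noisy step of random length.  Both headings are computed from the
    position ``delay`` steps ago.  The trial ends when the line tip enters
    ``hit_radius`` of the target, or at a step cap (recorded as a miss).

    Sample timestamps advance by a jittered interval around ``dt_ms``:
    recording is time-driven, so spatial spacing varies with speed.
    """
    origin = np.asarray(layout[spec.start_dot], dtype=float)
    target = np.asarray(layout[spec.end_dot], dtype=float)
    if np.allclose(origin, target):
        raise ValueError("degenerate trial: origin equals target")
    theta = float(spec.distortion)
    offset = np.array([params.lateral_offset, 0.0])
    aim_required = required_mouse_position(target, theta, origin) + offset
    aim_target = target + offset
    b = params.cursor_bias_w if spec.cue == "biased" else 0.0

    straight_steps = int(np.ceil(np.linalg.norm(target - origin) / params.speed_mean))
    cap = max(4, int(step_cap_factor * straight_steps))

    pts = [origin.copy()]
    times = [0.0]
    heading: np.ndarray | None = None
    hit = False
    for _k in range(cap):
        ref = pts[max(0, len(pts) - 1 - params.delay)]
        err = float(np.linalg.norm(aim_required - ref))
        b_eff = b * err / (err + params.bias_taper) if err > 0 else 0.0
        h_corr = _unit(aim_required - ref)
        h_naive = _unit(aim_target - ref)
        cmd = _unit((1.0 - b_eff) * h_corr + b_eff * h_naive)
        heading = cmd if heading is None else _unit(
            (1.0 - params.gain) * heading + params.gain * cmd
        )
        step = max(0.0, rng.normal(params.speed_mean, params.speed_cv * params.speed_mean))
        pos = pts[-1] + heading * step
        if params.noise_sd > 0:
            pos = pos + rng.normal(0.0, params.noise_sd, size=2)
        pts.append(pos)
        times.append(times[-1] + dt_ms * rng.uniform(0.75, 1.25))
        line_tip = apply_distortion(pos, theta, origin)
        if np.linalg.norm(line_tip - target) <= params.hit_radius:
            hit = True
            break

    mouse_xy = np.asarray(pts)
    line_xy = apply_distortion(mouse_xy, theta, origin)
    t = np.asarray(times)
    return TrialRecord(
        subject_id="",
        spec=spec,
        mouse=RawTrajectory(t, mouse_xy),
        line=RawTrajectory(t, line_xy),
        hit=hit,
    )


def simulate_experiment(
    n_subjects: int,
    population: PopulationParams | None = None,
    seed: int = 0,
    layout: DotLayout | None = None,
    schedule_config: dict | None = None,
    simulate_fillers: bool = True,
    keep_fillers: bool = False,
) -> list[TrialRecord]:
    """Simulate a cohort; returns experimental-trial records only by default.

    Each subject gets an independent schedule and an independent parameter
    draw from ``population``; everything is deterministic given ``seed``.
    Filler trials are simulated (they are part of the session) but dropped
    from the returned analysis store, mirroring the design's exclusion rule;
    set ``simulate_fillers=False`` to skip them for speed, or
    ``keep_fillers=True`` to retain their records.
    """
    if n_subjects < 2:
        raise ValueError("a cohort needs at least 2 subjects")
    population = population or PopulationParams()
    layout = layout or build_default_layout()
    root = np.random.SeedSequence(seed)
    subject_seqs = root.spawn(n_subjects)

    records: list[TrialRecord] = []
    for i, seq in enumerate(subject_seqs):
        rng = np.random.default_rng(seq)
        sched_seed = int(rng.integers(0, 2**31 - 1))
        sched = build_schedule(sched_seed, schedule_config)
        params = population.draw(rng)
        sid = f"S{i + 1:03d}"
        for spec in sched.trials:
            if spec.role == "filler" and not simulate_fillers:
                continue
            rec = simulate_trial(params, spec, layout, rng)
            rec = replace(rec, subject_id=sid)
            if spec.role == "experimental" or keep_fillers:
                records.append(rec)
    return records


def records_to_frame(records: list[TrialRecord]) -> pd.DataFrame:
    """Long sample table: one row per stream sample, with all trial labels.

    Columns: subject_id, trial_index, role, trajectory, start_dot, end_dot,
    distortion_deg, cue, hit, stream, t_ms, x_mm, y_mm.  This is the raw CSV
    schema accepted back by :func:`frame_to_records`.
    """
    chunks = []
    for rec in records:
        s = rec.spec
        for stream, traj in (("mouse", rec.mouse), ("line", rec.line)):
            n = len(traj)
            chunks.append(
                pd.DataFrame(
                    {
                        "subject_id": np.repeat(rec.subject_id, n),
                        "trial_index": s.index,
                        "role": s.role,
                        "trajectory": s.trajectory or "",
                        "start_dot": s.start_dot,
                        "end_dot": s.end_dot,
                        "distortion_deg": s.distortion,
                        "cue": s.cue,
                        "hit": rec.hit,
                        "stream": stream,
                        "t_ms": traj.t_ms,
                        "x_mm": traj.xy[:, 0],
                        "y_mm": traj.xy[:, 1],
                    }
                )
            )
    return pd.concat(chunks, ignore_index=True)


def frame_to_records(frame: pd.DataFrame) -> list[TrialRecord]:
    """Rebuild :class:`TrialRecord` objects from the raw sample table."""
    records = []
    for (sid, idx), g in frame.groupby(["subject_id", "trial_index"], sort=True):
        first = g.iloc[0]
        spec = TrialSpec(
            index=int(idx),
            role=str(first["role"]),
            start_dot=int(first["start_dot"]),
            end_dot=int(first["end_dot"]),
            trajectory=str(first["trajectory"]) or None,
            distortion=int(first["distortion_deg"]),
            cue=str(first["cue"]),
            block=1,
        )
        streams = {}
        for stream, gs in g.groupby("stream"):
            gs = gs.sort_values("t_ms")
            streams[stream] = RawTrajectory(
                gs["t_ms"].to_numpy(), gs[["x_mm", "y_mm"]].to_numpy()
            )
        records.append(
            TrialRecord(
                subject_id=str(sid),
                spec=spec,
                mouse=streams["mouse"],
                line=streams["line"],
                hit=bool(first["hit"]),
            )
        )
    return records
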