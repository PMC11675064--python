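"""Trajectory normalization and binning.

Every recorded trajectory is mapped into a common frame in three steps:

1. *Centering*: translate so the origin dot sits at (0, 0).
2. *Alignment*: rotate about the origin so the destination dot sits on the
   positive y-axis at (0, L), L being the dot-pair chord length.
3. *Rescaling*: interpolate the unevenly time-sampled path to an even
   arc-length polyline and read x at every integer millimetre of y.

Because recording is time-driven, raw sample spacing depends on movement
speed; the arc-length interpolation removes that dependence.  Movements can
backtrack in y, so a y level may be crossed several times; the first
crossing along the path is used and levels never crossed are flagged as
missing rather than imputed.

After normalization, x values of negative-distortion trials are negated
(mirrored about the y-axis) so left/right deviations are comparable across
distortion signs, and per-mm samples are pooled into 10-mm y bins.  The
first bin (0-10 mm) and any trailing partial bin are discarded; with the
default rules a 351 mm trajectory keeps 34 bins and a 210 mm one keeps 20.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .geometry import DotLayout, TRAJECTORIES, build_default_layout, rotate_point
from .simulate import TrialRecord

__all__ = [
    "NormalizedTrajectory",
    "center",
    "align",
    "interpolate_and_sample",
    "normalize_trial",
    "mirror_negative",
    "bin_samples",
    "preprocess_records",
    "retained_bins",
]

BIN_WIDTH_MM = 10.0

# tolerance applied before flooring lengths, so a chord recovered as
# 350.999...9 mm after rotation still yields 351 y levels
_FLOOR_EPS = 1e-9


def _floor(value: float) -> int:
    return int(np.floor(value + _FLOOR_EPS))


@dataclass(frozen=True)
class NormalizedTrajectory:
    """x (mm) at y = 1, 2, ..., floor(length) mm in the aligned frame."""

    subject_id: str
    trajectory: str
    distortion: int
    cue: str
    length: float
    xs: np.ndarray  # shape (floor(length),), NaN where a y level was never crossed

    def __post_init__(self) -> None:
        xs = np.asarray(self.xs, dtype=float)
        if xs.shape != (_floor(self.length),):
            raise ValueError("xs must have one entry per integer mm of y")
        object.__setattr__(self, "xs", xs)

    @property
    def n_missing(self) -> int:
        return int(np.isnan(self.xs).sum())


def center(points, origin_dot, dest_dot):
    """Translate so the origin dot is at (0, 0); returns (points, origin, dest)."""
    points = np.asarray(points, dtype=float)
    origin_dot = np.asarray(origin_dot, dtype=float)
    dest_dot = np.asarray(dest_dot, dtype=float)
    return points - origin_dot, origin_dot - origin_dot, dest_dot - origin_dot


def align(points, dest_dot):
    """Rotate about (0, 0) so the destination dot lands on the +y axis.

    Assumes the trajectory is already centered.  Returns the rotated points
    and the rotated destination (0, ||dest||).
    """
    points = np.asarray(points, dtype=float)
    dest_dot = np.asarray(dest_dot, dtype=float)
    norm = np.linalg.norm(dest_dot)
    if norm == 0:
        raise ValueError("destination dot coincides with the origin")
    if points.shape[0] == 0:
        raise ValueError("empty trajectory")
    phi = 90.0 - np.degrees(np.arctan2(dest_dot[1], dest_dot[0]))
    return rotate_point(points, phi), rotate_point(dest_dot, phi)


def interpolate_and_sample(points, length: float, resolution: float = 0.1) -> np.ndarray:
    """Read x at each integer mm of y from an aligned trajectory.

    The polyline is first resampled evenly in arc length at ``resolution``
    mm, then each y level y = 1..floor(length) gets the x of the *first*
    crossing of that level along the path (piecewise-linear within
    segments).  Levels never crossed are NaN.
    """
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or points.shape[1] != 2:
        raise ValueError("points must have shape (n, 2)")
    # collapse consecutive duplicates so arc length is strictly increasing
    keep = np.ones(len(points), dtype=bool)
    keep[1:] = np.any(np.diff(points, axis=0) != 0, axis=1)
    points = points[keep]
    if len(points) < 2:
        raise ValueError("need at least 2 distinct points")

    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    n_dense = max(2, int(np.ceil(s[-1] / resolution)) + 1)
    # keep the original vertices in the grid so corner extrema are exact
    sd = np.union1d(np.linspace(0.0, s[-1], n_dense), s)
    x = np.interp(sd, s, points[:, 0])
    y = np.interp(sd, s, points[:, 1])

    n_levels = _floor(length)
    xs = np.full(n_levels, np.nan)
    y0, y1 = y[:-1], y[1:]
    lo = np.floor(np.minimum(y0, y1)).astype(int) + 1
    hi = np.floor(np.maximum(y0, y1)).astype(int)
    crossing = np.flatnonzero(lo <= hi)
    remaining = n_levels
    for i in crossing:
        if remaining == 0:
            break
        dy = y1[i] - y0[i]
        for m in range(lo[i], hi[i] + 1):
            if 1 <= m <= n_levels and np.isnan(xs[m - 1]):
                xs[m - 1] = x[i] + (m - y0[i]) * (x[i + 1] - x[i]) / dy
                remaining -= 1
    return xs


def normalize_trial(
    record: TrialRecord,
    layout: DotLayout | None = None,
    stream: str = "mouse",
    resolution: float = 0.1,
) -> NormalizedTrajectory:
    """Center, align and resample one trial's chosen stream.

    ``stream`` selects the analyzed trajectory: the hand movement
    (``"mouse"``, default) or the drawn line (``"line"``).
    """
    layout = layout or build_default_layout()
    spec = record.spec
    if spec.trajectory is None:
        raise ValueError("cannot normalize a filler trial (no trajectory label)")
    traj = getattr(record, stream)
    origin = layout[spec.start_dot]
    dest = layout[spec.end_dot]
    pts, _, dest_c = center(traj.xy, origin, dest)
    pts, dest_a = align(pts, dest_c)
    length = float(dest_a[1])
    xs = interpolate_and_sample(pts, length, resolution)
    return NormalizedTrajectory(
        subject_id=record.subject_id,
        trajectory=spec.trajectory,
        distortion=spec.distortion,
        cue=spec.cue,
        length=length,
        xs=xs,
    )


def mirror_negative(nt: NormalizedTrajectory) -> NormalizedTrajectory:
    """Negate x for negative-distortion trials (180-degree flip about the
    y-axis); the signed distortion label is preserved for grouping."""
    if nt.distortion >= 0:
        return nt
    return replace(nt, xs=-nt.xs)


def retained_bins(
    length: float,
    include_partial_bins: bool = False,
    min_partial_width_mm: float = 5.0,
) -> list[int]:
    """Indices of the 10-mm bins kept for a trajectory of given length.

    Bin k covers y in [10k, 10(k+1)).  Bin 0 is always discarded, as is a
    trailing bin not fully inside the trajectory, unless
    ``include_partial_bins`` keeps partial bins at least
    ``min_partial_width_mm`` wide.
    """
    k_max = _floor(length / BIN_WIDTH_MM) - 1
    bins = list(range(1, k_max + 1))
    partial_width = length - BIN_WIDTH_MM * (k_max + 1)
    if include_partial_bins and partial_width >= min_partial_width_mm:
        bins.append(k_max + 1)
    return bins


def bin_samples(
    nts: list[NormalizedTrajectory],
    include_partial_bins: bool = False,
    min_partial_width_mm: float = 5.0,
) -> pd.DataFrame:
    """Pool per-mm samples of one trajectory's trials into 10-mm y bins.

    Returns a long table with one row per retained per-mm sample:
    subject_id, trajectory, distortion, cue, bin_index, bin_label, y_mm, x.
    Missing y levels contribute no rows.  Raises on mixed trajectory labels.
    """
    if not nts:
        raise ValueError("no trajectories to bin")
    labels = {nt.trajectory for nt in nts}
    if len(labels) > 1:
        raise ValueError(f"mixed trajectory labels: {sorted(labels)}")

    chunks = []
    for nt in nts:
        keep = set(retained_bins(nt.length, include_partial_bins, min_partial_width_mm))
        y = np.arange(1, len(nt.xs) + 1)
        k = y // int(BIN_WIDTH_MM)
        mask = np.isin(k, list(keep)) & ~np.isnan(nt.xs)
        if not mask.any():
            continue
        chunks.append(
            pd.DataFrame(
                {
                    "subject_id": nt.subject_id,
                    "trajectory": nt.trajectory,
                    "distortion": nt.distortion,
                    "cue": nt.cue,
                    "bin_index": k[mask],
                    "y_mm": y[mask],
                    "x": nt.xs[mask],
                }
            )
        )
    out = pd.concat(chunks, ignore_index=True)
    out["bin_label"] = [
        f"{10 * k}-{10 * (k + 1)}" for k in out["bin_index"]
    ]
    return out


def preprocess_records(
    records: list[TrialRecord],
    layout: DotLayout | None = None,
    stream: str = "mouse",
    only_hits: bool = True,
    resolution: float = 0.1,
    include_partial_bins: bool = False,
    min_partial_width_mm: float = 5.0,
) -> pd.DataFrame:
    """Full pipeline: normalize, mirror, and bin a set of trial records.

    Filler trials and (by default) missed trials are excluded.  Returns the
    binned long table for all trajectories combined.
    """
    layout = layout or build_default_layout()
    by_traj: dict[str, list[NormalizedTrajectory]] = {}
    for rec in records:
        if rec.spec.role != "experimental":
            continue
        if only_hits and not rec.hit:
            continue
        nt = mirror_negative(normalize_trial(rec, layout, stream, resolution))
        by_traj.setdefault(nt.trajectory, []).append(nt)
    if not by_traj:
        raise ValueError("no analyzable records")
    frames = [
        bin_samples(nts, include_partial_bins, min_partial_width_mm)
        for _, nts in sorted(by_traj.items())
    ]
    return pd.concat(frames, ignore_index=True)
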