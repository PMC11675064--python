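"""Screen geometry for the distorted line-drawing task.

Coordinates are millimetres in a screen-centered frame: x increases to the
participant's right, y increases upward (away from the body), origin at the
screen center.  Pixel units exist only at the I/O boundary through
:class:`ScreenCalibration`.

The task's visual distortion rotates the drawn line about the trial's start
position by a fixed angle.  The sign convention follows the task description:
a *positive* distortion pushes the line to the *right* of the instantaneous
movement direction, a negative one to the left.  In this frame that is a
clockwise rotation, i.e. rotation by ``-theta`` with the standard
counter-clockwise rotation matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import yaml

__all__ = [
    "DISTORTION_LEVELS",
    "CUE_CONDITIONS",
    "ScreenCalibration",
    "TrajectoryDef",
    "DotLayout",
    "TRAJECTORIES",
    "SCREEN_WIDTH_MM",
    "SCREEN_HEIGHT_MM",
    "rotate_point",
    "apply_distortion",
    "required_mouse_position",
    "build_default_layout",
    "load_layout_yaml",
]

#: The five distortion angles (degrees) used in the task.
DISTORTION_LEVELS: tuple[int, ...] = (-20, -10, 0, 10, 20)

#: Visual-input conditions: cursor visible ("biased") or hidden ("unbiased").
CUE_CONDITIONS: tuple[str, str] = ("biased", "unbiased")

#: Display area, mm.
SCREEN_WIDTH_MM = 950.0
SCREEN_HEIGHT_MM = 550.0


@dataclass(frozen=True)
class ScreenCalibration:
    """Pixel-to-millimetre mapping, one ratio per screen axis.

    Obtained in practice by measuring the on-screen length of a 500-px
    vertical and a 500-px horizontal line.
    """

    px_per_mm_x: float
    px_per_mm_y: float

    def __post_init__(self) -> None:
        if self.px_per_mm_x <= 0 or self.px_per_mm_y <= 0:
            raise ValueError("calibration ratios must be strictly positive")

    def px_to_mm(self, xy_px) -> np.ndarray:
        xy_px = np.asarray(xy_px, dtype=float)
        return xy_px / np.array([self.px_per_mm_x, self.px_per_mm_y])

    def mm_to_px(self, xy_mm) -> np.ndarray:
        xy_mm = np.asarray(xy_mm, dtype=float)
        return xy_mm * np.array([self.px_per_mm_x, self.px_per_mm_y])


@dataclass(frozen=True)
class TrajectoryDef:
    """One experimental dot-pair movement (labels A-D)."""

    label: str
    start_dot: int
    end_dot: int
    length: float  # mm, straight-line distance between the two dots
    start_quad: str
    end_quad: str
    direction: str  # proximal-distal or distal-proximal
    side: str  # ipsi/contra with respect to the dominant (right) hand

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError("trajectory length must be positive")


#: The four experimental trajectories: dot pair, chord length (mm) and
#: quadrant/direction/side metadata.
TRAJECTORIES: dict[str, TrajectoryDef] = {
    "A": TrajectoryDef("A", 1, 5, 351.0, "bottom-right", "top-right",
                       "proximal-distal", "ipsi-ipsi"),
    "B": TrajectoryDef("B", 1, 2, 269.0, "bottom-right", "bottom-left",
                       "proximal-distal", "ipsi-contra"),
    "C": TrajectoryDef("C", 4, 6, 351.0, "top-left", "bottom-right",
                       "distal-proximal", "contra-ipsi"),
    "D": TrajectoryDef("D", 5, 3, 210.0, "top-right", "top-left",
                       "distal-proximal", "ipsi-contra"),
}

EXPERIMENTAL_PAIRS: frozenset[tuple[int, int]] = frozenset(
    (t.start_dot, t.end_dot) for t in TRAJECTORIES.values()
)


def _default_positions() -> dict[int, np.ndarray]:
    # Dot coordinates are not part of the published design; only the four
    # chord lengths and the quadrant descriptions are.  The defaults place
    # the dots so every chord is exact by construction (start + length *
    # unit direction) and every dot lands in its described quadrant, inside
    # the 950 x 550 mm display area.
    d = np.deg2rad
    dot1 = np.array([150.0, -250.0])
    dot5 = dot1 + 351.0 * np.array([np.sin(d(5)), np.cos(d(5))])
    dot2 = dot1 + 269.0 * np.array([-np.cos(d(20)), np.sin(d(20))])
    dot4 = np.array([-170.0, 180.0])
    dot6 = dot4 + 351.0 * np.array([np.sin(d(40)), -np.cos(d(40))])
    dot3 = dot5 + 210.0 * np.array([-np.cos(d(8)), -np.sin(d(8))])
    return {1: dot1, 2: dot2, 3: dot3, 4: dot4, 5: dot5, 6: dot6}


@dataclass(frozen=True)
class DotLayout:
    """Positions (mm, screen-centered) of the six target dots."""

    positions: Mapping[int, np.ndarray] = field(default_factory=_default_positions)

    def __post_init__(self) -> None:
        if sorted(self.positions) != [1, 2, 3, 4, 5, 6]:
            raise ValueError("layout must define dots 1..6 exactly")
        object.__setattr__(
            self,
            "positions",
            {k: np.asarray(v, dtype=float) for k, v in self.positions.items()},
        )

    def __getitem__(self, dot: int) -> np.ndarray:
        return self.positions[dot]

    def chord(self, a: int, b: int) -> float:
        return float(np.linalg.norm(self[a] - self[b]))

    def trajectory_direction(self, label: str) -> np.ndarray:
        """Unit vector from the trajectory's start dot to its end dot."""
        t = TRAJECTORIES[label]
        v = self[t.end_dot] - self[t.start_dot]
        return v / np.linalg.norm(v)


def rotate_point(p, theta_deg: float, origin=(0.0, 0.0)) -> np.ndarray:
    """Rotate point(s) ``p`` by ``theta_deg`` counter-clockwise about ``origin``.

    ``p`` may be a single (x, y) pair or an array of shape (..., 2).
    """
    p = np.asarray(p, dtype=float)
    origin = np.asarray(origin, dtype=float)
    th = np.deg2rad(theta_deg)
    c, s = np.cos(th), np.sin(th)
    rel = p - origin
    out = np.empty_like(rel)
    out[..., 0] = c * rel[..., 0] - s * rel[..., 1]
    out[..., 1] = s * rel[..., 0] + c * rel[..., 1]
    return out + origin


def apply_distortion(mouse_point, theta_deg: float, trial_origin) -> np.ndarray:
    """Map a mouse position to the drawn-line position.

    The line deviates from the mouse movement by the fixed angle
    ``theta_deg`` about the trial's start position; positive angles push the
    line to the right of the movement direction (clockwise in screen
    coordinates), negative to the left.  ``theta_deg = 0`` is the identity.
    """
    return rotate_point(mouse_point, -theta_deg, trial_origin)


def required_mouse_position(target, theta_deg: float, trial_origin) -> np.ndarray:
    """Mouse position whose distorted line lands exactly on ``target``.

    Inverse of :func:`apply_distortion`: compensating a distortion means
    exaggerating the mouse displacement to the opposite side.
    """
    return rotate_point(target, theta_deg, trial_origin)


def build_default_layout(config: Mapping | None = None) -> DotLayout:
    """Build the dot layout, validating the four experimental chord lengths.

    ``config`` keys (all optional):

    - ``dots``: mapping ``{dot label: (x_mm, y_mm)}`` overriding the default
      positions (echoed exactly);
    - ``chord_tolerance_mm``: tolerance for the chord check (default 1e-6);
    - ``check_chords``: disable validation for free-form layouts.

    Raises ``ValueError`` if a chord misses its nominal length by more than
    the tolerance while checking is enabled.
    """
    config = dict(config or {})
    tol = float(config.get("chord_tolerance_mm", 1e-6))
    check = bool(config.get("check_chords", True))
    if "dots" in config:
        positions = {int(k): np.asarray(v, dtype=float)
                     for k, v in config["dots"].items()}
        layout = DotLayout(positions)
    else:
        layout = DotLayout()
    if check:
        for t in TRAJECTORIES.values():
            got = layout.chord(t.start_dot, t.end_dot)
            if abs(got - t.length) > tol:
                raise ValueError(
                    f"chord {t.start_dot}-{t.end_dot} is {got:.6f} mm, "
                    f"expected {t.length} mm (trajectory {t.label})"
                )
    return layout


def load_layout_yaml(path) -> tuple[DotLayout, ScreenCalibration | None]:
    """Read a layout/calibration config block from a YAML file.

    Expected structure::

        dots: {1: [150.0, -250.0], ...}   # mm, optional
        chord_tolerance_mm: 1.0e-6        # optional
        calibration:                      # optional
          px_per_mm_x: 2.02
          px_per_mm_y: 2.04
    """
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    layout = build_default_layout(cfg)
    calib = None
    if "calibration" in cfg:
        calib = ScreenCalibration(**cfg["calibration"])
    return layout, calib
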