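"""Profile curves and significance figures.

A profile curve is, for one (trajectory, distortion, cue) cell, the per-bin
mean lateral deviation: first averaged within subject, then across
subjects, so every subject contributes equally regardless of trial or
sample counts.  Figures show one panel per distortion level with the
biased (cursor visible, red) and unbiased (cursor hidden, blue) curves and
a vertical bar spanning each significant run.  Plotted values can be
exported as CSV so figure content can be compared exactly, independent of
rendering.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import pandas as pd

from .stats import SignificanceRun

__all__ = ["build_profiles", "render_trajectory_figure"]

CUE_COLORS = {"biased": "tab:red", "unbiased": "tab:blue"}


def build_profiles(binned: pd.DataFrame) -> pd.DataFrame:
    """Per-bin mean x for every (trajectory, distortion, cue) cell.

    Means are taken over subjects of per-subject bin means.  Returns a tidy
    table with columns trajectory, distortion, cue, bin_index, mean_x, n
    (number of contributing subjects).
    """
    if binned.empty:
        raise ValueError("empty binned table")
    per_subject = (
        binned.groupby(
            ["trajectory", "distortion", "cue", "bin_index", "subject_id"],
            as_index=False,
        )["x"]
        .mean()
    )
    out = (
        per_subject.groupby(
            ["trajectory", "distortion", "cue", "bin_index"], as_index=False
        )
        .agg(mean_x=("x", "mean"), n=("subject_id", "nunique"))
        .sort_values(["trajectory", "distortion", "cue", "bin_index"])
        .reset_index(drop=True)
    )
    return out


def render_trajectory_figure(
    profiles: pd.DataFrame,
    runs: list[SignificanceRun],
    out_path,
    trajectory: str | None = None,
) -> None:
    """One panel per distortion: biased/unbiased curves + significance bars.

    ``profiles`` is the output of :func:`build_profiles` restricted (or
    restrictable via ``trajectory``) to one trajectory; ``runs`` are that
    trajectory's significant spans.  The output format follows the file
    suffix (.svg, .png, .pdf).
    """
    if trajectory is not None:
        profiles = profiles[profiles["trajectory"] == trajectory]
    trajs = profiles["trajectory"].unique()
    if len(trajs) != 1:
        raise ValueError("profiles must cover exactly one trajectory")
    traj = str(trajs[0])

    distortions = sorted(profiles["distortion"].unique())
    fig, axes = plt.subplots(
        1, len(distortions), figsize=(3.2 * len(distortions), 3.6),
        sharey=True, squeeze=False,
    )
    for ax, d in zip(axes[0], distortions):
        sub = profiles[profiles["distortion"] == d]
        for cue, g in sub.groupby("cue"):
            g = g.sort_values("bin_index")
            ax.plot(
                10 * g["bin_index"], g["mean_x"],
                color=CUE_COLORS.get(cue, "k"), label=cue,
            )
        for run in runs:
            if run.distortion == d:
                ax.axvspan(
                    10 * run.start_bin, 10 * (run.end_bin + 1),
                    color="0.2", alpha=0.15, lw=0,
                )
        ax.set_title(f"{traj}: {d:+d}\N{DEGREE SIGN}")
        ax.set_xlabel("bin (mm along movement)")
        ax.axhline(0.0, color="0.7", lw=0.6)
    axes[0][0].set_ylabel("lateral deviation x (mm)")
    axes[0][0].legend(frameon=False, fontsize=8)
    fig.suptitle(f"Trajectory {traj}: biased vs unbiased profiles")
    fig.tight_layout()
    fig.savefig(out_path)
    plt.close(fig)
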