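"""Bin-wise mixed-model analysis of lateral deviation.

For every retained 10-mm bin of a trajectory, the pooled per-mm lateral
deviations are modelled as

    x ~ cue * distortion + (1 | subject)

with cue (cursor visible/hidden) and distortion (5-level categorical) as
sum-coded fixed effects and a random intercept per subject, fit by REML.
Post hoc, the biased - unbiased marginal difference is estimated at each
distortion level with a Wald z test; p-values are Bonferroni-multiplied by
the post hoc family size (the 5 distortion levels of the bin, by default)
and then compared against a trajectory-level threshold of 0.05 divided by
the number of bins.  Contiguous spans of significant bins are reported as
runs per distortion level.

Two multiple-testing layers are therefore in force: the per-bin post hoc
family and the per-trajectory bin count.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import patsy
from scipy import stats as sps
import statsmodels.formula.api as smf

__all__ = [
    "FORMULA",
    "BinFit",
    "BinContrast",
    "SignificanceRun",
    "adjusted_alpha",
    "fit_bin_model",
    "posthoc_contrasts",
    "extract_runs",
    "analyze_trajectory",
]

FORMULA = "x ~ C(cue, Sum) * C(distortion, Sum)"


def adjusted_alpha(n_bins: int) -> float:
    """Trajectory-level Bonferroni threshold 0.05 / n_bins."""
    if n_bins < 1:
        raise ValueError("n_bins must be at least 1")
    return 0.05 / n_bins


@dataclass(frozen=True)
class BinFit:
    """Fixed-effect estimates and covariance for one bin's model."""

    params: pd.Series
    cov: pd.DataFrame
    design_info: object
    distortion_levels: tuple[int, ...]
    group_var: float | None  # random-intercept variance (None for OLS route)
    converged: bool
    singular: bool
    method: str  # "mixed" or "ols"


@dataclass(frozen=True)
class BinContrast:
    """Biased - unbiased marginal difference at one distortion level."""

    trajectory: str
    bin_index: int
    distortion: int
    estimate: float  # mm
    se: float
    p_raw: float
    p_adj: float
    significant: bool | None = None


@dataclass(frozen=True)
class SignificanceRun:
    """Maximal contiguous span of significant bins for one distortion."""

    trajectory: str
    distortion: int
    start_bin: int
    end_bin: int


def _ols_fit(df: pd.DataFrame) -> tuple[pd.Series, pd.DataFrame, object]:
    res = smf.ols(FORMULA, df).fit()
    return res.params, res.cov_params(), res.model.data.design_info


def fit_bin_model(df: pd.DataFrame, zero_variance: bool = False) -> BinFit:
    """Fit one bin's model on the pooled per-mm samples.

    Requires at least 2 subjects and both cue levels.  ``zero_variance``
    constrains the random-intercept variance to zero, which reduces the
    model to ordinary least squares on the same design.  A mixed fit that
    fails to converge falls back to the zero-variance fit with a warning;
    a boundary fit (vanishing random variance) is flagged ``singular`` but
    kept.
    """
    if df["subject_id"].nunique() < 2:
        raise ValueError("bin model needs at least 2 subjects")
    if df["cue"].nunique() < 2:
        raise ValueError("bin model needs both cue levels")
    levels = tuple(sorted(df["distortion"].unique()))

    if zero_variance:
        params, cov, dinfo = _ols_fit(df)
        return BinFit(params, cov, dinfo, levels, None, True, False, "ols")

    res = None
    converged = False
    for method in ("bfgs", "powell", "lbfgs"):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                cand = smf.mixedlm(FORMULA, df, groups=df["subject_id"]).fit(
                    reml=True, method=method
                )
        except (np.linalg.LinAlgError, ValueError):
            continue
        if cand.converged and np.isfinite(cand.fe_params).all():
            res, converged = cand, True
            break
    if res is None or not converged:
        warnings.warn("mixed fit did not converge; falling back to zero-variance fit")
        params, cov, dinfo = _ols_fit(df)
        return BinFit(params, cov, dinfo, levels, None, False, True, "ols")

    fe_names = list(res.fe_params.index)
    cov = res.cov_params().loc[fe_names, fe_names]
    group_var = float(res.cov_re.iloc[0, 0])
    singular = group_var < 1e-8
    return BinFit(
        res.fe_params, cov, res.model.data.design_info, levels,
        group_var, converged, singular, "mixed",
    )


def posthoc_contrasts(
    fit: BinFit,
    trajectory: str = "",
    bin_index: int = -1,
    n_contrasts: int | None = None,
) -> list[BinContrast]:
    """Biased - unbiased estimated marginal difference per distortion level.

    The p-value of each Wald z test is multiplied by the family size
    (default: the number of distortion levels in the bin) and capped at 1.
    """
    family = n_contrasts if n_contrasts is not None else len(fit.distortion_levels)
    out = []
    for d in fit.distortion_levels:
        frames = patsy.build_design_matrices(
            [fit.design_info],
            pd.DataFrame({"cue": ["biased", "unbiased"], "distortion": [d, d]}),
        )[0]
        rows = np.asarray(frames)
        c = rows[0] - rows[1]
        est = float(c @ fit.params.to_numpy())
        se = float(np.sqrt(c @ fit.cov.to_numpy() @ c))
        z = est / se if se > 0 else np.inf * np.sign(est)
        p = float(2.0 * sps.norm.sf(abs(z)))
        out.append(
            BinContrast(
                trajectory=trajectory,
                bin_index=bin_index,
                distortion=int(d),
                estimate=est,
                se=se,
                p_raw=p,
                p_adj=min(1.0, p * family),
            )
        )
    return out


def extract_runs(
    bin_indices, significant, trajectory: str = "", distortion: int = 0
) -> list[SignificanceRun]:
    """Maximal contiguous runs of significant bins.

    ``bin_indices`` are the bins with estimable models, in increasing
    order; a missing bin index breaks contiguity (gaps are not bridged).
    """
    runs: list[SignificanceRun] = []
    start = prev = None
    for b, sig in zip(bin_indices, significant):
        if sig and start is not None and b == prev + 1:
            prev = b
            continue
        if start is not None:
            runs.append(SignificanceRun(trajectory, distortion, start, prev))
            start = None
        if sig:
            start = prev = b
    if start is not None:
        runs.append(SignificanceRun(trajectory, distortion, start, prev))
    return runs


def analyze_trajectory(
    binned: pd.DataFrame,
    alpha: float | None = None,
    n_contrasts: int | None = None,
    zero_variance: bool = False,
) -> tuple[pd.DataFrame, list[SignificanceRun]]:
    """Fit every retained bin of one trajectory and extract significance runs.

    Returns the per-(bin, distortion) contrast table and the list of
    maximal contiguous significant runs per distortion level.  ``alpha``
    defaults to the trajectory-level Bonferroni threshold
    ``adjusted_alpha(number of bins)``.  Bins whose model is inestimable
    (single subject or single cue after exclusions) are reported missing
    and break run contiguity.
    """
    trajs = binned["trajectory"].unique()
    if len(trajs) != 1:
        raise ValueError("analyze_trajectory expects a single trajectory")
    traj = str(trajs[0])
    bins = sorted(binned["bin_index"].unique())
    if alpha is None:
        alpha = adjusted_alpha(len(bins))

    rows = []
    for b in bins:
        sub = binned[binned["bin_index"] == b]
        try:
            fit = fit_bin_model(sub, zero_variance=zero_variance)
        except ValueError as err:
            warnings.warn(f"bin {b} of trajectory {traj} inestimable: {err}")
            continue
        for con in posthoc_contrasts(fit, traj, int(b), n_contrasts):
            rows.append(
                {
                    "trajectory": con.trajectory,
                    "bin_index": con.bin_index,
                    "distortion": con.distortion,
                    "estimate": con.estimate,
                    "se": con.se,
                    "p_raw": con.p_raw,
                    "p_adj": con.p_adj,
                    "significant": con.p_adj < alpha,
                    "method": fit.method,
                    "singular": fit.singular,
                }
            )
    contrasts = pd.DataFrame(rows)

    runs: list[SignificanceRun] = []
    if not contrasts.empty:
        for d, g in contrasts.groupby("distortion"):
            g = g.sort_values("bin_index")
            runs.extend(
                extract_runs(
                    g["bin_index"].tolist(), g["significant"].tolist(), traj, int(d)
                )
            )
    return contrasts, runs
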