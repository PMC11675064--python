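"""Per-bin mixed model, post hoc contrasts and significance runs."""

import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest

import reachbias as rb
from reachbias.stats import fit_bin_model, posthoc_contrasts


def make_bin_data(rng, n_subjects=6, n_per_cell=4, noise_sd=3.0,
                  subject_sd=0.0, cell_effect=None):
    """Balanced one-bin table with known cell means.

    ``cell_effect(distortion, cue)`` gives the cell's true mean; default 0.
    """
    rows = []
    for s in range(n_subjects):
        off = rng.normal(0.0, subject_sd) if subject_sd > 0 else 0.0
        for d in rb.DISTORTION_LEVELS:
            for cue in rb.CUE_CONDITIONS:
                mu = cell_effect(d, cue) if cell_effect else 0.0
                for _ in range(n_per_cell):
                    rows.append(
                        (f"S{s}", "A", d, cue, 1,
                         mu + off + rng.normal(0.0, noise_sd))
                    )
    return pd.DataFrame(
        rows, columns=["subject_id", "trajectory", "distortion", "cue",
                       "bin_index", "x"]
    )


def cell_mean_oracle(df, d):
    """Observed biased - unbiased mean difference at one distortion level."""
    sub = df[df.distortion == d]
    return (sub.loc[sub.cue == "biased", "x"].mean()
            - sub.loc[sub.cue == "unbiased", "x"].mean())


class TestAdjustedAlpha:
    def test_34_bins(self):
        assert rb.adjusted_alpha(34) == pytest.approx(0.00147, abs=5e-6)

    def test_20_bins(self):
        assert rb.adjusted_alpha(20) == pytest.approx(0.0025)

    def test_single_bin(self):
        assert rb.adjusted_alpha(1) == 0.05

    def test_invalid(self):
        with pytest.raises(ValueError):
            rb.adjusted_alpha(0)


class TestBinModel:
    def test_contrasts_match_cell_mean_oracle_zero_variance(self):
        rng = np.random.default_rng(10)
        effect = lambda d, cue: (2.0 if cue == "biased" else 0.0) * (d / 10.0)
        df = make_bin_data(rng, cell_effect=effect)
        fit = fit_bin_model(df, zero_variance=True)
        for con in posthoc_contrasts(fit):
            assert con.estimate == pytest.approx(
                cell_mean_oracle(df, con.distortion), abs=1e-6
            )

    def test_mixed_fit_matches_oracle_on_balanced_design(self):
        # with a balanced design the fixed effects are orthogonal to the
        # random intercept, so the mixed estimates equal the cell means too
        rng = np.random.default_rng(11)
        df = make_bin_data(rng, subject_sd=2.0)
        fit = fit_bin_model(df)
        assert fit.method == "mixed"
        for con in posthoc_contrasts(fit):
            assert con.estimate == pytest.approx(
                cell_mean_oracle(df, con.distortion), abs=1e-6
            )

    def test_random_intercept_sd_recovered(self):
        rng = np.random.default_rng(12)
        df = make_bin_data(rng, n_subjects=40, subject_sd=2.0)
        fit = fit_bin_model(df)
        assert fit.group_var is not None
        assert 1.5 <= np.sqrt(fit.group_var) <= 2.5

    def test_cue_swap_flips_estimates(self):
        rng = np.random.default_rng(13)
        effect = lambda d, cue: 1.5 if cue == "biased" else 0.0
        df = make_bin_data(rng, cell_effect=effect)
        swapped = df.assign(
            cue=df.cue.map({"biased": "unbiased", "unbiased": "biased"})
        )
        a = {c.distortion: c.estimate
             for c in posthoc_contrasts(fit_bin_model(df, zero_variance=True))}
        b = {c.distortion: c.estimate
             for c in posthoc_contrasts(fit_bin_model(swapped, zero_variance=True))}
        for d in a:
            assert b[d] == pytest.approx(-a[d], abs=1e-9)

    def test_single_subject_raises(self):
        rng = np.random.default_rng(14)
        df = make_bin_data(rng, n_subjects=1)
        with pytest.raises(ValueError, match="subjects"):
            fit_bin_model(df)

    def test_single_cue_raises(self):
        rng = np.random.default_rng(15)
        df = make_bin_data(rng)
        with pytest.raises(ValueError, match="cue"):
            fit_bin_model(df[df.cue == "biased"])


class TestAgainstLme4:
    def test_contrasts_match_lme4_emmeans(self, tmp_path):
        """Cross-validation against the R reference stack: lme4 REML fit
        plus emmeans cue contrasts per distortion on the same table."""
        rng = np.random.default_rng(31)
        effect = lambda d, cue: (1.5 if cue == "biased" else 0.0) * abs(d) / 10
        df = make_bin_data(rng, n_subjects=8, subject_sd=2.0,
                           cell_effect=effect)
        csv = tmp_path / "bin.csv"
        df.to_csv(csv, index=False)
        out = tmp_path / "r_contrasts.csv"
        script = tmp_path / "fit.R"
        script.write_text(textwrap.dedent(f"""
            suppressMessages({{library(lme4); library(emmeans)}})
            d <- read.csv("{csv}")
            d$cue <- factor(d$cue); d$distortion <- factor(d$distortion)
            m <- lmer(x ~ cue*distortion + (1|subject_id), data=d, REML=TRUE)
            con <- as.data.frame(pairs(emmeans(m, ~ cue | distortion),
                                       adjust="none"))
            write.csv(con, "{out}", row.names=FALSE)
        """))
        subprocess.run(["Rscript", str(script)], check=True,
                       capture_output=True)
        ref = pd.read_csv(out).set_index("distortion")

        fit = fit_bin_model(df)
        assert fit.method == "mixed"
        for con in posthoc_contrasts(fit, n_contrasts=1):
            row = ref.loc[con.distortion]
            assert con.estimate == pytest.approx(row["estimate"], abs=1e-3)
            assert con.se == pytest.approx(row["SE"], abs=1e-3)


class TestPosthocAdjustment:
    def test_single_contrast_unadjusted(self):
        rng = np.random.default_rng(16)
        fit = fit_bin_model(make_bin_data(rng), zero_variance=True)
        for one, five in zip(posthoc_contrasts(fit, n_contrasts=1),
                             posthoc_contrasts(fit, n_contrasts=5)):
            assert one.p_adj == pytest.approx(one.p_raw)
            assert five.p_adj == pytest.approx(min(1.0, one.p_raw * 5))

    def test_adjusted_p_capped_at_one(self):
        rng = np.random.default_rng(17)
        fit = fit_bin_model(make_bin_data(rng), zero_variance=True)
        cons = posthoc_contrasts(fit, n_contrasts=1000)
        assert all(c.p_adj <= 1.0 for c in cons)
        assert any(c.p_adj == 1.0 for c in cons)


class TestRuns:
    def test_run_extraction_from_p_sequence(self):
        alpha = 0.0025
        ps = [0.5, 1e-5, 1e-5, 0.2, 1e-5]
        runs = rb.extract_runs(range(1, 6), [p < alpha for p in ps])
        assert [(r.start_bin, r.end_bin) for r in runs] == [(2, 3), (5, 5)]

    def test_gap_in_bins_breaks_run(self):
        runs = rb.extract_runs([1, 2, 4], [True, True, True])
        assert [(r.start_bin, r.end_bin) for r in runs] == [(1, 2), (4, 4)]

    def test_no_significance_no_runs(self):
        assert rb.extract_runs([1, 2, 3], [False, False, False]) == []


class TestAnalyzeTrajectory:
    def test_detected_runs_grow_with_bias_weight(self):
        """Power monotonicity: significant-bin count for distorted trials is
        non-decreasing in the simulated cursor-bias weight."""
        totals = []
        for i, w in enumerate((0.0, 0.25, 0.5)):
            pop = rb.PopulationParams(cursor_bias_w=(w, w))
            recs = rb.simulate_experiment(
                6, population=pop, seed=21, simulate_fillers=False
            )
            binned = rb.preprocess_records(recs)
            con, runs = rb.analyze_trajectory(
                binned[binned.trajectory == "D"]
            )
            sig = con[(con.distortion != 0) & con.significant]
            totals.append(len(sig))
        assert totals[0] <= totals[1] <= totals[2]
        assert totals[2] > totals[0]

    def test_effect_direction_recovered(self, small_binned):
        """Cursor-visible trials deviate more: positive biased - unbiased
        estimates and long runs late in the movement for distorted trials."""
        con, runs = rb.analyze_trajectory(
            small_binned[small_binned.trajectory == "A"]
        )
        n_bins = con.bin_index.max()
        late = con[(con.bin_index > 2 * n_bins / 3) & (con.distortion != 0)]
        assert (late.estimate > 0).all()
        for d in (-20, -10, 10, 20):
            assert any(
                r.distortion == d and r.end_bin > 2 * n_bins / 3 for r in runs
            )

    def test_mixed_trajectories_rejected(self, small_binned):
        with pytest.raises(ValueError, match="single trajectory"):
            rb.analyze_trajectory(small_binned)
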