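import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest

from erpmix import RandomStructure, SingleTrialLMM


def balanced_data(
    n_part=6,
    n_stim=8,
    reps=4,
    cell_means=None,
    sd_part=1.0,
    sd_stim=0.5,
    sd_resid=1.0,
    sd_part_slope=0.0,
    seed=0,
):
    """Balanced two-factor (duration x category) synthetic amplitude table
    with crossed participant/stimulus intercepts and optional by-participant
    duration slopes."""
    if cell_means is None:
        cell_means = {(33, "face"): -3.0, (216, "face"): -4.0,
                      (33, "house"): -1.0, (216, "house"): -1.2}
    rng = np.random.default_rng(seed)
    up = rng.normal(0, sd_part, n_part)
    us = rng.normal(0, sd_stim, n_stim)
    slope = rng.normal(0, sd_part_slope, n_part)
    rows = []
    for p in range(n_part):
        for s in range(n_stim):
            for (dur, cat), mu in cell_means.items():
                for _ in range(reps):
                    y = (
                        mu
                        + up[p]
                        + us[s]
                        + slope[p] * (1 if dur == 33 else -1)
                        + rng.normal(0, sd_resid)
                    )
                    rows.append((p + 1, s + 1, dur, cat, y))
    return pd.DataFrame(
        rows,
        columns=["participant_id", "stimulus_id", "duration", "category", "mean_amplitude"],
    )


@pytest.fixture(scope="module")
def fitted_balanced():
    data = balanced_data(seed=3)
    model = SingleTrialLMM(data, factors=("duration", "category"))
    return data, model.fit()


class TestCellMeanRecovery:
    def test_emmeans_match_raw_cell_means(self, fitted_balanced):
        """On balanced data with intercept-only random effects the model
        cell means coincide with the raw condition means (GLS = cell-mean
        estimator on a balanced crossed design)."""
        data, res = fitted_balanced
        em = res.emmeans(["duration", "category"])
        raw = data.groupby(["duration", "category"])["mean_amplitude"].mean()
        for _, row in em.iterrows():
            assert row["emmean"] == pytest.approx(
                raw[(row["duration"], row["category"])], abs=1e-6
            )

    def test_grand_mean_when_no_factors_requested(self, fitted_balanced):
        data, res = fitted_balanced
        em = res.emmeans([])
        assert len(em) == 1
        assert em["emmean"].iloc[0] == pytest.approx(
            data["mean_amplitude"].mean(), abs=1e-6
        )

    def test_averaging_over_balanced_factor_preserves_mean(self, fitted_balanced):
        data, res = fitted_balanced
        by_dur = res.emmeans(["duration"])
        full = res.emmeans(["duration", "category"])
        for _, row in by_dur.iterrows():
            cells = full[full["duration"] == row["duration"]]["emmean"]
            assert row["emmean"] == pytest.approx(cells.mean(), abs=1e-10)

    def test_unknown_factor_rejected(self, fitted_balanced):
        _, res = fitted_balanced
        with pytest.raises(ValueError):
            res.emmeans(["hemisphere"])


class TestLadder:
    def test_intercept_only_truth_recovered(self):
        """With zero slope variance in truth, the requested by-participant
        slope term is dropped (or estimated at ~0)."""
        data = balanced_data(sd_part_slope=0.0, seed=4)
        model = SingleTrialLMM(
            data,
            factors=("duration", "category"),
            random=RandomStructure(participant_slopes=("duration",)),
        )
        res = model.fit()
        slope_terms = [t for t in res.random_terms if "participant_x" in t]
        if slope_terms:
            assert res.vcomp[slope_terms[0]] < 0.05 * res.scale
        rungs = [r.name for r in res.ladder_trace]
        assert rungs[0] == "maximal" and rungs[-1] == "optimal"

    def test_genuine_intercepts_retained(self):
        data = balanced_data(sd_part=1.5, sd_stim=1.0, seed=5)
        res = SingleTrialLMM(data, factors=("duration",)).fit()
        assert set(res.random_terms) == {"participant", "stimulus"}
        assert res.vcomp["participant"] > 0.5
        # short-circuit: the maximal model survived as the optimal one
        assert res.ladder_trace[-1].terms == res.ladder_trace[0].terms

    def test_every_rung_logged(self):
        data = balanced_data(seed=6)
        res = SingleTrialLMM(data, factors=("duration",)).fit()
        names = [r.name for r in res.ladder_trace]
        assert "maximal" in names and "reduced/extended" in names and "optimal" in names
        assert all(isinstance(r.converged, bool) for r in res.ladder_trace)

    def test_degenerate_inputs_rejected(self):
        data = balanced_data(n_part=1)
        with pytest.raises(ValueError, match="participants"):
            SingleTrialLMM(data, factors=("duration",))
        data2 = balanced_data()
        data2["duration"] = 33
        with pytest.raises(ValueError, match="degenerate"):
            SingleTrialLMM(data2, factors=("duration",))


class TestContrasts:
    def test_pairwise_of_identical_cells_is_null(self):
        cm = {(33, "face"): -2.0, (216, "face"): -2.0,
              (33, "house"): -2.0, (216, "house"): -2.0}
        data = balanced_data(cell_means=cm, sd_part=0.2, sd_stim=0.1, seed=7)
        res = SingleTrialLMM(data, factors=("duration", "category")).fit()
        c = res.pairwise("duration", family=1)[0]
        assert abs(c.b) < 0.2
        assert c.p_nhst > 0.05

    def test_reported_t_is_b_over_se(self, fitted_balanced):
        _, res = fitted_balanced
        c = res.pairwise("duration", by=("category",), family=2)[0]
        assert c.t == pytest.approx(c.b / c.se)

    def test_family_mismatch_signaled(self):
        data = balanced_data(seed=8)
        data["four"] = np.tile(["a", "b", "c", "d"], len(data) // 4)
        res = SingleTrialLMM(data, factors=("four",)).fit()
        with pytest.raises(ValueError, match="family"):
            res.pairwise("four", family=3)

    def test_interaction_contrast_arithmetic(self):
        """Cells (face33, face216, house33, house216) = (1, 2, 3, 7) give
        the difference-of-differences (1-2) - (3-7) = ... laid out as
        (33 faces - 33 houses) - (216 faces - 216 houses) = (1-3)-(2-7) = 3."""
        cm = {(33, "face"): 1.0, (216, "face"): 2.0,
              (33, "house"): 3.0, (216, "house"): 7.0}
        data = balanced_data(
            cell_means=cm, sd_part=0.0, sd_stim=0.0, sd_resid=0.01, seed=9
        )
        res = SingleTrialLMM(data, factors=("duration", "category")).fit()
        c = res.interaction_contrasts("category", "duration", family=1)[0]
        # (face-house at 33) - (face-house at 216) = (1-3) - (2-7) = 3
        assert c.b == pytest.approx(3.0, abs=0.05)

    def test_additive_cells_have_no_interaction(self):
        cm = {(33, "face"): 1.0, (216, "face"): 2.0,
              (33, "house"): 3.0, (216, "house"): 4.0}
        data = balanced_data(
            cell_means=cm, sd_part=0.1, sd_stim=0.1, sd_resid=0.2, seed=10
        )
        res = SingleTrialLMM(data, factors=("duration", "category")).fit()
        c = res.interaction_contrasts("category", "duration", family=1)[0]
        assert abs(c.b) < 3 * c.se

    def test_se_shrinks_with_sample_size(self):
        """Contrast SEs scale roughly as 1/sqrt(n_trials)."""
        ses = {}
        for reps in (2, 8, 32):
            data = balanced_data(reps=reps, sd_part=0.3, sd_stim=0.2, seed=11)
            res = SingleTrialLMM(data, factors=("duration",)).fit()
            ses[reps] = res.pairwise("duration", family=1)[0].se
        assert ses[8] == pytest.approx(ses[2] / 2, rel=0.35)
        assert ses[32] == pytest.approx(ses[8] / 2, rel=0.35)

    def test_summary_mentions_ladder_and_variances(self, fitted_balanced):
        _, res = fitted_balanced
        s = res.summary()
        assert "variance components" in s and "ladder" in s and "residual" in s


class TestVarianceRecovery:
    def test_crossed_variance_components_recovered(self):
        """Simulating known participant/stimulus intercept SDs, the fitted
        variance components land in a broad interval around the truth."""
        data = balanced_data(
            n_part=20, n_stim=12, reps=6, sd_part=1.0, sd_stim=0.6, seed=12
        )
        res = SingleTrialLMM(data, factors=("duration", "category")).fit()
        assert 0.3 < res.vcomp["participant"] < 3.0   # truth 1.0
        assert 0.1 < res.vcomp["stimulus"] < 1.2      # truth 0.36
        assert 0.7 < res.scale < 1.4                  # truth 1.0


class TestAgainstLme4:
    def test_fixed_effects_match_lme4(self, tmp_path):
        """Independent cross-check: lme4 fits the same crossed-intercept
        model; fixed effects and SEs must agree."""
        data = balanced_data(n_part=5, n_stim=6, reps=2, seed=13)
        csv = tmp_path / "d.csv"
        data.to_csv(csv, index=False)
        rscript = textwrap.dedent(f"""
            suppressMessages(library(lme4))
            d <- read.csv("{csv}")
            d$duration <- factor(d$duration); contrasts(d$duration) <- contr.sum(2)
            d$category <- factor(d$category); contrasts(d$category) <- contr.sum(2)
            m <- lmer(mean_amplitude ~ duration * category +
                      (1 | participant_id) + (1 | stimulus_id), data = d, REML = TRUE)
            cat(fixef(m), sep = "\\n")
            cat(sqrt(diag(vcov(m))), sep = "\\n")
        """)
        out = subprocess.run(
            ["Rscript", "-e", rscript], capture_output=True, text=True, timeout=300
        )
        assert out.returncode == 0, out.stderr
        vals = [float(x) for x in out.stdout.split()]
        fe_r, se_r = np.array(vals[:4]), np.array(vals[4:8])

        res = SingleTrialLMM(data, factors=("duration", "category")).fit()
        fe_py = res.fe_params
        se_py = np.sqrt(np.diag(res.cov_fe))
        # orders: patsy sum coding sorts levels the same way as contr.sum on
        # sorted factor levels; compare as sorted magnitude sets to stay
        # robust to sign conventions of the coding
        assert np.allclose(np.sort(np.abs(fe_py)), np.sort(np.abs(fe_r)), atol=2e-3)
        assert np.allclose(np.sort(se_py), np.sort(se_r), rtol=0.05)
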