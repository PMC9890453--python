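import numpy as np
import pandas as pd
import pytest

from erpmix import GenerativeParams, assign_responses, render_epochs, simulate_trials
from erpmix.design import DURATION_LONG, DURATION_SHORT
from erpmix.simulate import gaussian_template, template_window_mean

from conftest import make_face_design


def certain_detection(p: float) -> dict:
    return {
        ("face", DURATION_SHORT): p,
        ("face", DURATION_LONG): p,
        ("house", DURATION_SHORT): p,
        ("house", DURATION_LONG): p,
    }


class TestDetectionGating:
    def test_detected_trials_carry_full_amplitude(self, tiny_design, quiet_params):
        """All-or-none with certain detection: the face-specific increment is
        the full amplitude on every intact-face trial, at either duration."""
        params = GenerativeParams(
            **{**quiet_params.__dict__, "p_detect": certain_detection(1.0)}
        )
        t = simulate_trials(tiny_design, params, seed=0)
        faces = t[(t["type"] == "intact") & (t["category"] == "face")]
        assert (faces["eff_amp_n170"] == params.a_n170_full).all()
        by_dur = faces.groupby("duration")["eff_amp_n170"].mean()
        assert by_dur[DURATION_SHORT] == by_dur[DURATION_LONG]

    def test_undetected_trials_carry_nothing(self, tiny_design, quiet_params):
        params = GenerativeParams(
            **{**quiet_params.__dict__, "p_detect": certain_detection(0.0)}
        )
        t = simulate_trials(tiny_design, params, seed=0)
        assert (t["eff_amp_n170"] == 0.0).all()

    def test_scrambled_trials_never_carry_category_component(self, simulated_trials):
        scr = simulated_trials[simulated_trials["type"] == "scrambled"]
        assert (scr["eff_amp_n170"] == 0.0).all()
        assert (scr["detected"] == 0).all()

    def test_dilution_law(self):
        """Averaging over detected and missed trials dilutes the mean
        face-specific amplitude to p_detect times the full response."""
        p = 0.47
        n = 10_000
        design = make_face_design(n)
        params = GenerativeParams(p_detect=certain_detection(p))
        t = simulate_trials(design, params, seed=123)
        amp = t["eff_amp_n170"].to_numpy()
        mc_se = amp.std(ddof=1) / np.sqrt(n)
        assert abs(amp.mean() - p * params.a_n170_full) < 3 * mc_se

    def test_conditioning_on_detection_removes_duration_effect(self, quiet_params):
        """All-or-none: given detection, amplitude is duration-independent."""
        d = pd.concat(
            [make_face_design(2000, duration=DURATION_SHORT),
             make_face_design(2000, duration=DURATION_LONG)],
            ignore_index=True,
        )
        params = GenerativeParams(**{**quiet_params.__dict__})
        t = simulate_trials(d, params, seed=5)
        det = t[t["detected"] == 1]
        means = det.groupby("duration")["eff_amp_n170"].mean()
        assert means[DURATION_SHORT] == pytest.approx(means[DURATION_LONG])

    def test_graded_signature(self, quiet_params):
        """Graded: even high-confidence trials keep the scaled response, so
        the duration gap equals (1 - g(33)) * full amplitude."""
        g33 = 0.6
        d = pd.concat(
            [make_face_design(4000, duration=DURATION_SHORT),
             make_face_design(4000, duration=DURATION_LONG)],
            ignore_index=True,
        )
        params = GenerativeParams(
            **{
                **quiet_params.__dict__,
                "hypothesis": "graded",
                "g": {DURATION_SHORT: g33, DURATION_LONG: 1.0},
            }
        )
        t = simulate_trials(d, params, seed=6)
        high = t[t["response_key"] == 1]
        gap = (
            high.loc[high["duration"] == DURATION_LONG, "eff_amp_n170"].mean()
            - high.loc[high["duration"] == DURATION_SHORT, "eff_amp_n170"].mean()
        )
        assert gap == pytest.approx((1 - g33) * params.a_n170_full)


class TestDeterminismAndEquivalence:
    def test_identical_seeds_bit_identical(self, tiny_design):
        params = GenerativeParams.all_or_none_preset()
        a = simulate_trials(tiny_design, params, seed=42)
        b = simulate_trials(tiny_design, params, seed=42)
        pd.testing.assert_frame_equal(a, b)

    def test_graded_at_unit_gain_equals_certain_detection(self, tiny_design):
        """g = 1 graded and p_detect = 1 all-or-none are the same process."""
        aon = GenerativeParams(p_detect=certain_detection(1.0))
        grd = GenerativeParams(hypothesis="graded")
        a = simulate_trials(tiny_design, aon, seed=9)
        b = simulate_trials(tiny_design, grd, seed=9)
        pd.testing.assert_frame_equal(
            a.drop(columns="detected"), b.drop(columns="detected")
        )

    def test_invalid_hypothesis_rejected(self):
        with pytest.raises(ValueError):
            GenerativeParams(hypothesis="both")


class TestResponses:
    def test_sure_evidence_maps_to_extreme_keys(self):
        keys = assign_responses(np.array([5.0, 1.0, 0.0, -1.0, -5.0]), 0.6, 1.8)
        assert keys.tolist() == [1, 2, 3, 4, 5]

    def test_infinite_thresholds_give_all_guesses(self):
        keys = assign_responses(np.array([-100.0, 0.0, 100.0]), np.inf, np.inf)
        assert (keys == 3).all()

    def test_non_monotone_thresholds_rejected(self):
        with pytest.raises(ValueError):
            assign_responses(np.zeros(3), 2.0, 1.0)

    def test_key_assignment_monotone_in_evidence(self):
        e = np.linspace(-6, 6, 1001)
        keys = assign_responses(e, 0.6, 1.8)
        assert (np.diff(keys) <= 0).all()

    def test_calibrated_key1_share(self):
        """The preset's Key-1 share for 33 ms intact faces falls inside the
        reported group CI [0.346, 0.591] around M = 0.469."""
        design = make_face_design(20_000)
        t = simulate_trials(design, GenerativeParams.all_or_none_preset(), seed=77)
        share = (t["response_key"] == 1).mean()
        assert 0.346 < share < 0.591
        assert share == pytest.approx(0.469, abs=0.05)


class TestRenderEpochs:
    def test_zero_amplitude_zero_noise_gives_zero_epoch(self, quiet_params):
        d = make_face_design(3)
        params = GenerativeParams(
            **{
                **quiet_params.__dict__,
                "a_p1": 0.0,
                "a_n1_base": 0.0,
                "p_detect": certain_detection(0.0),
            }
        )
        t = simulate_trials(d, params, seed=0)
        es = render_epochs(t, params, seed=0)
        assert np.allclose(es.data, 0.0)

    def test_window_mean_matches_template_quadrature(self, quiet_params):
        """Noiseless detected trial: the 152-192 ms window mean equals the
        trial amplitude times the template mean, computed here by direct
        numerical evaluation of the Gaussian."""
        from erpmix import mean_amplitude

        d = make_face_design(1)
        params = GenerativeParams(
            **{
                **quiet_params.__dict__,
                "a_p1": 0.0,
                "a_n1_base": 0.0,
                "right_gain": 1.0,
                "p_detect": certain_detection(1.0),
            }
        )
        t = simulate_trials(d, params, seed=0)
        es = render_epochs(t, params, seed=0)
        table = mean_amplitude(es, 152.0, 192.0, "N170")

        # independent quadrature over the exact sample grid
        grid = np.arange(152.0, 192.0 + 1e-9, 4.0)
        expected = -params.a_n170_full * np.mean(
            np.exp(-0.5 * ((grid - params.n170_center) / params.n170_sd) ** 2)
        )
        assert table["mean_amplitude"].to_numpy() == pytest.approx(expected, rel=1e-12)

    def test_half2_gain_shifts_window_mean_linearly(self, quiet_params):
        from erpmix import mean_amplitude

        d1 = make_face_design(1, half=1)
        d2 = make_face_design(1, half=2)
        params = GenerativeParams(
            **{
                **quiet_params.__dict__,
                "a_p1": 0.0,
                "right_gain": 1.0,
                "p_detect": certain_detection(1.0),
            }
        )
        es1 = render_epochs(simulate_trials(d1, params, seed=0), params, seed=0)
        es2 = render_epochs(simulate_trials(d2, params, seed=0), params, seed=0)
        m1 = mean_amplitude(es1, 152.0, 192.0, "N170")["mean_amplitude"].iloc[0]
        m2 = mean_amplitude(es2, 152.0, 192.0, "N170")["mean_amplitude"].iloc[0]
        tmean = template_window_mean(params.n170_center, params.n170_sd, 152.0, 192.0)
        assert m1 - m2 == pytest.approx(params.half2_gain * tmean, rel=1e-9)

    def test_template_outside_epoch_rejected(self, quiet_params):
        d = make_face_design(1)
        params = GenerativeParams(
            **{**quiet_params.__dict__, "n170_center": 950.0}
        )
        t = simulate_trials(d, params, seed=0)
        with pytest.raises(ValueError, match="support"):
            render_epochs(t, params, seed=0)

    def test_empty_trial_list_rejected(self, quiet_params):
        with pytest.raises(ValueError):
            render_epochs(pd.DataFrame(columns=["amp_n1"]), quiet_params, seed=0)

    def test_epoch_grid_spans_1500_ms(self, quiet_params):
        times = quiet_params.times()
        assert times[0] == -500.0 and times[-1] == 996.0
        assert len(times) == 375
        assert times[-1] - times[0] + 4.0 == 1500.0


def test_epochset_roundtrip(tmp_path, quiet_params):
    d = make_face_design(2)
    t = simulate_trials(d, quiet_params, seed=0)
    es = render_epochs(t, quiet_params, seed=1)
    es.save(tmp_path / "ep")
    from erpmix import EpochSet

    back = EpochSet.load(tmp_path / "ep")
    assert np.array_equal(back.data, es.data)
    assert back.channels == es.channels
    assert len(back.metadata) == len(es.metadata)
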