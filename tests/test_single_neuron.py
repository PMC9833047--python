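"""Tests of the feedforward single-neuron experiment machinery."""

import numpy as np
import pytest

from infomaxstdp.params import PlasticityParams
from infomaxstdp.single_neuron import (
    FeedforwardConfig,
    PairingProtocol,
    StdpCurve,
    calibrate_lambda,
    estimate_mean_intensity,
    measure_stdp_curve,
    run_pairing_trial,
    run_pairing_trials,
)


class TestProtocolValidation:
    @pytest.mark.parametrize("kind, delta_t", [
        ("pre-post", None), ("pre-post", -5.0), ("post-pre", 5.0),
        ("post-pre", None), ("pre-only", 10.0), ("bogus", None),
    ])
    def test_inconsistent_protocols_rejected(self, kind, delta_t):
        with pytest.raises(ValueError):
            PairingProtocol(kind=kind, delta_t=delta_t)

    def test_bad_config_rejected(self):
        with pytest.raises(ValueError):
            FeedforwardConfig(n_stim=0)
        with pytest.raises(ValueError):
            FeedforwardConfig(background_rate_down=-0.1)

    def test_sem_requires_two_trials(self, ff_config, plasticity, rng):
        with pytest.raises(ValueError):
            measure_stdp_curve(ff_config, [10.0], plasticity, "down", rng,
                               n_trials=1, g_bar=0.5)

    def test_zero_offset_rejected(self, ff_config, plasticity, rng):
        with pytest.raises(ValueError):
            measure_stdp_curve(ff_config, [0.0], plasticity, "down", rng,
                               n_trials=10, g_bar=0.5)


class TestMeanIntensity:
    def test_up_down_calibration(self, ff_config, rng):
        """Background-only runs recover the states' mean intensities:
        ~5.9 Hz up, ~0.5 Hz down (convexity lifts them slightly above
        the intensity at the mean potential)."""
        up = estimate_mean_intensity(ff_config, "up", rng, duration=3e5)
        down = estimate_mean_intensity(ff_config, "down", rng, duration=3e5)
        assert up.g_bar == pytest.approx(5.9, rel=0.1)
        assert down.g_bar == pytest.approx(0.5, rel=0.15)
        assert up.mode == "fixed-per-state"

    def test_deterministic_given_seed(self, ff_config):
        a = estimate_mean_intensity(ff_config, "up", np.random.default_rng(7),
                                    duration=5e4)
        b = estimate_mean_intensity(ff_config, "up", np.random.default_rng(7),
                                    duration=5e4)
        assert a.g_bar == b.g_bar


class TestPairingTrials:
    def test_shape_and_single_trial(self, ff_config, plasticity, rng):
        protocol = PairingProtocol(kind="pre-post", delta_t=10.0, n_trials=7,
                                   state="down")
        dw = run_pairing_trials(ff_config, protocol, plasticity, rng, g_bar=0.5)
        assert dw.shape == (7, ff_config.n_stim)
        single = run_pairing_trial(ff_config, protocol, plasticity, rng,
                                   g_bar=0.5)
        assert single.shape == (ff_config.n_stim,)

    def test_forced_post_outside_window_rejected(self, ff_config, plasticity, rng):
        protocol = PairingProtocol(kind="pre-post", delta_t=400.0, n_trials=2,
                                   state="down")
        with pytest.raises(ValueError):
            run_pairing_trials(ff_config, protocol, plasticity, rng, g_bar=0.5,
                               trial_length=500.0, stim_time=250.0)

    def test_prepost_potentiates_more_in_down_state(self, ff_config, rng):
        """Pre-post pairing: the information term potentiates more at a
        low mean intensity than at a high one (the depression bias)."""
        info_only = PlasticityParams(lam=0.0)
        n = 800
        down = run_pairing_trials(
            ff_config, PairingProtocol("pre-post", 10.0, n, "down"),
            info_only, np.random.default_rng(1), g_bar=0.51).mean()
        up = run_pairing_trials(
            ff_config, PairingProtocol("pre-post", 10.0, n, "up"),
            info_only, np.random.default_rng(2), g_bar=5.94).mean()
        assert down > up > 0

    def test_postpre_depresses_both_states(self, ff_config, plasticity):
        """Post-pre pairing at -10 ms: refractory suppression blocks the
        information term while the cost still collects, so the weight
        falls in both states."""
        n = 600
        for state, g_bar, seed in (("down", 0.51, 3), ("up", 5.94, 4)):
            dw = run_pairing_trials(
                ff_config, PairingProtocol("post-pre", -10.0, n, state),
                plasticity, np.random.default_rng(seed), g_bar=g_bar)
            per_trial = dw.mean(axis=1)
            sem = per_trial.std(ddof=1) / np.sqrt(n)
            assert per_trial.mean() < -2 * sem


class TestCalibrateLambda:
    def test_no_bracket_sign_change_raises(self, ff_config, plasticity):
        with pytest.raises(ValueError, match="sign change"):
            calibrate_lambda(ff_config, plasticity, seed=3, n_trials=200,
                             bracket=(5.0, 10.0), g_bar=0.51)

    def test_small_calibration_near_printed_value(self, ff_config, plasticity):
        """A reduced-trial calibration lands in the neighbourhood of the
        default cost coefficient 0.32 (the acceptance run uses 10^4
        trials; this smoke run uses 1500)."""
        lam = calibrate_lambda(ff_config, plasticity, seed=11, n_trials=1500,
                               g_bar=0.513)
        assert 0.15 < lam < 0.6


class TestStdpCurve:
    def test_curve_converges_to_pre_only_and_orders_states(self, ff_config,
                                                           plasticity):
        """Large |dt| converges to the pre-only level; the up-state curve
        lies at or below the down-state curve at matched offsets."""
        offsets = [-150.0, 10.0, 150.0]
        n = 500
        curves = {}
        for state, g_bar, seed in (("down", 0.51, 5), ("up", 5.94, 6)):
            curves[state] = measure_stdp_curve(
                ff_config, offsets, plasticity, state,
                np.random.default_rng(seed), n_trials=n, g_bar=g_bar)
        for state, curve in curves.items():
            for i in (0, 2):  # +/-150 ms: beyond the eligibility window
                gap = abs(curve.mean_dw[i] - curve.pre_only_mean)
                tol = 3 * np.hypot(curve.sem_dw[i], curve.pre_only_sem)
                assert gap < tol, (state, offsets[i])
        # depression bias at the pairing offset
        assert curves["up"].mean_dw[1] < curves["down"].mean_dw[1]

    def test_sem_validation(self):
        with pytest.raises(ValueError):
            StdpCurve(offsets=np.array([10.0]), mean_dw=np.array([0.0]),
                      sem_dw=np.array([-1.0]), pre_only_mean=0.0,
                      pre_only_sem=0.0, state="down")
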