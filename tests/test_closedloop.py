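"""Closed-loop simulator: pulse safety envelope, detection rule, recovery
law, session causality and determinism."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vasotone import (
    ControllerParams,
    GenConfig,
    HealthyReference,
    SafetyError,
    make_pulse_train,
    detect_dysfunction,
    run_closed_loop,
    vascular_response,
)
from vasotone.closedloop import stimulation_gamma


REF = HealthyReference(mean_power=312.5)


def loop_cfg(noise_rms=0.0, seed=0):
    return GenConfig(n_channels=1, fs=1000.0, duration=60.0,
                     noise_rms=noise_rms, mains_amp=0.0, seed=seed)


class TestPulseTrain:
    def test_default_charge_per_phase(self):
        p = make_pulse_train(300.0, 100.0)
        assert p.charge_per_phase_nC == pytest.approx(30.0)
        assert p.net_charge_nC == 0.0

    def test_hard_limit_rejected(self):
        with pytest.raises(SafetyError):
            make_pulse_train(600.0)

    def test_override_band_requires_flag(self):
        with pytest.raises(SafetyError):
            make_pulse_train(400.0)
        p = make_pulse_train(400.0, allow_high=True)
        assert p.amplitude == 400.0

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        amp=st.floats(min_value=1.0, max_value=300.0),
        width=st.floats(min_value=10.0, max_value=500.0),
    )
    def test_any_accepted_train_is_charge_balanced(self, amp, width):
        p = make_pulse_train(amp, width, n_pulses=5, rate=50.0)
        wf = p.waveform(fs=1_000_000.0)
        assert np.sum(wf) == pytest.approx(0.0, abs=1e-9)
        assert p.charge_per_phase_nC == pytest.approx(amp * width * 1e-3)

    def test_cathodal_first(self):
        wf = make_pulse_train(300.0, 100.0, n_pulses=1).waveform(fs=100000.0)
        first = wf[np.flatnonzero(wf)[0]]
        assert first < 0


class TestDetection:
    def test_at_reference_not_dysfunctional(self):
        assert detect_dysfunction(REF.mean_power, REF) is False

    def test_deep_deficit_detected(self):
        assert detect_dysfunction(0.3 * REF.mean_power, REF) is True

    def test_exact_threshold_is_strict(self):
        assert detect_dysfunction(0.5 * REF.mean_power, REF, theta=0.5) is False


class TestResponseLaw:
    def test_reference_is_fixed_point(self):
        p = make_pulse_train()
        assert vascular_response(REF.mean_power, REF, p) == REF.mean_power

    def test_two_step_closed_form(self):
        # P0 = 0.4 ref, γ = 0.55: deficit shrinks by 0.45 per train, so
        # P2 = ref (1 − 0.6·0.45²) ≈ 0.8785 ref — inside the recovered band
        p = make_pulse_train(300.0)
        power = 0.4 * REF.mean_power
        for _ in range(2):
            power = vascular_response(power, REF, p)
        assert power / REF.mean_power == pytest.approx(1 - 0.6 * 0.45**2, rel=1e-9)
        assert power >= 0.85 * REF.mean_power

    def test_weaker_pulses_need_more_trains(self):
        assert stimulation_gamma(100.0) < stimulation_gamma(300.0)

        def trains_to_recover(amp):
            p = make_pulse_train(amp)
            power, n = 0.4 * REF.mean_power, 0
            while power < 0.85 * REF.mean_power:
                power = vascular_response(power, REF, p)
                n += 1
            return n

        assert trains_to_recover(300.0) < trains_to_recover(100.0)

    def test_never_overshoots_reference(self):
        p = make_pulse_train(300.0)
        power = 0.1 * REF.mean_power
        for _ in range(50):
            new = vascular_response(power, REF, p)
            assert power <= new <= REF.mean_power
            power = new


class TestSession:
    def test_healthy_start_no_stimulation(self):
        log = run_closed_loop(loop_cfg(), REF, duration=30.0, state="baseline")
        assert log.n_stimulations == 0

    def test_stented_chronic_recovers_in_two_stimulations(self):
        log = run_closed_loop(loop_cfg(), REF, duration=60.0,
                              state="stented_chronic")
        assert log.n_stimulations == 2
        assert log.recovered

    def test_every_stimulation_preceded_by_detection(self):
        log = run_closed_loop(loop_cfg(noise_rms=2.63, seed=4), REF, duration=60.0)
        det_times = [e["t"] for e in log.of_kind("detection")]
        for e in log.of_kind("stimulation"):
            assert any(0 <= e["t"] - td <= 5.0 for td in det_times)

    def test_latent_power_monotone_and_bounded(self):
        log = run_closed_loop(loop_cfg(), REF, duration=60.0)
        latent = [e["latent"] for e in log.of_kind("power")]
        assert all(a <= b + 1e-12 for a, b in zip(latent, latent[1:]))
        assert max(latent) <= REF.mean_power + 1e-9

    def test_serialized_log_byte_identical_across_reruns(self):
        a = run_closed_loop(loop_cfg(noise_rms=2.63, seed=11), REF, seed=11)
        b = run_closed_loop(loop_cfg(noise_rms=2.63, seed=11), REF, seed=11)
        assert a.to_json() == b.to_json()

    def test_post_recovery_power_is_stable(self):
        ctrl = ControllerParams(hold_windows=4)
        log = run_closed_loop(loop_cfg(noise_rms=0.5, seed=2), REF,
                              ctrl, duration=120.0)
        assert log.recovered
        est = log.power_trace()
        tail = est[-4:]
        assert np.std(tail) / np.mean(tail) < 0.05

    def test_misconfigured_controller_rejected_before_loop(self):
        with pytest.raises(ValueError):
            run_closed_loop(loop_cfg(), REF, ControllerParams(theta=0.0))
        with pytest.raises(ValueError):
            run_closed_loop(
                loop_cfg(), REF, ControllerParams(theta=0.9, recovery_frac=0.8)
            )

    def test_safety_never_violated_in_session_logs(self):
        rng = np.random.default_rng(123)
        for _ in range(10):
            amp = float(rng.uniform(10, 600))
            allow = bool(rng.integers(0, 2))
            ctrl = ControllerParams(amplitude=amp, allow_high=allow)
            try:
                log = run_closed_loop(loop_cfg(seed=1), REF, ctrl, duration=30.0)
            except SafetyError:
                assert amp > 500.0 or (amp > 300.0 and not allow)
                continue
            for e in log.of_kind("stimulation"):
                assert e["amplitude"] <= 500.0
                assert e["amplitude"] <= 300.0 or allow
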