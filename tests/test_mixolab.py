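import dataclasses

import numpy as np
import pytest

from breadtex.mixolab import (
    ExtractionConfig,
    MixolabParameters,
    TorqueCurve,
    detect_phases,
    extract_parameters,
    smooth_envelope,
)
from breadtex.synthetic import ChopinProtocol, generate_torque_curve, random_parameters


def _flat_curve(value=0.0, protocol=None):
    protocol = protocol or ChopinProtocol()
    time = np.arange(0, protocol.total_minutes + 1e-9, 1 / 60.0)
    return TorqueCurve(
        time=time,
        torque=np.full_like(time, value),
        temperature=protocol.temperature_at(time),
    )


class TestTorqueCurveValidation:
    def test_rejects_nonmonotone_time(self):
        with pytest.raises(ValueError, match="time not increasing"):
            TorqueCurve(time=[0, 2, 1], torque=[0, 0, 0], temperature=[30, 30, 30])

    def test_rejects_negative_torque(self):
        with pytest.raises(ValueError):
            TorqueCurve(time=[0, 1], torque=[0, -1], temperature=[30, 30])

    def test_rejects_length_mismatch(self):
        with pytest.raises(ValueError):
            TorqueCurve(time=[0, 1], torque=[0, 0, 0], temperature=[30, 30])


class TestSmoothEnvelope:
    def test_constant(self):
        curve = _flat_curve(0.7)
        upper, mid, lower = smooth_envelope(curve, 0.5)
        assert np.allclose(upper, 0.7)
        assert np.allclose(mid, 0.7)
        assert np.allclose(lower, 0.7)

    def test_sinusoid_closed_form(self):
        # peak-to-peak A around mean m; window of one full period
        t = np.arange(0, 10, 1 / 60.0)
        m, a, period = 1.0, 0.2, 0.2
        torque = m + 0.5 * a * np.sin(2 * np.pi * t / period)
        curve = TorqueCurve(time=t, torque=torque, temperature=np.full_like(t, 30.0))
        upper, mid, lower = smooth_envelope(curve, period)
        interior = slice(30, -30)
        assert np.allclose((upper - lower)[interior], a, atol=a * 0.02)
        assert np.allclose(mid[interior], m, atol=0.01)

    def test_monotone_ramp_bound(self):
        t = np.arange(0, 10, 1 / 60.0)
        slope = 0.3
        curve = TorqueCurve(time=t, torque=slope * t, temperature=np.full_like(t, 30.0))
        window = 0.5
        _, mid, _ = smooth_envelope(curve, window)
        interior = slice(60, -60)
        assert np.all(np.abs(mid[interior] - slope * t[interior]) <= slope * window / 2 + 1e-9)

    def test_ordering(self, control_params):
        curve = generate_torque_curve(control_params, noise_sd=0.02, seed=1)
        upper, mid, lower = smooth_envelope(curve, 0.3)
        assert np.all(upper >= mid - 1e-12)
        assert np.all(mid >= lower - 1e-12)

    def test_window_too_long(self):
        curve = _flat_curve(1.0)
        with pytest.raises(ValueError):
            smooth_envelope(curve, 1000.0)


class TestPhaseDetection:
    def test_full_schedule(self, control_params, protocol):
        curve = generate_torque_curve(control_params, protocol)
        phases = detect_phases(curve)
        assert phases.heating_onset is not None
        assert curve.time[phases.heating_onset] == pytest.approx(
            protocol.heating_onset_min, abs=0.15
        )
        assert curve.time[phases.ramp_end] == pytest.approx(protocol.ramp_end_min, abs=0.15)
        assert phases.has_cooling

    def test_isothermal_record(self):
        t = np.arange(0, 5, 1 / 60.0)
        curve = TorqueCurve(time=t, torque=np.zeros_like(t), temperature=np.full_like(t, 30.0))
        phases = detect_phases(curve)
        assert phases.heating_onset is None
        assert not phases.has_cooling


class TestExtraction:
    def test_control_round_trip(self, control_params, protocol):
        curve = generate_torque_curve(control_params, protocol)
        got = extract_parameters(curve)
        assert got.c1 == pytest.approx(1.10, abs=0.01)
        assert got.c2 == pytest.approx(0.52, abs=0.01)
        assert got.c3 == pytest.approx(1.61, abs=0.01)
        assert got.c4 == pytest.approx(1.29, abs=0.01)
        assert got.c5 == pytest.approx(1.89, abs=0.01)
        assert got.stability == pytest.approx(6.97, abs=0.1)
        assert got.gelling_mid == pytest.approx(66.0, abs=0.5)
        assert got.t_hydr == pytest.approx(3.63, abs=0.1)
        assert got.t1 == pytest.approx(7.08, abs=0.1)
        assert got.t3 == pytest.approx(21.7, abs=0.1)
        assert got.amplitude == pytest.approx(0.073, abs=0.01)
        assert got.water_absorption == 62.8

    def test_flat_zero_record(self):
        got = extract_parameters(_flat_curve(0.0))
        assert got.c1 == 0.0
        assert got.c2 == 0.0 and got.c5 == 0.0
        assert got.amplitude == 0.0 and got.stability == 0.0
        assert got.t_hydr is None

    def test_no_heating_gives_partial_result(self):
        t = np.arange(0, 10, 1 / 60.0)
        torque = np.clip(t / 4.0, 0, 1.0)
        curve = TorqueCurve(time=t, torque=torque, temperature=np.full_like(t, 30.0))
        with pytest.warns(UserWarning, match="no temperature rise"):
            got = extract_parameters(curve)
        assert got.c1 is not None
        assert got.c2 is None and got.c3 is None and got.c5 is None
        assert got.gelling_mid is None

    def test_noiseless_round_trip_random_vectors(self):
        for i in range(15):
            params = random_parameters(np.random.default_rng(400 + i))
            got = extract_parameters(generate_torque_curve(params))
            for name, tol in (
                ("c1", 0.01), ("c2", 0.01), ("c3", 0.01), ("c4", 0.01), ("c5", 0.01),
                ("amplitude", 0.01),
            ):
                assert getattr(got, name) == pytest.approx(getattr(params, name), abs=tol), name
            for name in ("t_hydr", "t1", "t3", "stability"):
                assert getattr(got, name) == pytest.approx(getattr(params, name), abs=0.1), name
            assert got.gelling_mid == pytest.approx(params.gelling_mid, abs=0.5)

    def test_noisy_round_trip_sample(self):
        ok = 0
        for i in range(25):
            params = random_parameters(np.random.default_rng(900 + i))
            curve = generate_torque_curve(params, noise_sd=0.01, seed=i)
            got = extract_parameters(curve)
            ok += all(
                abs(getattr(got, n) - getattr(params, n)) <= 0.03
                for n in ("c1", "c2", "c3", "c4", "c5", "amplitude")
            ) and all(
                abs(getattr(got, n) - getattr(params, n)) <= 0.2
                for n in ("t_hydr", "t1", "t3", "stability")
            ) and abs(got.gelling_mid - params.gelling_mid) <= 1.0
        assert ok >= 24

    def test_extracted_ordering_invariants(self):
        for i in range(10):
            params = random_parameters(np.random.default_rng(700 + i))
            got = extract_parameters(generate_torque_curve(params, noise_sd=0.01, seed=i))
            got.check_ordering()
            assert got.c2 <= got.c1 and got.c2 <= got.c3
            assert got.t1 < got.t3

    def test_gelling_mid_between_phase_temperatures(self, protocol):
        for i in range(10):
            params = random_parameters(np.random.default_rng(800 + i))
            got = extract_parameters(generate_torque_curve(params))
            assert protocol.start_temp < got.gelling_mid
            t3_temp = protocol.temperature_at(np.array([got.t3]))[0]
            assert got.gelling_mid <= t3_temp + 0.5

    def test_slope_beta_monotone_in_c3(self, control_params):
        slopes = []
        for c3 in (1.45, 1.61, 1.80):
            params = dataclasses.replace(control_params, c3=c3)
            got = extract_parameters(generate_torque_curve(params))
            slopes.append(got.slope_beta)
        assert slopes[0] < slopes[1] < slopes[2]

    def test_config_validation(self):
        with pytest.raises(ValueError):
            ExtractionConfig(stability_tolerance=0.0)
        with pytest.raises(ValueError):
            ExtractionConfig(hydration_fraction=1.5)
        with pytest.raises(ValueError):
            ExtractionConfig(smoothing_window_min=-1)


class TestParameterChecks:
    def test_check_ordering_catches_violations(self):
        p = MixolabParameters(c1=1.0, c2=1.2)
        with pytest.raises(ValueError, match="C2"):
            p.check_ordering()
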