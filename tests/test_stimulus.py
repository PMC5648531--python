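"""Protocol builders and deterministic Ca2+ waveforms."""

import json

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad

from svpools.stimulus import (CaParams, PulseProtocol,
                              build_random_low_freq_train,
                              build_regular_train, build_triplet_train,
                              ca_residual, ca_sensor, concat_protocols,
                              residual_peaks)


class TestBuilders:
    def test_regular_train_is_arithmetic_progression(self):
        p = build_regular_train(100.0, 50, 0.0)
        assert np.allclose(p.pulse_times, np.arange(50) * 0.01)

    def test_lfd_protocol_ends_at_149_5_s(self):
        p = build_regular_train(2.0, 300)
        assert p.n_pulses == 300
        assert p.pulse_times[-1] == pytest.approx(149.5)

    def test_degenerate_single_pulse(self):
        p = build_regular_train(1.0, 1, t0=5.0)
        assert np.allclose(p.pulse_times, [5.0])

    @pytest.mark.parametrize("freq,n", [(0.0, 10), (-2.0, 10), (2.0, 0)])
    def test_regular_train_rejects_bad_args(self, freq, n):
        with pytest.raises(ValueError):
            build_regular_train(freq, n)

    def test_triplet_train_layout(self):
        p = build_triplet_train(100, 2.0, 100.0)
        assert p.n_pulses == 300
        assert np.allclose(p.pulse_times[:3], [0.0, 0.01, 0.02])
        assert p.pulse_times[3] == pytest.approx(0.5)

    def test_single_triplet_at_200hz(self):
        p = build_triplet_train(1, 2.0, 200.0)
        assert np.allclose(p.pulse_times, [0.0, 0.005, 0.01])

    def test_triplet_must_fit_repeat_interval(self):
        with pytest.raises(ValueError):
            build_triplet_train(100, 2.0, 3.0)

    def test_random_train_isis_within_band(self):
        p = build_random_low_freq_train(300, 0.5, 10.0, seed=1)
        isis = np.diff(p.pulse_times)
        assert p.n_pulses == 300
        assert np.all(np.diff(p.pulse_times) > 0)
        assert isis.min() >= 0.1 and isis.max() <= 2.0

    def test_random_train_collapsed_band_is_regular(self):
        a = build_random_low_freq_train(5, 2.0, 2.0, seed=99)
        b = build_regular_train(2.0, 5)
        assert np.allclose(a.pulse_times, b.pulse_times)

    def test_random_train_rejects_bad_args(self):
        with pytest.raises(ValueError):
            build_random_low_freq_train(0, 0.5, 10.0, seed=1)
        with pytest.raises(ValueError):
            build_random_low_freq_train(10, 5.0, 2.0, seed=1)

    @given(seed=st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_random_train_deterministic_under_seed(self, seed):
        a = build_random_low_freq_train(20, 0.5, 10.0, seed)
        b = build_random_low_freq_train(20, 0.5, 10.0, seed)
        assert np.array_equal(a.pulse_times, b.pulse_times)

    def test_concat_lfd_and_recovery_train(self):
        lfd = build_regular_train(2.0, 300)
        rec = build_regular_train(100.0, 50)
        p = concat_protocols(lfd, rec, gap=0.5, names=("LFD", "recovery"))
        assert p.n_pulses == 350
        assert p.segments == (("LFD", 0, 300), ("recovery", 300, 350))
        assert p.pulse_times[300] == pytest.approx(150.0)
        assert p.segment_slice("recovery") == slice(300, 350)

    def test_concat_ten_ms_gap(self):
        lfd = build_regular_train(2.0, 300)
        rec = build_regular_train(100.0, 50)
        p = concat_protocols(lfd, rec, gap=0.01)
        assert p.pulse_times[300] == pytest.approx(149.51)

    def test_concat_with_empty_tail_is_identity(self):
        a = build_regular_train(2.0, 5)
        b = PulseProtocol(np.array([]))
        p = concat_protocols(a, b, gap=0.0)
        assert np.array_equal(p.pulse_times, a.pulse_times)

    def test_protocol_invariants_enforced(self):
        with pytest.raises(ValueError):
            PulseProtocol(np.array([0.0, 0.0, 1.0]))
        with pytest.raises(ValueError):
            PulseProtocol(np.array([-1.0, 1.0]))
        with pytest.raises(ValueError):
            PulseProtocol(np.array([0.0, 1.0]),
                          segments=(("a", 0, 2), ("b", 1, 2)))


class TestResidualCa:
    def test_single_pulse_increment(self, ca):
        p = build_regular_train(2.0, 3)
        assert ca_residual(0.0, p, ca) == pytest.approx(520e-9)

    def test_geometric_series_at_50th_pulse_of_100hz(self, ca):
        # closed form: 520 * (1 - exp(-50*ISI/tau)) / (1 - exp(-ISI/tau)) nM
        p = build_regular_train(100.0, 50)
        expected = 520e-9 * (1 - np.exp(-50 * 0.01 / 0.042)) \
            / (1 - np.exp(-0.01 / 0.042))
        assert ca_residual(p.pulse_times[-1], p, ca) == pytest.approx(expected,
                                                                      rel=1e-12)
        assert expected > 2e-6  # builds up to ~2.5 uM

    def test_decays_back_to_rest_between_2hz_pulses(self, ca):
        p = build_regular_train(2.0, 2)
        val = ca_residual(0.5 - 1e-12, p, ca)
        assert val == pytest.approx(520e-9 * np.exp(-0.5 / 0.042), rel=1e-6)
        assert val < 4e-12  # ~3.5e-3 nM, back at rest

    def test_zero_before_first_pulse_nonnegative_after(self, ca):
        p = build_regular_train(10.0, 5, t0=1.0)
        t = np.linspace(0, 2, 500)
        r = ca_residual(t, p, ca)
        assert np.all(r[t < 1.0] == 0.0)
        assert np.all(r >= 0.0)

    def test_peak_sequence_increases_and_converges_at_100hz(self, ca):
        p = build_regular_train(100.0, 200)
        peaks = residual_peaks(p, ca)
        # strictly increasing until the geometric series has converged to
        # float precision, never above the closed-form limit
        assert np.all(np.diff(peaks[:50]) > 0)
        assert np.all(np.diff(peaks) >= -1e-18)
        limit = 520e-9 / (1 - np.exp(-0.01 / 0.042))
        assert peaks[-1] == pytest.approx(limit, rel=1e-9)
        assert np.all(peaks <= limit * (1 + 1e-12))

    def test_no_summation_at_2hz(self, ca):
        peaks = residual_peaks(build_regular_train(2.0, 20), ca)
        rel_diff = np.abs(np.diff(peaks)) / peaks[:-1]
        assert np.all(rel_diff < 1e-5)  # consecutive peaks differ by < 0.001%


class TestSensorCa:
    def test_peak_is_rest_plus_residual_plus_amplitude(self, ca):
        p = build_regular_train(1.0, 1)
        val = ca_sensor(0.0, p, ca)
        assert val == pytest.approx(ca.ca_rest + 520e-9 + ca.ap_amplitude,
                                    rel=1e-9)

    def test_half_width_definition(self, ca):
        p = build_regular_train(1.0, 1, t0=1.0)
        half = ca_sensor(1.0 + ca.ap_fwhm / 2, p, ca)
        gauss = half - ca.ca_rest - ca_residual(1.0 + ca.ap_fwhm / 2, p, ca)
        assert gauss == pytest.approx(ca.ap_amplitude / 2, rel=1e-9)

    def test_baseline_far_from_pulses(self, ca):
        p = build_regular_train(1.0, 1, t0=1.0)
        assert ca_sensor(0.2, p, ca) == pytest.approx(ca.ca_rest, rel=1e-9)

    def test_gaussian_area_over_one_pulse(self, ca):
        # integral of the AP term over a pulse equals amplitude*sigma*sqrt(2*pi)
        p = build_regular_train(1.0, 1, t0=1.0)

        def ap_term(t):
            return ca_sensor(t, p, ca) - ca.ca_rest - ca_residual(t, p, ca)

        area, _ = quad(ap_term, 1.0 - 0.01, 1.0 + 0.01,
                       points=[1.0], epsabs=1e-22, epsrel=1e-12, limit=200)
        expected = ca.ap_amplitude * ca.ap_sigma * np.sqrt(2 * np.pi)
        assert area == pytest.approx(expected, rel=1e-9)

    def test_residual_flag_removes_residual_term(self, ca):
        p = build_regular_train(100.0, 10)
        t = 0.095
        with_res = ca_sensor(t, p, ca)
        without = ca_sensor(t, p, ca.replace(sensor_sees_residual=False))
        assert with_res - without == pytest.approx(ca_residual(t, p, ca),
                                                   rel=1e-12)


class TestSerialization:
    def test_csv_round_trip_preserves_times_and_segments(self, tmp_path):
        p = concat_protocols(build_regular_train(2.0, 10),
                             build_regular_train(100.0, 5), gap=0.5,
                             names=("LFD", "recovery"))
        path = tmp_path / "protocol.csv"
        p.to_csv(path)
        q = PulseProtocol.from_csv(path)
        assert np.allclose(p.pulse_times, q.pulse_times)
        assert q.segments == p.segments

    def test_json_round_trip(self, tmp_path):
        p = build_triplet_train(4, 2.0, 100.0)
        path = tmp_path / "protocol.json"
        p.to_json(path)
        q = PulseProtocol.from_json(path)
        assert np.allclose(p.pulse_times, q.pulse_times)
        assert q.label == p.label
        r = PulseProtocol.from_json(p.to_json())
        assert np.allclose(p.pulse_times, r.pulse_times)

    def test_ca_params_validation(self):
        with pytest.raises(ValueError):
            CaParams(residual_tau=0.0)
        with pytest.raises(ValueError):
            CaParams(ap_amplitude=-1e-6)
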