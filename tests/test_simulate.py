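"""Trace synthesis: path statistics, rendering, filtering, noise, end-to-end."""

import numpy as np
import pytest

from kcvgate import (GatingScheme, SimulationConfig, add_noise, bessel_lowpass,
                     render_current, simulate_state_path, simulate_trace,
                     stationary_probabilities)
from kcvgate.simulate import StatePath, rise_time


class TestStatePath:
    def test_short_duration_single_state(self, two_state_scheme):
        p = simulate_state_path(two_state_scheme, 1e-9, seed=0)
        assert len(p.states) == 1 and p.states[0] == "O"

    def test_open_fraction_matches_stationary(self, two_state_scheme):
        p_o = stationary_probabilities(two_state_scheme)["O"]
        fracs = [simulate_state_path(two_state_scheme, 100.0, seed=s).open_fraction()
                 for s in range(5)]
        assert np.allclose(fracs, p_o, atol=0.02)

    def test_mean_sojourns_match_rates(self, two_state_scheme):
        p = simulate_state_path(two_state_scheme, 100.0, seed=3)
        assert p.sojourns("C1").mean() == pytest.approx(1 / 300, rel=0.05)
        assert p.sojourns("O").mean() == pytest.approx(1 / 100, rel=0.05)

    def test_seeded_determinism(self, two_state_scheme):
        a = simulate_state_path(two_state_scheme, 5.0, seed=7)
        b = simulate_state_path(two_state_scheme, 5.0, seed=7)
        assert np.array_equal(a.times, b.times) and a.states == b.states

    def test_alternation_enforced(self):
        with pytest.raises(ValueError):
            StatePath(np.array([0.0, 1.0]), ["O", "O"], 2.0)


class TestRender:
    def test_always_open_is_constant(self, two_state_scheme):
        cfg = SimulationConfig(duration=0.01, seed=0, oversample=10)
        p = StatePath(np.array([0.0]), ["O"], 0.01)
        x = render_current(p, two_state_scheme, cfg)
        assert np.all(x == two_state_scheme.i_true)

    def test_square_wave(self, two_state_scheme):
        times = np.arange(0, 10) * 1e-3
        states = ["O" if i % 2 == 0 else "C1" for i in range(10)]
        p = StatePath(times, states, 0.01)
        cfg = SimulationConfig(duration=0.01, seed=0, oversample=10)
        x = render_current(p, two_state_scheme, cfg)
        assert set(np.unique(x)) == {0.0, 6.0}
        # 1-ms plateaus at 50 kHz = 50 samples per level
        assert np.abs(np.mean(x) - 3.0) < 0.1

    def test_time_average_matches_occupancy(self, two_state_scheme):
        p = simulate_state_path(two_state_scheme, 50.0, seed=1)
        cfg = SimulationConfig(duration=50.0, seed=1, oversample=10)
        x = render_current(p, two_state_scheme, cfg)
        expected = two_state_scheme.i_true * stationary_probabilities(
            two_state_scheme)["O"]
        assert np.mean(x) == pytest.approx(expected, rel=0.02)

    def test_negative_voltage_downward_openings(self, two_state_scheme):
        p = StatePath(np.array([0.0]), ["O"], 0.01)
        cfg = SimulationConfig(duration=0.01, seed=0, voltage=-120.0, oversample=10)
        x = render_current(p, two_state_scheme, cfg)
        assert np.all(x == -6.0)


class TestBesselFilter:
    def test_dc_gain_unity(self):
        y = bessel_lowpass(np.full(5000, 3.3), 1000.0, 50000.0)
        assert y[-1] == pytest.approx(3.3, rel=1e-6)

    def test_zero_in_zero_out(self):
        assert np.all(bessel_lowpass(np.zeros(100), 1000.0, 50000.0) == 0)

    def test_rise_time_scaling(self):
        # 4th-order Bessel: 10-90% rise ~ 0.34 / cutoff
        assert rise_time(1000.0) == pytest.approx(0.34e-3, rel=0.1)
        assert rise_time(2000.0) == pytest.approx(0.17e-3, rel=0.1)

    def test_cutoff_above_nyquist_rejected(self):
        with pytest.raises(ValueError):
            bessel_lowpass(np.zeros(10), 30000.0, 50000.0)

    def test_pulse_charge_conserved(self):
        fs = 250000.0
        x = np.zeros(int(0.1 * fs))
        x[1000:1000 + int(0.005 * fs)] = 6.0   # 5-ms pulse
        y = bessel_lowpass(x, 1000.0, fs)
        assert y.sum() == pytest.approx(x.sum(), rel=1e-3)


class TestNoise:
    def test_zero_sd_identity(self):
        x = np.arange(10.0)
        assert np.array_equal(add_noise(x, 0.0, seed=0), x)

    def test_sample_sd(self):
        x = np.zeros(10**6)
        y = add_noise(x, 0.8, seed=1)
        assert y.std() == pytest.approx(0.8, rel=0.02)
        assert y.mean() == pytest.approx(0.0, abs=0.01)

    def test_different_seeds_differ(self):
        x = np.zeros(100)
        assert not np.array_equal(add_noise(x, 1.0, 1), add_noise(x, 1.0, 2))


class TestSimulateTrace:
    def test_bit_identical_for_same_seed(self, two_state_scheme):
        cfg = SimulationConfig(duration=2.0, noise_sd=0.5, voltage=120.0,
                               seed=9, oversample=10)
        a = simulate_trace(two_state_scheme, cfg)
        b = simulate_trace(two_state_scheme, cfg)
        assert np.array_equal(a.samples, b.samples)

    def test_noiseless_mean_matches_occupancy(self, two_state_scheme):
        cfg = SimulationConfig(duration=100.0, noise_sd=0.0, voltage=120.0,
                               seed=2, oversample=10)
        tr = simulate_trace(two_state_scheme, cfg)
        expected = 6.0 * stationary_probabilities(two_state_scheme)["O"]
        assert tr.samples[100:].mean() == pytest.approx(expected, rel=0.01)

    def test_slow_scheme_two_histogram_modes(self):
        s = GatingScheme({"C1": (20.0, 20.0)}, i_true=6.0)   # 50-ms sojourns
        cfg = SimulationConfig(duration=30.0, noise_sd=0.2, voltage=120.0,
                               seed=5, oversample=10)
        tr = simulate_trace(s, cfg)
        counts, edges = np.histogram(tr.samples, bins=60)
        centers = 0.5 * (edges[:-1] + edges[1:])
        lower = centers < 3.0
        assert abs(centers[lower][np.argmax(counts[lower])]) < 0.3
        assert abs(centers[~lower][np.argmax(counts[~lower])] - 6.0) < 0.3

    def test_fast_flicker_time_averages(self):
        # O-M gating far above the cutoff collapses to one apparent level
        s = GatingScheme({"M": (30000.0, 90000.0)}, i_true=6.0)
        cfg = SimulationConfig(duration=2.0, noise_sd=0.0, voltage=120.0,
                               seed=6, oversample=400)
        tr = simulate_trace(s, cfg)
        apparent = 6.0 * 90000.0 / 120000.0
        assert tr.samples[50:].mean() == pytest.approx(apparent, rel=0.02)
        assert tr.samples[50:].std() < 1.0
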