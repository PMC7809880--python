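"""Amplitude histograms, noise convolution and the beta-fit engine
(fast checks; the full parameter-recovery study lives in the acceptance
suite)."""

import numpy as np
import pytest

from kcvgate import SimulationConfig, simulate_trace, stationary_probabilities
from kcvgate.amphist import (AmplitudeHistogram, BetaFitResult, NoiseModel,
                             build_amplitude_histogram, gating_factor,
                             predict_histogram, _chi_square)


def candidate(**kw):
    base = dict(i_true=6.0, k_om=2000.0, k_mo=6000.0, k_of=1000.0,
                k_fo=9000.0, k_os=5.0, k_so=30.0)
    base.update(kw)
    return BetaFitResult(**base)


class TestAmplitudeHistogram:
    def test_counts_conserved(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 1.0, 10**5)
        h = build_amplitude_histogram(x, 0.1)
        assert int(h.counts.sum()) == h.total == 10**5

    def test_constant_trace_single_occupied_bin(self):
        h = build_amplitude_histogram(np.full(1000, 3.0), 0.1)
        assert np.count_nonzero(h.counts) == 1

    def test_moments_of_pure_noise(self):
        rng = np.random.default_rng(1)
        h = build_amplitude_histogram(rng.normal(0, 1.0, 10**6), 0.05)
        mean = np.average(h.centers, weights=h.counts)
        sd = np.sqrt(np.average((h.centers - mean) ** 2, weights=h.counts))
        assert sd == pytest.approx(1.0, rel=0.02)


class TestNoiseModel:
    def test_parametric_kernel_normalized(self):
        k = NoiseModel(sd=0.8).kernel(0.1)
        assert k.sum() == pytest.approx(1.0)
        assert len(k) % 2 == 1

    def test_empirical_from_baseline(self):
        rng = np.random.default_rng(2)
        nm = NoiseModel.from_trace(rng.normal(0.3, 0.5, 10**5), 0.05)
        k = nm.kernel(0.05)
        assert k.sum() == pytest.approx(1.0)
        centers = (np.arange(len(k)) - len(k) // 2) * 0.05
        assert abs(np.sum(centers * k)) < 0.05

    def test_requires_exactly_one_spec(self):
        with pytest.raises(ValueError):
            NoiseModel()


class TestPredict:
    CFG = dict(duration=5.0, sampling_rate=5000.0, oversample=40,
               voltage=120.0)

    def test_deterministic_under_common_seed(self):
        cfg = SimulationConfig(seed=1, **self.CFG)
        cand = candidate()
        centers = np.arange(-2.0, 8.0, 0.1)
        a = predict_histogram(cand, cfg, NoiseModel(sd=0.8), 7, centers, 10**5)
        b = predict_histogram(cand, cfg, NoiseModel(sd=0.8), 7, centers, 10**5)
        assert np.array_equal(a.counts, b.counts)

    def test_nearly_always_open_single_peak_at_itrue(self):
        cand = candidate(k_om=1e-2, k_of=1e-2, k_os=1e-2,
                         k_mo=1e3, k_fo=1e3, k_so=1e3)
        cfg = SimulationConfig(seed=2, **self.CFG)
        centers = np.arange(-2.0, 8.0, 0.1)
        h = predict_histogram(cand, cfg, NoiseModel(sd=0.5), 3, centers, 10**5)
        assert h.centers[np.argmax(h.counts)] == pytest.approx(6.0, abs=0.15)

    def test_slow_gating_peak_areas_match_occupancy(self):
        cand = candidate(k_om=1e-2, k_of=1e-2, k_mo=1e3, k_fo=1e3,
                         k_os=20.0, k_so=20.0)   # P_S = 0.5, 50-ms sojourns
        cfg = SimulationConfig(seed=3, duration=30.0, sampling_rate=5000.0,
                               oversample=10, voltage=120.0)
        centers = np.arange(-2.0, 8.0, 0.1)
        h = predict_histogram(cand, cfg, NoiseModel(sd=0.3), 4, centers, 10**6)
        closed_area = h.counts[centers < 3.0].sum() / h.counts.sum()
        assert closed_area == pytest.approx(0.5, abs=0.05)

    def test_fast_flicker_shifts_open_peak(self):
        cand = candidate(k_om=20000.0, k_mo=60000.0, k_of=1e-2, k_os=1e-2)
        cfg = SimulationConfig(seed=4, duration=5.0, sampling_rate=5000.0,
                               oversample=400, voltage=120.0)
        centers = np.arange(-2.0, 8.0, 0.1)
        h = predict_histogram(cand, cfg, NoiseModel(sd=0.3), 5, centers, 10**5)
        peak = h.centers[np.argmax(h.counts)]
        assert peak == pytest.approx(6.0 * 0.75, abs=0.3)
        assert peak < 6.0   # apparent current below I_true

    def test_convolution_preserves_total(self):
        cfg = SimulationConfig(seed=5, **self.CFG)
        centers = np.arange(-4.0, 10.0, 0.1)
        h = predict_histogram(candidate(), cfg, NoiseModel(sd=0.8), 6,
                              centers, 123456)
        assert h.counts.sum() == pytest.approx(123456, abs=1.0)


class TestChiSquare:
    def test_zero_for_identical(self):
        x = np.array([10.0, 50.0, 200.0, 50.0, 10.0])
        assert _chi_square(x, x) == 0.0

    def test_tail_pooling_keeps_low_bins(self):
        obs = np.array([1.0, 2.0, 100.0, 2.0, 1.0])
        exp = np.array([1.0, 2.0, 100.0, 2.0, 1.0])
        assert np.isfinite(_chi_square(obs, exp))


class TestGatingFactor:
    @pytest.mark.parametrize("k_fo,k_of,expected", [
        (5000.0, 5000.0, 0.5), (9000.0, 1000.0, 0.9)])
    def test_values(self, k_fo, k_of, expected):
        assert gating_factor(candidate(k_fo=k_fo, k_of=k_of)) == pytest.approx(expected)

    def test_limit_all_open(self):
        assert gating_factor(candidate(k_of=1e-9)) == pytest.approx(1.0)


class TestValidation:
    def test_rejects_nonpositive_rates(self):
        with pytest.raises(ValueError):
            candidate(k_om=0.0)

    def test_histogram_requires_uniform_bins(self):
        with pytest.raises(ValueError):
            AmplitudeHistogram(np.array([0.0, 0.1, 0.3]), np.array([1, 1, 1]),
                               0.1, 3)
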