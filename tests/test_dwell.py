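"""Dwell-time statistics: histograms, mixture fits, model selection,
occupation probabilities, missed-events correction."""

import numpy as np
import pytest

from kcvgate.dwell import (adjusted_r2, build_histogram, estimate_rare_state,
                           fit_exponential_mixture, missed_events_correction,
                           occupation_probabilities, select_model,
                           ExponentialMixtureFit)


def exp_durations(tau, n, seed):
    return np.random.default_rng(seed).exponential(tau, n)


class TestHistogram:
    def test_counts_conserved(self):
        d = exp_durations(1e-3, 10**4, 0)
        h = build_histogram(d)
        assert h.counts.sum() == h.total

    def test_single_event(self):
        h = build_histogram(np.array([5e-3]))
        assert h.total == 1 and h.counts.sum() == 1

    def test_log_mode_near_tau(self):
        # under log binning the density t*exp(-t/tau) peaks at t = tau
        d = exp_durations(1e-3, 10**4, 1)
        h = build_histogram(d, bins_per_decade=10)
        mode = h.centers[np.argmax(h.counts)]
        assert 0.5e-3 < mode < 2e-3


class TestAdjustedR2:
    def test_perfect_fit(self):
        assert adjusted_r2(1.0, 30, 6) == 1.0

    def test_hand_values(self):
        assert adjusted_r2(0.98, 30, 6) == pytest.approx(1 - 0.02 * 29 / 23)
        assert adjusted_r2(0.0, 11, 1) == pytest.approx(1 - 10 / 9)

    @pytest.mark.parametrize("n,p", [(5, 4), (3, 2), (10, 0)])
    def test_invalid_inputs(self, n, p):
        with pytest.raises(ValueError):
            adjusted_r2(0.9, n, p)


class TestMixtureFit:
    def test_single_component_recovery(self):
        h = build_histogram(exp_durations(1e-3, 10**4, 2))
        f = fit_exponential_mixture(h, 1)
        assert f.taus[0] == pytest.approx(1e-3, rel=0.05)
        assert f.amplitudes[0] == pytest.approx(10**4, rel=0.05)

    def test_two_component_recovery(self):
        rng = np.random.default_rng(3)
        d = np.concatenate([rng.exponential(1e-3, 8000),
                            rng.exponential(50e-3, 2000)])
        f = fit_exponential_mixture(build_histogram(d), 2)
        assert f.taus[0] == pytest.approx(1e-3, rel=0.10)
        assert f.taus[1] == pytest.approx(50e-3, rel=0.10)
        assert f.amplitudes[0] / f.amplitudes[1] == pytest.approx(4.0, rel=0.15)

    def test_perfect_counts_r2_one(self):
        edges = 1e-3 * 10 ** (np.arange(21) / 10)
        expected = 1000 * (np.exp(-edges[:-1] / 5e-3) - np.exp(-edges[1:] / 5e-3))
        counts = np.round(expected).astype(int)
        from kcvgate.dwell import DwellTimeHistogram
        h = DwellTimeHistogram("closed", edges, counts, int(counts.sum()))
        f = fit_exponential_mixture(h, 1)
        assert f.r2 > 0.999 and f.r2_adj > 0.999

    def test_model_selection_prefers_true_order(self):
        rng = np.random.default_rng(4)
        d = np.concatenate([rng.exponential(1e-3, 8000),
                            rng.exponential(80e-3, 2000)])
        h = build_histogram(d)
        f2 = fit_exponential_mixture(h, 2)
        f3 = fit_exponential_mixture(h, 3)
        assert select_model(f2, f3) is f2

    def test_select_model_tie_goes_to_fewer(self):
        f1 = ExponentialMixtureFit(np.array([10.0]), np.array([1e-3]),
                                   0.99, 0.95, 20, 2)
        f2 = ExponentialMixtureFit(np.array([5.0, 5.0]), np.array([1e-3, 1e-2]),
                                   0.995, 0.95, 20, 4)
        assert select_model(f1, f2) is f1
        assert select_model(f2, f1) is f1


class TestRareState:
    def test_no_outliers_no_rare_state(self):
        d = exp_durations(1e-3, 10**4, 5)
        h = build_histogram(d)
        f = fit_exponential_mixture(h, 1)
        out = estimate_rare_state(d, h, f)
        # any appended component would have to lie beyond the fitted tail
        assert out.n_components <= f.n_components + 1
        if out.n_components > f.n_components:
            assert out.amplitudes[-1] < 0.01 * f.amplitudes[0]

    def test_injected_long_events_recovered(self):
        rng = np.random.default_rng(6)
        short = rng.exponential(1e-3, 10**4)
        long = rng.normal(0.5, 0.02, 20)
        d = np.concatenate([short, long])
        h = build_histogram(d)
        f = fit_exponential_mixture(h, 1)
        out = estimate_rare_state(d, h, f)
        assert out.n_components == 2
        assert out.amplitudes[-1] == pytest.approx(20, abs=2)
        assert out.taus[-1] == pytest.approx(long.mean(), rel=0.05)
        assert bool(out.estimated[-1])


class TestOccupation:
    def test_symmetry(self):
        st = occupation_probabilities((100, 1e-2), [(100, 1e-2)])
        assert st.probabilities["C1"] == pytest.approx(0.5)

    def test_hand_values(self):
        st = occupation_probabilities((1000, 1e-2), [(500, 2e-3), (10, 0.1)])
        assert st.probabilities["C1"] == pytest.approx(1000 / 12000)
        assert st.probabilities["C2"] == pytest.approx(1000 / 12000)
        assert st.probabilities["O"] == pytest.approx(10000 / 12000)
        assert st.frequencies["C1"] == pytest.approx((1000 / 12000) / 2e-3)

    def test_reproduces_stationary_distribution(self, three_closed_scheme):
        # exact expected dwell statistics must return the analytic occupancies
        from kcvgate.schemes import expected_dwell_times, stationary_probabilities
        tau = expected_dwell_times(three_closed_scheme)
        ktot = three_closed_scheme.total_exit_from_open
        n_open = 10000.0
        closed = [(n_open * three_closed_scheme.entry_rate(c) / ktot, tau[c])
                  for c in three_closed_scheme.closed_states]
        st = occupation_probabilities((n_open, tau["O"]), closed)
        truth = stationary_probabilities(three_closed_scheme)
        for i, c in enumerate(three_closed_scheme.closed_states):
            assert st.probabilities[f"C{i + 1}"] == pytest.approx(truth[c], rel=1e-9)

    def test_identities(self):
        st = occupation_probabilities((321, 7e-3), [(55, 1e-3), (9, 0.2)])
        assert sum(st.probabilities.values()) == pytest.approx(1.0, abs=1e-12)
        assert st.frequencies["O"] == pytest.approx(
            st.frequencies["C1"] + st.frequencies["C2"], rel=1e-12)
        for c in ("C1", "C2"):
            assert st.frequencies[c] == pytest.approx(
                st.probabilities[c] / st.lifetimes[c], rel=1e-12)


class TestMissedEvents:
    def _stats_and_fit(self, n_c=1000.0, tau_c=1e-3, n_o=1001.0, tau_o=1e-2):
        st = occupation_probabilities((n_o, tau_o), [(n_c, tau_c)])
        fit = ExponentialMixtureFit(np.array([n_c]), np.array([tau_c]),
                                    1.0, 1.0, 20, 2)
        return st, fit

    def test_vanishing_dead_time_limit(self):
        st, fit = self._stats_and_fit()
        out = missed_events_correction(st, fit, 1e-9)
        assert out.tau_open_corrected == pytest.approx(1e-2, rel=1e-5)

    def test_hand_value(self):
        st, fit = self._stats_and_fit()
        out = missed_events_correction(st, fit, 2e-4)
        n_miss = 1000 * (np.exp(0.2) - 1)
        assert n_miss == pytest.approx(221.4, abs=0.1)
        assert out.tau_open_corrected == pytest.approx(
            1001 * 1e-2 / (1001 + n_miss), rel=1e-6)

    def test_warns_when_dead_time_too_long(self):
        st, fit = self._stats_and_fit(tau_c=1e-4)
        with pytest.warns(UserWarning):
            missed_events_correction(st, fit, 2e-4)
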