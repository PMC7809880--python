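"""Reusable study protocols: end-to-end recovery experiments.

These functions wire the pipeline stages together into the standard in
silico experiments: generate-and-refit checks for the dose-response and
Boltzmann models, the simulate -> detect -> I/V conductance study for an
ohmic channel, and the simulate -> detect -> dwell-statistics recovery for
the reference three-slow-state scheme.  Analysis drivers, tests and the
reproduction script all run these.
"""

from __future__ import annotations

import numpy as np

from .curves import (BoltzmannFit, DoseResponseFit, IVFit, boltzmann,
                     conductance_from_iv, dose_response, fit_boltzmann,
                     fit_dose_response)
from .detect import estimate_open_current, hinkley_detect
from .dwell import StateStatistics, analyze_events
from .schemes import GatingScheme, stationary_probabilities
from .simulate import SimulationConfig, simulate_trace

__all__ = ["boltzmann_refit", "dose_response_refit", "ohmic_iv_study",
           "slow_gating_study", "REFERENCE_SLOW_SCHEME", "reference_slow_scheme"]

#: entry/exit rates of the reference slow scheme: closed lifetimes of
#: 1 ms (C1), 20 ms (C2) and 300 ms (C3) with distinct entry rates
REFERENCE_SLOW_SCHEME = {"C1": (50.0, 1000.0), "C2": (5.0, 50.0),
                         "C3": (0.5, 1.0 / 0.3)}


def reference_slow_scheme(i_true: float = 11.0) -> GatingScheme:
    return GatingScheme(REFERENCE_SLOW_SCHEME, i_true=i_true)


def boltzmann_refit(p_max: float, p_min: float, z: float, v_half: float,
                    v_start: float = -160.0, v_stop: float = 160.0,
                    v_step: float = 20.0) -> BoltzmannFit:
    """Generate a noiseless P_O/V curve from the Boltzmann model and refit it.

    All four parameters are free in the refit; recovering the generating
    V_1/2 and z validates the fitting route used on measured P_O/V data.
    """
    v = np.arange(v_start, v_stop + v_step / 2, v_step)
    p = boltzmann(v, p_max, p_min, z, v_half)
    return fit_boltzmann(v, p)


def dose_response_refit(y_max: float, k: float, y_0: float,
                        doses=(0.0, 5.0, 10.0, 20.0, 30.0, 50.0, 100.0)
                        ) -> DoseResponseFit:
    """Generate a noiseless saturating-exponential dose series and refit it."""
    x = np.asarray(doses, float)
    return fit_dose_response(x, dose_response(x, y_max, k, y_0))


def ohmic_iv_study(conductance_ps: float = 92.0, seed: int = 0,
                   duration: float = 8.0, noise_sd: float = 0.8,
                   voltages: np.ndarray | None = None,
                   slow_rates: tuple[float, float] = (10.0, 50.0)) -> IVFit:
    """Simulate -> detect -> I/V slope for an ohmic slow-gating channel.

    At each protocol voltage an independent trace is simulated with
    I_true = G*V, idealized with the Hinkley detector, and the open-channel
    current estimated from the detected open sojourns; the conductance is
    the OLS slope of those currents against voltage.
    """
    if voltages is None:
        voltages = np.concatenate([np.arange(-160.0, -39.0, 20.0),
                                   np.arange(40.0, 161.0, 20.0)])
    ss = np.random.SeedSequence(seed)
    currents = []
    for v, child in zip(voltages, ss.spawn(len(voltages))):
        i_true = abs(conductance_ps * v) * 1e-3
        scheme = GatingScheme({"C2": slow_rates}, i_true=i_true)
        cfg = SimulationConfig(duration=duration, noise_sd=noise_sd,
                               voltage=float(v), oversample=10,
                               seed=int(child.generate_state(1)[0] % (2**31)))
        trace = simulate_trace(scheme, cfg)
        currents.append(estimate_open_current(trace))
    return conductance_from_iv(voltages, np.array(currents))


def slow_gating_study(seed: int = 0, duration: float = 600.0,
                      noise_sd: float = 0.8, voltage: float = 120.0,
                      scheme: GatingScheme | None = None
                      ) -> tuple[StateStatistics, dict]:
    """Simulate -> detect -> dwell statistics for the reference slow scheme.

    Returns the recovered state statistics together with the analytic truth
    (stationary occupancies and mean lifetimes) for comparison.
    """
    if scheme is None:
        scheme = reference_slow_scheme()
    cfg = SimulationConfig(duration=duration, noise_sd=noise_sd,
                           voltage=voltage, oversample=10,
                           seed=int(np.random.SeedSequence(seed)
                                    .generate_state(1)[0] % (2**31)))
    trace = simulate_trace(scheme, cfg)
    events = hinkley_detect(trace)
    stats, closed_fit, open_fit = analyze_events(events)
    stat = stationary_probabilities(scheme)
    truth = {
        "P": dict(stat.probabilities),
        "tau": {"O": 1.0 / scheme.total_exit_from_open,
                **{c: 1.0 / scheme.exit_rate(c) for c in scheme.closed_states}},
    }
    return stats, {"truth": truth, "closed_fit": closed_fit,
                   "open_fit": open_fit, "n_events": len(events)}
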