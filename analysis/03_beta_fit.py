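#!/usr/bin/env python
"""Extended beta-distribution analysis of fast gating.

Simulates a 120-s recording of a channel with sub-millisecond O-M gating
(2000/6000 s^-1), microsecond O-F gating (gating factor 0.9) and a merged
slow state S (occupancy ~0.1) at I_true = 6 pA with 0.8 pA setup noise,
then recovers I_true and the six rate constants by fitting the amplitude
histogram with simulated, noise-convolved candidates.  Writes
results/beta_fit.csv.  Runtime is a few minutes (the objective simulates a
filtered trace per evaluation).
"""

from pathlib import Path

import pandas as pd

from kcvgate import SimulationConfig, simulate_trace
from kcvgate.amphist import (BetaFitResult, NoiseModel,
                             build_amplitude_histogram, fit_beta)

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"
SEED = 5

TRUTH = BetaFitResult(i_true=6.0, k_om=2000.0, k_mo=6000.0,
                      k_of=1000.0, k_fo=9000.0, k_os=5.0, k_so=30.0)

def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    cfg = SimulationConfig(duration=120.0, sampling_rate=5000.0, oversample=40,
                           noise_sd=0.8, voltage=120.0, seed=SEED)
    trace = simulate_trace(TRUTH.scheme(), cfg)
    hist = build_amplitude_histogram(trace, 0.1)
    init = BetaFitResult(i_true=5.2, k_om=3000.0, k_mo=4500.0, k_of=1500.0,
                         k_fo=6000.0, k_os=8.0, k_so=20.0)
    cfg_eval = SimulationConfig(duration=120.0, sampling_rate=5000.0,
                                oversample=40, noise_sd=0.0, voltage=120.0,
                                seed=SEED)
    res = fit_beta(hist, NoiseModel(sd=0.8), init, cfg_eval,
                   sim_duration=10.0, n_restarts=2, maxiter=300, seed=99)
    rows = []
    for name in ("i_true", "k_om", "k_mo", "k_of", "k_fo", "k_os", "k_so"):
        rows.append({"parameter": name, "true": getattr(TRUTH, name),
                     "fitted": getattr(res, name)})
    rows.append({"parameter": "gating_factor", "true": TRUTH.gating_factor,
                 "fitted": res.gating_factor})
    df = pd.DataFrame(rows)
    df["rel_error_pct"] = 100 * (df.fitted / df.true - 1)
    df.to_csv(RESULTS / "beta_fit.csv", index=False)
    print(df.to_string(index=False, float_format=lambda x: f"{x:.4g}"))
    print(f"\nchi-square objective {res.objective:.1f} after {res.n_eval} "
          f"evaluations")
    print("note: the O-F rates individually sit at the edge of the temporal "
          "resolution; their ratio (the gating factor) is the robust readout")

if __name__ == "__main__":
    main()
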