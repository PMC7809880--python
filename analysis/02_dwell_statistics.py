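#!/usr/bin/env python
"""Dwell-time analysis of slow gating on a long synthetic recording.

Runs simulate -> Hinkley idealization -> log-binned dwell histograms ->
exponential-mixture fits with adjusted-R^2 model selection -> occupation
probabilities / switching frequencies -> missed-events correction, on a
600-s trace of the reference three-slow-state scheme, and compares every
recovered quantity with its analytic value.  Writes
results/dwell_statistics.csv.
"""

from pathlib import Path

import pandas as pd

from kcvgate.protocols import slow_gating_study

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"
SEED = 11

def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    stats, info = slow_gating_study(seed=SEED, duration=600.0)
    truth = info["truth"]
    rows = []
    for s in stats.states:
        row = {"state": s,
               "P_recovered": stats.probabilities[s],
               "tau_recovered_s": stats.lifetimes[s],
               "f_recovered_per_s": stats.frequencies[s]}
        if s in truth["P"]:
            row["P_true"] = truth["P"][s]
            row["tau_true_s"] = truth["tau"][s]
        rows.append(row)
    df = pd.DataFrame(rows)
    df.to_csv(RESULTS / "dwell_statistics.csv", index=False)
    print(df.to_string(index=False, float_format=lambda x: f"{x:.4g}"))
    print(f"\n{info['n_events']} events idealized; "
          f"closed fit used {info['closed_fit'].n_components} components "
          f"(R2_adj = {info['closed_fit'].r2_adj:.4f})")
    print(f"corrected mean open lifetime: {stats.tau_open_corrected*1e3:.2f} ms "
          f"(raw {stats.lifetimes['O']*1e3:.2f} ms, "
          f"analytic {truth['tau']['O']*1e3:.2f} ms)")

if __name__ == "__main__":
    main()
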