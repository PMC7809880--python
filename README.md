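# kcvgate

Single-channel gating analysis for small viral K⁺ channels (Kcv/Kmpv
family) recorded in planar lipid bilayers — the tool chain needed to ask
how bilayer composition (cholesterol, anionic phospholipids) changes
unitary conductance and gating.

Single-channel currents mix processes on very different time scales: slow
closures (milliseconds to seconds) appear as resolved shut levels, while
fast gating in the selectivity filter (microseconds to sub-milliseconds) is
smeared out by the recording filter and only survives as excess noise and a
reduced apparent current.  `kcvgate` covers both regimes plus the
curve-level summaries:

* **Kinetic model** — star-topology Markov schemes: one open state O,
  closed states F, M (fast) and C1…C4 / S (slow), each reachable only from
  O.  Stationary occupancies `P_X = P_O·k_OX/k_XO` and lifetimes
  `τ_X = 1/k_XO` are available in closed form.
* **Synthetic recordings** — exact-jump-time simulation, 4th-order Bessel
  low-pass (−3 dB at 1 kHz), decimation to 5 kHz, recorder noise; fully
  seeded and bit-reproducible.
* **Idealization** — two-sided Hinkley (cusum) detector with dead-time
  censoring.
* **Dwell-time statistics** — log-binned histograms, 1–3-exponential
  mixture fits selected by adjusted R²
  (`R²_adj = 1 − (1−R²)(n−1)/(n−p−1)`), a threshold rule for rare
  long-lived states, occupation probabilities
  `P_Ci = N_Ci·τ_Ci / (N_O·τ_O + Σ N_Cj·τ_Cj)`, switching frequencies
  `f_Ci = P_Ci/τ_Ci` (with `f_O = Σ f_Ci`), and a missed-events correction
  of the mean open lifetime.
* **Extended β-distribution analysis** — amplitude histograms of filtered
  4-state gating are predicted by simulation, convolved with the setup
  noise, and a simplex search recovers the true open-channel current
  I_true, the O-M rate constants and the O-F gating factor
  `k_FO/(k_FO+k_OF)`.
* **Curve fits** — saturating-exponential dose response
  `Y = Y_max(1−e^(−X/k)) + Y_0`, Boltzmann voltage activation
  `P_O = (P_O,max−P_O,min)/(1+exp(zF(V_1/2−V)/RT)) + P_O,min`, I/V slope
  conductance, and arithmetic/geometric summary statistics.

See `docs/methods.md` for the models, numerical choices and limitations.

## Worked example

Recover the slow-gating structure of a channel with three closed states
(lifetimes 1 ms, 20 ms, 300 ms) from a simulated 600-s recording at
+120 mV:

```python
from kcvgate.protocols import slow_gating_study

stats, info = slow_gating_study(seed=11, duration=600.0)
```

which is what `analysis/02_dwell_statistics.py` runs; it prints

```
state  P_recovered  tau_recovered_s  f_recovered_per_s  P_true  tau_true_s
    O       0.7764          0.02498              38.02  0.7692     0.01802
   C1      0.03799          0.00112              33.93 0.03846       0.001
   C2      0.07857           0.0211              3.723 0.07692        0.02
   C3       0.1071           0.2961             0.3617  0.1154         0.3

36894 events idealized; closed fit used 3 components (R2_adj = 0.9656)
corrected mean open lifetime: 17.81 ms (raw 24.98 ms, analytic 18.02 ms)
```

Reading this: the three closed lifetimes come back within ~5–12 % and the
occupancies within ~10 %.  The raw mean open time (24.98 ms) overshoots the
true 18.02 ms because sub-millisecond closures below the 0.34-ms dead time
go undetected and silently fuse open sojourns; the missed-events correction
brings it back to 17.81 ms.

The other drivers follow the same pattern: `analysis/01_simulate_recordings.py`
generates the voltage-protocol traces (into `scratch/`),
`analysis/03_beta_fit.py` recovers I_true and fast-gating rates from an
amplitude histogram, and `analysis/04_curve_fits.py` runs the fold-change,
Boltzmann, dose-response and pipeline-conductance analyses (tables under
`results/`).

A `kcvgate` command-line interface mirrors the stages
(`simulate`, `detect`, `dwell`, `betafit`, `fitcurves`, `report`); run
`kcvgate --help`.

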