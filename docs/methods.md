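# Methods

`kcvgate` implements the complete single-channel analysis chain used to
quantify lipid effects on small viral K⁺ channels: stochastic simulation of
gating, recording-chain emulation, event idealization, dwell-time
statistics, amplitude-histogram inference of unresolved fast gating, and
the curve-level fits (dose-response, Boltzmann, I/V).  This note describes
the models, the numerical choices, and what the synthetic-data tests do and
do not demonstrate.

## Gating model

Gating is modelled as a continuous-time Markov chain on a *star* topology:
one conducting open state O and a set of closed states each connected only
to O.  Closed states fall into two kinetic classes:

* **fast** — F (microsecond) and M (sub-millisecond), faster than the
  recording filter; they never appear as resolved closures and manifest
  only as excess noise and apparent-current reduction;
* **slow** — C1…C4 and the merged representative S, resolved as discrete
  closures by a level detector.

Rates are per-voltage constants in s⁻¹ (`k_OX` entry, `k_XO` exit); no
voltage-dependent rate law is modelled because the experimental analysis is
per-voltage.  For a star scheme detailed balance holds on every edge, so
the stationary distribution is `P_X = P_O · k_OX / k_XO` with `P_O` fixed by
normalization; mean lifetimes are `τ_O = 1/Σ_X k_OX` and `τ_X = 1/k_XO`.
These closed forms are the ground truth against which every estimator is
tested.

Merging the slow states into S (needed for amplitude-histogram analysis,
which cannot distinguish them) uses `k_OS = Σ k_OCi` and
`k_SO = k_OS · P_O / P_S`.  The exit rate is chosen to preserve the total
slow occupancy exactly; the individual `k_SO` components are not separately
identifiable from the histogram, so occupancy preservation is the natural
constraint.  Closed-level current is 0 pA by convention and the open level
carries the sign of the holding voltage, so negative-voltage traces show
downward openings.

## Synthetic recordings

`simulate_trace` emulates the recording chain of a planar-bilayer setup:

1. **Path** — exact-jump-time (Gillespie) simulation: sojourns are
   exponential with the summed exit rate; from O the sink closed state is
   drawn with probability `k_OX / Σ k_OY`.
2. **Render** — piecewise-constant current on an oversampled grid
   (default 50× the sampling rate); each grid interval takes the level of
   the state occupying the majority of the interval, computed exactly from
   the cumulative open-time integral (ties count as open).  The
   oversampled rate should exceed ~20× the fastest rate constant; a warning
   is raised otherwise.
3. **Filter** — digital 4th-order Bessel low-pass (−3 dB at the cutoff,
   magnitude-normalized, bilinear transform with prewarping via
   `scipy.signal.bessel`), applied causally at the oversampled rate so that
   sub-sample gating shapes the histogram the way an analog filter shapes a
   continuous current.  The 10–90 % step rise time is ≈ 0.34/f_c (0.34 ms
   at 1 kHz).
4. **Decimate** — simple subsampling to the acquisition rate (the Bessel
   filter is the anti-alias stage), default 5 kHz after 1-kHz filtering.
5. **Noise** — white zero-mean Gaussian recorder noise added after
   decimation (default), with an option for band-limited pre-filter noise.
   The amplitude-histogram fit convolves with a noise histogram instead of
   relying on this choice, so inference is insensitive to it.

All randomness derives from one seed through named substreams
(`numpy.random.SeedSequence`); identical inputs give bit-identical traces.

Default study conditions mirror the experimental protocol: voltages from
+160 to −160 mV in 20-mV steps, 5 kHz / 1 kHz sampling/filtering
(10 kHz / 1 kHz for the contact-bubble configuration), unitary conductances
of a few tens to ~200 pS, and recorder noise of 0.8 pA SD — a typical value
for this class of recordings, chosen once and used throughout.

What the generator does **not** emulate: capacitive transients, baseline
drift, 50/60-Hz pickup, multi-channel membranes, and voltage-dependent rate
laws.  Tests passing on these synthetic traces therefore demonstrate the
correctness of the estimators under the stated model, not robustness to
every artifact of real recordings.

## Event idealization (Hinkley detector)

Slow gating is idealized with a two-sided cumulative-sum (Hinkley) jump
detector run against the midline between the closed and open levels.  In
the correct state the cusum drifts away from the midline sum; after a level
change it reverses, and a jump is called when the excursion from the
running extremum exceeds the threshold λ.  The jump time is assigned to the
extremum sample, which coincides with the midline crossing — dwell
durations therefore carry no detection-delay bias.  The constant 50 %
step-response delay of the Bessel filter is subtracted from all jump times.

Parameter defaults (two-pass): levels from the two dominant amplitude-
histogram modes, refined once from the means over detected sojourns
(sojourn edges trimmed by 0.25 ms against filter transients); noise SD from
the median absolute first difference; λ = 5 σ (pA·samples), which keeps the
false-positive rate on pure noise below one event per 10⁶ samples whenever
the level separation exceeds ≈ 3 σ while resolving events close to one
sample; dead time = the filter rise time (0.34 ms at 1 kHz).  Sojourns
shorter than the dead time are merged into their flanking sojourns
(shortest first, via a heap over a linked event list; the operation is
idempotent).  The detector is two-level; multi-conductance idealization is
out of scope.

Closures shorter than roughly half the filter rise time never cross the
midline and are invisible in principle — this is exactly the missed-events
regime the correction below addresses.

## Dwell-time statistics

Dwell-time histograms use logarithmic bins (10 per decade) from the dead
time to the longest observed duration.  Because detected durations are
quantized to the sampling interval, bin edges are snapped onto the
half-sample grid whenever the quantum exceeds half the narrowest bin —
otherwise empty alias bins corrupt the fit.

Open-time histograms are fitted with one exponential; closed-time
histograms with two and three.  The fit minimizes Poisson-weighted least
squares (weights `1/max(count, 1)`) of the expected bin counts
`N_i (e^(−t_lo/τ_i) − e^(−t_hi/τ_i))`, with parameters in log space and two
starting points (event-quantile taus and log-spaced taus).  `N_i` is thus
the *extrapolated* total event count of component i, including events below
the dead time.  R² is computed on the same weighted residuals — the
weighted form is what makes the adjusted-R² model selection sensitive to
sparsely populated long-lived components.  Model choice takes the larger
`R²_adj = 1 − (1−R²)(n−1)/(n−p−1)`; ties go to fewer components.

Long-lived states too rare to fit are handled by the threshold rule: scan
bin edges left to right, starting from the peak of the fitted expected
counts (ahead of the peak, sparse leading bins of a log grid can predict
< 1 event without meaning anything), for the first edge t\* whose following
bin is predicted to hold less than one event; all observed events longer
than t\* form one additional component with their count and arithmetic-mean
lifetime, subsequently treated as if fitted.  On clean data this can append
a tiny spurious component (a few tail events of the longest fitted state);
it is reported as estimated-by-averaging and its occupancy is negligible.

Occupation probabilities and switching frequencies follow
`P_Ci = N_Ci τ_Ci / (N_O τ_O + Σ_j N_Cj τ_Cj)`, `P_O = 1 − Σ P_Ci`,
`f_Ci = P_Ci / τ_Ci`, and `f_O = Σ f_Ci` (every closed state is entered
from the single open state).  The identities `Σ P = 1` and `f_O = Σ f_Ci`
hold by construction and are asserted.

The missed-events correction extrapolates each fitted closed component
below the dead time, `N_miss,i = N_i (e^(t_d/τ_i) − 1)`, and corrects the
open lifetime as `τ_O,corr = N_O τ_O / (N_O + Σ N_miss,i)` — each missed
closure rejoins two measured open sojourns that were counted as one.  This
is a deliberately simple first-order correction (flagged as approximate in
the exports), not an exact missed-event likelihood; on the reference
scheme it moves τ_O from ≈ +39 % error to within a few percent.

## Amplitude-histogram (extended β-distribution) analysis

Fast gating attenuates and distorts the open peak of the all-point
amplitude histogram.  For the 4-state {O, F, M, S} scheme filtered by a
4th-order Bessel filter no practical analytic histogram exists, so
predicted histograms are *simulated*: a noiseless filtered trace of the
candidate scheme is generated, histogrammed on the measured bin grid
(padded by the kernel half-width), convolved with the setup-noise histogram
(empirical, or Gaussian of given SD), and rescaled to the measured total
count.

The search minimizes a Pearson χ² with pooled tails (interior bins require
an expected count ≥ 5) over I_true and the six rate constants (rates in log
space) with a Nelder–Mead simplex, restarted twice from perturbed points.
Every objective evaluation reuses the same simulation seed (common random
numbers), making the objective deterministic and effectively continuous in
the parameters.  Per-evaluation simulations use a 10-s trace at 40×
oversampling (200 kHz), rescaled to the measured count — the histogram
shape converges long before the measured 120-s length, and this keeps a
full fit in the minutes range on one core.

Robust readouts at the reference signal-to-noise ratio (I_true = 6 pA,
noise 0.8 pA): I_true to a few percent, the O-M rates to ~10–20 %, and the
O-F *gating factor* `k_FO/(k_FO + k_OF)` to a few hundredths.  The
individual O-F rates sit at the edge of the temporal resolution and are not
separately well determined — only their ratio is, which is why the gating
factor is the reported quantity for microsecond gating.

## Curve-level fits

* **Dose-response**: `Y = Y_max (1 − e^(−X/k)) + Y_0`, least squares via
  `scipy.optimize.curve_fit`.  The equation is implemented exactly in this
  form; note that under it the half-maximal increase occurs at `X = k ln 2`,
  not at `X = k`.  Both `k` (the headline dose constant) and `k ln 2` are
  reported, along with the fold increase `(Y_0 + Y_max)/Y_0`.  Under noise,
  `k` and `Y_max` trade off strongly with only a 7-point dose series; the
  identifiable quantities are the fitted curve and the fold increase
  (within ~5 % at 5 % multiplicative noise), and the tests assert those.
* **Boltzmann**: `P_O = (P_O,max − P_O,min)/(1 + exp(zF(V_1/2 − V)/RT)) +
  P_O,min`, all four parameters free, bounded `0 ≤ P_O,min` and
  `P_O,max ≤ 1`; T defaults to 295 K.  Noiseless generate-and-refit is
  exact to numerical precision; at 5 % noise the median V_1/2 error is
  ≈ 2 mV.
* **I/V conductance**: ordinary least-squares slope of open-channel current
  vs voltage over |V| ∈ [40, 160] mV (slope conductance; the low-voltage
  points are excluded because their absolute currents approach the noise).
  Open-channel currents come from the detector's refined open-level means.
* **Summary statistics**: arithmetic and geometric mean ± SD; geometric
  statistics are used when aggregating lifetimes and occupancies across
  replicates, matching the skewed distributions of those quantities.
  `ttest`/`anova` are thin `scipy.stats` wrappers for table-style
  comparisons; no multiple-testing correction is applied.

## Problem sizes and reproducibility

The packaged studies use: 600 s for the three-slow-state dwell recovery
(≈ 37 000 events), 8 s per voltage for the I/V pipeline (14 voltages), 100-s
paths × 20 seeds for occupancy checks, and a 120-s measured trace for the
β-distribution recovery.  These sizes put Monte-Carlo error comfortably
inside the assertion tolerances (lifetimes within 15 %, occupancies within
20 %, I_true within 5 %, O-M rates within 20 %, conductance within 5 %)
while keeping the full suite in the minutes range.  Every stochastic step
takes an explicit seed, and `scripts/acceptance.py --seed N` reproduces the
headline numbers deterministically for any N.

## Known limitations

* The detector and dwell pipeline assume a single channel with two current
  levels; superimposed channels or subconductances are not handled.
* The missed-events correction is first order; for dead times approaching
  the shortest closed lifetime it degrades (a warning is raised).
* The rare-state rule can append a negligible spurious component fed by the
  tail of the longest fitted exponential.
* β-distribution fits need ≥ 10⁵ samples and a sufficient signal-to-noise
  ratio; at low SNR the O-F branch is unidentifiable (as in the
  experimental analyses, where low-voltage points are dropped).
* Dose-response `k` is reported as fitted but is poorly identified from
  few-point noisy dose series — compare fold changes or fitted curves, not
  raw `k`, across conditions.
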