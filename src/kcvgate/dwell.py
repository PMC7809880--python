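"""Dwell-time statistics of slow gating.

From an idealized event list this module builds log-binned dwell-time
histograms, fits them with mixtures of 1-3 exponential components by
weighted least squares, selects the number of components by the adjusted
coefficient of determination

    R_adj^2 = 1 - (1 - R^2) (n - 1) / (n - p - 1),

estimates rare long-lived closed states that a fit cannot resolve (events
beyond the dwell time where the fitted mixture predicts less than one event
in the next bin are pooled and averaged), converts component counts and
lifetimes into occupation probabilities

    P_Ci = N_Ci tau_Ci / (N_O tau_O + sum_j N_Cj tau_Cj)

and switching frequencies f_Ci = P_Ci / tau_Ci (with f_O = sum_i f_Ci, since
every closed state is entered from the single open state), and applies a
simple missed-events correction to the mean open lifetime.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .detect import EventList

__all__ = [
    "DwellTimeHistogram", "ExponentialMixtureFit", "StateStatistics",
    "build_histogram", "fit_exponential_mixture", "adjusted_r2",
    "select_model", "estimate_rare_state", "occupation_probabilities",
    "missed_events_correction", "analyze_events",
]


@dataclass(frozen=True)
class DwellTimeHistogram:
    """Log-binned dwell-time histogram of one state."""

    state: str
    edges: np.ndarray        # s, strictly increasing
    counts: np.ndarray
    total: int

    def __post_init__(self) -> None:
        if np.any(np.diff(self.edges) <= 0):
            raise ValueError("bin edges must be strictly increasing")
        if np.any(np.asarray(self.counts) < 0):
            raise ValueError("counts must be non-negative")
        if int(np.sum(self.counts)) != self.total:
            raise ValueError("counts must sum to the total event count")

    @property
    def centers(self) -> np.ndarray:
        return np.sqrt(self.edges[:-1] * self.edges[1:])   # geometric centers


@dataclass(frozen=True)
class ExponentialMixtureFit:
    """Exponential mixture fitted to a dwell-time histogram.

    ``amplitudes[i]`` is the total (extrapolated) number of events N_i of
    component i; ``taus[i]`` its mean dwell time in seconds.  Components are
    ordered by tau ascending.
    """

    amplitudes: np.ndarray
    taus: np.ndarray
    r2: float
    r2_adj: float
    n_points: int
    n_params: int
    estimated: np.ndarray = field(default_factory=lambda: np.array([], dtype=bool))

    def __post_init__(self) -> None:
        if np.any(self.taus <= 0) or np.any(self.amplitudes <= 0):
            raise ValueError("component amplitudes and taus must be positive")
        if np.any(np.diff(self.taus) < 0):
            raise ValueError("components must be ordered by tau ascending")

    @property
    def n_components(self) -> int:
        return len(self.taus)

    def expected_counts(self, edges: np.ndarray) -> np.ndarray:
        return _mixture_counts(edges, self.amplitudes, self.taus)


@dataclass(frozen=True)
class StateStatistics:
    """Per-state occupation probabilities, lifetimes and switching frequencies."""

    states: list[str]                 # ["O", "C1", ...]
    probabilities: dict[str, float]
    lifetimes: dict[str, float]       # s
    counts: dict[str, float]
    frequencies: dict[str, float]     # s^-1
    tau_open_corrected: float | None = None

    def __post_init__(self) -> None:
        total = sum(self.probabilities.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError("state probabilities must sum to 1")


def build_histogram(events: EventList | np.ndarray, state: str = "closed",
                    bins_per_decade: int = 10,
                    t_min: float | None = None) -> DwellTimeHistogram:
    """Log-spaced dwell-time histogram from an event list or duration array.

    Bins span [t_min, max duration] at ``bins_per_decade`` bins per decade;
    ``t_min`` defaults to the detector dead time when available, else the
    shortest duration.
    """
    if isinstance(events, EventList):
        durations = events.durations_of(state)
        if t_min is None:
            t_min = events.meta.get("dead_time")
    else:
        durations = np.asarray(events, float)
    if durations.size == 0:
        raise ValueError(f"no events of state {state!r}")
    if t_min is None or t_min <= 0:
        t_min = float(durations.min())
    t_max = float(durations.max())
    if t_max <= t_min:
        t_max = t_min * 10 ** (1.0 / bins_per_decade)
    n_bins = max(1, int(np.ceil(np.log10(t_max / t_min) * bins_per_decade)))
    edges = t_min * 10 ** (np.arange(n_bins + 1) / bins_per_decade)
    edges[-1] = max(edges[-1], t_max * (1 + 1e-12))
    # durations measured from a sampled trace are quantized to the sample
    # interval; snap edges onto the half-sample grid so that no log bin is
    # narrower than one quantum (aliasing would corrupt the mixture fit)
    uniq = np.unique(durations[durations < np.quantile(durations, 0.5)])
    diffs = np.diff(uniq)
    diffs = diffs[diffs > 1e-6 * t_min]     # ignore float jitter
    if len(diffs) > 1:
        quantum = float(np.median(diffs))
        if quantum > 0 and quantum > 0.5 * float(np.min(np.diff(edges))):
            snapped = (np.floor(edges / quantum) + 0.5) * quantum
            snapped[-1] = max(snapped[-1], t_max * (1 + 1e-12))
            edges = np.unique(snapped)
    counts, _ = np.histogram(durations, bins=edges)
    inside = (durations >= edges[0]) & (durations <= edges[-1])
    return DwellTimeHistogram(state if isinstance(events, EventList) else "closed",
                              edges, counts, int(inside.sum()))


def _mixture_counts(edges, amplitudes, taus):
    """Expected bin counts of an exponential mixture (N_i total events each)."""
    lo = edges[:-1][:, None]
    hi = edges[1:][:, None]
    a = np.asarray(amplitudes)[None, :]
    t = np.asarray(taus)[None, :]
    return np.sum(a * (np.exp(-lo / t) - np.exp(-hi / t)), axis=1)


def adjusted_r2(r2: float, n: int, p: int) -> float:
    """Adjusted coefficient of determination; may be negative."""
    if p < 1:
        raise ValueError("p must be at least 1")
    if n <= p + 1:
        raise ValueError("need n > p + 1 data points")
    return 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)


def fit_exponential_mixture(hist: DwellTimeHistogram,
                            m: int) -> ExponentialMixtureFit:
    """Weighted least-squares fit of an m-component exponential mixture.

    Expected bin counts are compared with observed counts under Poisson
    weights max(count, 1); parameters are optimized in log space to keep
    N_i and tau_i positive.  R^2 is computed on the raw counts.
    """
    if m not in (1, 2, 3):
        raise ValueError("m must be 1, 2 or 3")
    edges, counts = hist.edges, np.asarray(hist.counts, float)
    n = len(counts)
    p = 2 * m
    if np.count_nonzero(counts) <= p:
        raise ValueError("not enough occupied bins for the requested components")
    if n <= p + 1:
        raise ValueError("not enough bins for the requested components")

    # multi-start: event-quantile taus and log-spaced taus across the range
    centers = hist.centers
    rep = np.repeat(centers, counts.astype(int))
    qs = np.quantile(np.log(rep), [(2 * i + 1) / (2 * m) for i in range(m)])
    inits = [np.exp(qs) * (1.0 + 1e-6 * np.arange(m))]
    if m > 1:
        inits.append(np.geomspace(2.0 * edges[0], edges[-1] / 3.0, m))
    amp0 = np.full(m, max(hist.total / m, 1.0))

    w = 1.0 / np.sqrt(np.maximum(counts, 1.0))

    def resid(x):
        a = np.exp(x[:m])
        t = np.exp(x[m:])
        return (_mixture_counts(edges, a, t) - counts) * w

    sol = None
    for tau0 in inits:
        x0 = np.log(np.concatenate([amp0, tau0]))
        s = least_squares(resid, x0, method="lm", max_nfev=20000)
        if not s.success:
            s = least_squares(resid, x0, method="trf", max_nfev=20000)
        if s.success and (sol is None or s.cost < sol.cost):
            sol = s
    if sol is None:
        raise RuntimeError("mixture fit did not converge")
    a = np.exp(sol.x[:m])
    tau = np.exp(sol.x[m:])
    order = np.argsort(tau)
    a, tau = a[order], tau[order]
    fitted = _mixture_counts(edges, a, tau)
    # R^2 on the Poisson-weighted residuals, consistent with the fit metric
    w2 = w ** 2
    ybar = float(np.sum(w2 * counts) / np.sum(w2))
    ss_res = float(np.sum(w2 * (counts - fitted) ** 2))
    ss_tot = float(np.sum(w2 * (counts - ybar) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    if ss_res < 1e-12 * max(1.0, float(np.sum(counts ** 2))):
        r2 = 1.0
    return ExponentialMixtureFit(a, tau, r2, adjusted_r2(r2, n, p), n, p,
                                 estimated=np.zeros(m, dtype=bool))


def select_model(fit_a: ExponentialMixtureFit,
                 fit_b: ExponentialMixtureFit) -> ExponentialMixtureFit:
    """Pick the fit with the larger adjusted R^2; ties go to fewer components."""
    if fit_a.r2_adj > fit_b.r2_adj:
        return fit_a
    if fit_b.r2_adj > fit_a.r2_adj:
        return fit_b
    return fit_a if fit_a.n_components <= fit_b.n_components else fit_b


def estimate_rare_state(durations: np.ndarray, hist: DwellTimeHistogram,
                        fit: ExponentialMixtureFit):
    """Detect an under-represented long-lived closed state.

    Scans bin edges left to right for the first dwell time t* beyond which
    the fitted mixture predicts fewer than one event in the following bin;
    all observed events longer than t* are pooled into one extra component
    with their count and arithmetic-mean lifetime.  Returns the augmented
    fit, or the original fit when no such events exist.
    """
    durations = np.asarray(durations, float)
    expected = fit.expected_counts(hist.edges)
    # scan left -> right, starting where the fitted mixture has its mass
    # (ahead of it, sparse leading bins of a log grid may predict < 1 event
    # without indicating an unresolved long-lived state)
    t_star = None
    for j in range(int(np.argmax(expected)), len(expected)):
        if expected[j] < 1.0:
            t_star = hist.edges[j]
            break
    if t_star is None:
        return fit
    long_ev = durations[durations > t_star]
    if long_ev.size == 0:
        return fit
    n_extra = float(long_ev.size)
    tau_extra = float(long_ev.mean())
    # only meaningful when clearly beyond the fitted components
    if tau_extra <= fit.taus[-1]:
        return fit
    a = np.append(fit.amplitudes, n_extra)
    tau = np.append(fit.taus, tau_extra)
    est = np.append(fit.estimated if fit.estimated.size else
                    np.zeros(fit.n_components, dtype=bool), True)
    return ExponentialMixtureFit(a, tau, fit.r2, fit.r2_adj,
                                 fit.n_points, fit.n_params, estimated=est)


def occupation_probabilities(open_stats: tuple[float, float],
                             closed_stats: list[tuple[float, float]],
                             labels: list[str] | None = None) -> StateStatistics:
    """Occupation probabilities and switching frequencies from dwell fits.

    ``open_stats`` is (N_O, tau_O); ``closed_stats`` is a list of
    (N_Ci, tau_Ci).  P_Ci = N_Ci tau_Ci / (N_O tau_O + sum N_Cj tau_Cj);
    P_O is the complement; f_Ci = P_Ci / tau_Ci and f_O = sum f_Ci.
    """
    n_o, tau_o = open_stats
    if n_o <= 0 or tau_o <= 0 or any(n <= 0 or t <= 0 for n, t in closed_stats):
        raise ValueError("all event counts and lifetimes must be positive")
    if labels is None:
        labels = [f"C{i + 1}" for i in range(len(closed_stats))]
    denom = n_o * tau_o + sum(n * t for n, t in closed_stats)
    probs = {lab: n * t / denom for lab, (n, t) in zip(labels, closed_stats)}
    probs["O"] = 1.0 - sum(probs.values())
    lifetimes = {"O": tau_o, **{lab: t for lab, (_, t) in zip(labels, closed_stats)}}
    counts = {"O": float(n_o), **{lab: float(n) for lab, (n, _) in zip(labels, closed_stats)}}
    freqs = {lab: probs[lab] / lifetimes[lab] for lab in labels}
    freqs["O"] = sum(freqs.values())
    return StateStatistics(["O", *labels], probs, lifetimes, counts, freqs)


def missed_events_correction(stats: StateStatistics,
                             fit: ExponentialMixtureFit,
                             dead_time: float) -> StateStatistics:
    """Correct the mean open lifetime for undetected brief closures.

    Each fitted closed component is extrapolated below the dead time:
    N_miss,i = N_i (exp(t_d / tau_i) - 1).  The missed closures split open
    sojourns that were measured as single long ones, so
    tau_O,corr = N_O tau_O / (N_O + sum N_miss,i).
    """
    if dead_time <= 0:
        raise ValueError("dead time must be positive")
    if np.any(fit.taus <= dead_time):
        warnings.warn("dead time exceeds a fitted closed lifetime; the "
                      "missed-events correction is unreliable", stacklevel=2)
    n_miss = float(np.sum(fit.amplitudes * (np.exp(dead_time / fit.taus) - 1.0)))
    n_o = stats.counts["O"]
    tau_o = stats.lifetimes["O"]
    tau_corr = n_o * tau_o / (n_o + n_miss)
    return StateStatistics(stats.states, stats.probabilities, stats.lifetimes,
                           stats.counts, stats.frequencies,
                           tau_open_corrected=tau_corr)


def analyze_events(events: EventList, bins_per_decade: int = 10,
                   max_components: int = 3) -> tuple[StateStatistics,
                                                     ExponentialMixtureFit,
                                                     ExponentialMixtureFit]:
    """Full slow-gating analysis of one idealized trace.

    Open times are fitted with a single exponential; closed times with 2 and
    3 components (adjusted-R^2 selection), plus the rare-state rule for
    long-lived outliers; occupation probabilities, switching frequencies and
    the missed-events-corrected open lifetime follow.  Returns
    (statistics, closed fit, open fit).
    """
    dead = events.meta.get("dead_time", 0.0)
    open_hist = build_histogram(events, "open", bins_per_decade)
    open_fit = fit_exponential_mixture(open_hist, 1)
    closed_hist = build_histogram(events, "closed", bins_per_decade)

    fits = []
    for m in range(2, max_components + 1):
        try:
            fits.append(fit_exponential_mixture(closed_hist, m))
        except (ValueError, RuntimeError):
            pass
    if not fits:
        fits = [fit_exponential_mixture(closed_hist, 1)]
    best = fits[0]
    for f in fits[1:]:
        best = select_model(best, f)
    best = estimate_rare_state(events.durations_of("closed"), closed_hist, best)

    n_open = float(open_fit.amplitudes[0])
    tau_open = float(open_fit.taus[0])
    closed = list(zip(best.amplitudes, best.taus))
    stats = occupation_probabilities((n_open, tau_open), closed)
    if dead and dead > 0:
        stats = missed_events_correction(stats, best, dead)
    return stats, best, open_fit
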