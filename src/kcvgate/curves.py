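"""Dose-response, Boltzmann and I/V fits, and summary statistics.

Two model functions quantify lipid and voltage effects on channel function:

* a single saturating exponential for the dependence of conductance or open
  probability on the anionic-lipid content X (%),

      Y(X) = Y_max (1 - exp(-X / k)) + Y_0,

  where Y_0 is the value in the neutral bilayer, Y_max the maximal increase
  and k the dose constant (the curve reaches half of its maximal increase at
  X = k ln 2; both k and k ln 2 are reported);

* a Boltzmann function for voltage activation,

      P_O(V) = (P_O,max - P_O,min) / (1 + exp(z F (V_1/2 - V) / (R T)))
               + P_O,min,

  with apparent valence z and half-activation voltage V_1/2 (mV).

Unitary conductance is the ordinary least-squares slope of the open-channel
current/voltage relation, in pS.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from scipy.optimize import curve_fit

__all__ = [
    "FARADAY", "GAS_CONSTANT",
    "DoseResponseFit", "BoltzmannFit", "IVFit", "SummaryStats",
    "dose_response", "boltzmann", "fit_dose_response", "fit_boltzmann",
    "conductance_from_iv", "summary", "ttest", "anova",
]

FARADAY = 96485.33212      # C/mol
GAS_CONSTANT = 8.314462618  # J/(mol K)


def dose_response(x, y_max, k, y_0):
    """Saturating exponential Y = Y_max (1 - exp(-X/k)) + Y_0."""
    return y_max * (1.0 - np.exp(-np.asarray(x, float) / k)) + y_0


def boltzmann(v_mv, p_max, p_min, z, v_half_mv, temperature=295.0):
    """Boltzmann voltage activation; voltages in mV."""
    arg = z * FARADAY * (np.asarray(v_half_mv - np.asarray(v_mv, float))
                         * 1e-3) / (GAS_CONSTANT * temperature)
    return (p_max - p_min) / (1.0 + np.exp(arg)) + p_min


@dataclass(frozen=True)
class DoseResponseFit:
    y_max: float
    k: float            # % anionic lipid
    y_0: float
    x: np.ndarray
    y: np.ndarray
    residual: float

    def __post_init__(self) -> None:
        if self.k <= 0:
            raise ValueError("dose constant k must be positive")

    @property
    def half_max_dose(self) -> float:
        """Dose at half-maximal increase under the fitted curve, k ln 2."""
        return self.k * np.log(2.0)

    @property
    def fold_increase(self) -> float:
        """(Y_0 + Y_max) / Y_0: saturating value over the neutral-bilayer value."""
        return (self.y_0 + self.y_max) / self.y_0

    def predict(self, x):
        return dose_response(x, self.y_max, self.k, self.y_0)


@dataclass(frozen=True)
class BoltzmannFit:
    p_max: float
    p_min: float
    z: float
    v_half: float       # mV
    temperature: float  # K
    residual: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_min < self.p_max <= 1.0 + 1e-9):
            raise ValueError("need 0 <= P_O,min < P_O,max <= 1")

    def predict(self, v_mv):
        return boltzmann(v_mv, self.p_max, self.p_min, self.z, self.v_half,
                         self.temperature)


@dataclass(frozen=True)
class IVFit:
    conductance_ps: float
    offset_pa: float
    v_range: tuple[float, float]
    residual: float

    def predict(self, v_mv):
        return self.conductance_ps * np.asarray(v_mv, float) * 1e-3 + self.offset_pa


@dataclass(frozen=True)
class SummaryStats:
    mean: float
    sd: float
    n: int
    mode: str           # "arithmetic" | "geometric"


def fit_dose_response(x, y) -> DoseResponseFit:
    """Least-squares fit of the saturating-exponential dose response.

    Requires at least three distinct doses including 0 (the neutral bilayer
    anchors Y_0).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(np.unique(x)) < 3:
        raise ValueError("need at least three distinct doses")
    if not np.any(x == 0):
        raise ValueError("the dose series must include X = 0")
    y0 = float(np.mean(y[x == 0]))
    ymax0 = max(float(y.max() - y0), 1e-6 * max(abs(y0), 1.0))
    k0 = max(float(np.mean(x[x > 0])) / 2, 1e-6)
    try:
        popt, _ = curve_fit(dose_response, x, y, p0=[ymax0, k0, y0],
                            maxfev=20000)
    except RuntimeError as exc:
        raise RuntimeError(f"dose-response fit did not converge: {exc}") from exc
    resid = float(np.sqrt(np.mean((dose_response(x, *popt) - y) ** 2)))
    return DoseResponseFit(popt[0], popt[1], popt[2], x, y, resid)


def fit_boltzmann(v_mv, p_open, temperature: float = 295.0) -> BoltzmannFit:
    """Least-squares Boltzmann fit with all four parameters free.

    P_O,min is bounded below by 0 and P_O,max above by 1.  The fit is
    invariant to the ordering of the input voltages.
    """
    v = np.asarray(v_mv, float)
    p = np.asarray(p_open, float)
    if len(v) < 5:
        raise ValueError("need at least five voltages spanning the transition")
    if np.ptp(p) < 1e-6:
        raise ValueError("open probabilities are flat; Boltzmann fit is degenerate")

    def model(vv, p_max, p_min, z, v_half):
        return boltzmann(vv, p_max, p_min, z, v_half, temperature)

    p0 = [min(float(p.max()), 1.0), max(float(p.min()), 0.0) + 1e-6, 1.0,
          float(v[np.argmin(np.abs(p - 0.5 * (p.max() + p.min())))])]
    bounds = ([0.0, 0.0, -np.inf, -np.inf], [1.0, 1.0, np.inf, np.inf])
    popt, _ = curve_fit(model, v, p, p0=p0, bounds=bounds, maxfev=20000)
    resid = float(np.sqrt(np.mean((model(v, *popt) - p) ** 2)))
    return BoltzmannFit(popt[0], popt[1], popt[2], popt[3], temperature, resid)


def conductance_from_iv(v_mv, i_pa,
                        v_range: tuple[float, float] = (40.0, 160.0)) -> IVFit:
    """Unitary conductance as the OLS slope of open-channel I vs V.

    Points with |V| inside ``v_range`` (default 40-160 mV, both signs) enter
    the fit; the slope is reported in pS and is unaffected by a current
    offset.
    """
    v = np.asarray(v_mv, float)
    i = np.asarray(i_pa, float)
    lo, hi = v_range
    mask = (np.abs(v) >= lo) & (np.abs(v) <= hi)
    if mask.sum() < 3:
        raise ValueError("need at least three I/V points in the fit range")
    slope, offset = np.polyfit(v[mask] * 1e-3, i[mask], 1)   # pA/V = pS... in nS
    fit = slope * v[mask] * 1e-3 + offset
    resid = float(np.sqrt(np.mean((fit - i[mask]) ** 2)))
    return IVFit(float(slope), float(offset), v_range, resid)


def summary(values, mode: str = "arithmetic") -> SummaryStats:
    """Arithmetic or geometric mean +/- SD of replicate measurements."""
    x = np.asarray(values, float)
    if mode == "arithmetic":
        return SummaryStats(float(x.mean()), float(x.std(ddof=1)) if len(x) > 1 else 0.0,
                            len(x), mode)
    if mode == "geometric":
        if np.any(x <= 0):
            raise ValueError("geometric statistics require positive data")
        lx = np.log(x)
        gsd = float(np.exp(lx.std(ddof=1))) if len(x) > 1 else 1.0
        return SummaryStats(float(np.exp(lx.mean())), gsd, len(x), mode)
    raise ValueError(f"unknown mode {mode!r}")


def ttest(a, b, paired: bool = False):
    """Two-sample Student's t test (thin wrapper for table comparisons)."""
    if paired:
        return sps.ttest_rel(a, b)
    return sps.ttest_ind(a, b)


def anova(*groups):
    """One-way ANOVA across measurement groups."""
    return sps.f_oneway(*groups)
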