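"""Star-topology Markov gating schemes for single K+ channels.

The channels analyzed here gate between one conducting open state ``O`` and a
set of non-conducting closed states that are each reachable *only* from the
open state (a "star" scheme).  Closed states fall into two kinetic classes:

* fast states ``F`` (microsecond) and ``M`` (sub-millisecond), whose
  transitions are faster than the recording filter and are only visible as
  excess noise in amplitude histograms;
* slow states ``C1``–``C4`` and the merged representative ``S``, whose
  sojourns are resolved by a level detector and analyzed as dwell times.

All rates are first-order rate constants in s^-1.  ``k_OX`` is the rate of
entering closed state ``X`` from ``O``; ``k_XO`` is the return rate.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "FAST_STATES",
    "SLOW_STATES",
    "GatingScheme",
    "StationaryDistribution",
    "stationary_probabilities",
    "expected_dwell_times",
    "merge_slow_states",
]

FAST_STATES = frozenset({"F", "M"})
SLOW_STATES = frozenset({"C1", "C2", "C3", "C4", "S"})
_ALLOWED_CLOSED = FAST_STATES | SLOW_STATES


class SchemeValidationError(ValueError):
    """Raised when a gating scheme violates the star-scheme invariants."""


@dataclass(frozen=True)
class GatingScheme:
    """One open state plus closed states with entry/exit rate pairs.

    Parameters
    ----------
    closed_rates
        Mapping ``{state label: (k_entry, k_exit)}`` in s^-1, where entry is
        O -> X and exit is X -> O.  Labels must come from
        ``{F, M, C1, C2, C3, C4, S}``.
    i_true
        True open-channel current magnitude in pA (before filter attenuation).
    closed_level
        Current of all closed states in pA (0 by convention).
    """

    closed_rates: dict[str, tuple[float, float]]
    i_true: float = 1.0
    closed_level: float = 0.0

    def __post_init__(self) -> None:
        seen = set()
        for label, (k_in, k_out) in self.closed_rates.items():
            if label not in _ALLOWED_CLOSED:
                raise SchemeValidationError(
                    f"unknown closed state {label!r}; allowed: {sorted(_ALLOWED_CLOSED)}"
                )
            if label in seen:
                raise SchemeValidationError(f"duplicate state label {label!r}")
            seen.add(label)
            for name, k in (("entry", k_in), ("exit", k_out)):
                if not (np.isfinite(k) and k > 0):
                    raise SchemeValidationError(
                        f"{name} rate of state {label!r} must be positive and finite, got {k}"
                    )
        if not np.isfinite(self.i_true):
            raise SchemeValidationError("i_true must be finite")

    # -- convenience views ------------------------------------------------
    @property
    def closed_states(self) -> list[str]:
        return list(self.closed_rates)

    @property
    def states(self) -> list[str]:
        return ["O", *self.closed_rates]

    @property
    def slow_states(self) -> list[str]:
        return [s for s in self.closed_rates if s in SLOW_STATES]

    @property
    def fast_states(self) -> list[str]:
        return [s for s in self.closed_rates if s in FAST_STATES]

    def entry_rate(self, state: str) -> float:
        return self.closed_rates[state][0]

    def exit_rate(self, state: str) -> float:
        return self.closed_rates[state][1]

    @property
    def total_exit_from_open(self) -> float:
        """Sum of all O -> closed rates (reciprocal of the mean open time)."""
        return float(sum(k for k, _ in self.closed_rates.values()))

    @property
    def max_rate(self) -> float:
        return float(max(k for pair in self.closed_rates.values() for k in pair))

    def open_level(self, voltage_mv: float) -> float:
        """Rendered open-channel current: |i_true| carries the voltage sign."""
        sign = -1.0 if voltage_mv < 0 else 1.0
        return sign * abs(self.i_true)

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "states": self.states,
            "rates": {s: list(map(float, pair)) for s, pair in self.closed_rates.items()},
            "i_true": float(self.i_true),
            "closed_level": float(self.closed_level),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GatingScheme":
        rates = {s: (float(p[0]), float(p[1])) for s, p in d["rates"].items()}
        return cls(rates, i_true=float(d.get("i_true", 1.0)),
                   closed_level=float(d.get("closed_level", 0.0)))

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    @classmethod
    def from_json(cls, s: str) -> "GatingScheme":
        return cls.from_dict(json.loads(s))


@dataclass(frozen=True)
class StationaryDistribution:
    """Per-state stationary probabilities of a gating scheme."""

    probabilities: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        vals = np.array(list(self.probabilities.values()))
        if np.any(vals < 0) or np.any(vals > 1):
            raise SchemeValidationError("stationary probabilities must lie in [0, 1]")
        if abs(vals.sum() - 1.0) > 1e-12:
            raise SchemeValidationError("stationary probabilities must sum to 1")

    def __getitem__(self, state: str) -> float:
        return self.probabilities[state]

    @property
    def open_probability(self) -> float:
        return self.probabilities["O"]


def stationary_probabilities(scheme: GatingScheme) -> StationaryDistribution:
    """Stationary distribution of a star scheme by detailed balance.

    Every O <-> X edge satisfies detailed balance in a star topology, so
    ``P_X = P_O * k_OX / k_XO`` and ``P_O`` follows from normalization.
    """
    ratios = {s: k_in / k_out for s, (k_in, k_out) in scheme.closed_rates.items()}
    p_open = 1.0 / (1.0 + sum(ratios.values()))
    probs = {"O": p_open, **{s: p_open * r for s, r in ratios.items()}}
    # renormalize away float round-off so the sum-to-1 invariant is exact
    total = sum(probs.values())
    return StationaryDistribution({s: p / total for s, p in probs.items()})


def expected_dwell_times(scheme: GatingScheme) -> dict[str, float]:
    """Mean state lifetimes in seconds.

    The open lifetime is the reciprocal of the summed exit rates; each closed
    state has a single exit path so its lifetime is ``1 / k_XO``.
    """
    out = {"O": 1.0 / scheme.total_exit_from_open}
    for s, (_, k_out) in scheme.closed_rates.items():
        out[s] = 1.0 / k_out
    return out


def merge_slow_states(scheme: GatingScheme) -> GatingScheme:
    """Lump all slow closed states into one representative state ``S``.

    Amplitude-histogram analysis cannot distinguish the slow states (their
    sojourns are all long compared with the filter response), so they are
    merged.  The merged entry rate is the sum of the slow entry rates, and the
    exit rate is chosen so that the merged scheme preserves the total slow
    occupancy: ``k_SO = k_OS * P_O / P_S``.
    """
    slow = scheme.slow_states
    if not slow:
        warnings.warn("scheme has no slow closed states; returning it unchanged",
                      stacklevel=2)
        return scheme
    stat = stationary_probabilities(scheme)
    k_os = sum(scheme.entry_rate(s) for s in slow)
    p_s = sum(stat[s] for s in slow)
    k_so = k_os * stat["O"] / p_s
    rates = {s: pair for s, pair in scheme.closed_rates.items() if s not in SLOW_STATES}
    rates["S"] = (k_os, k_so)
    return GatingScheme(rates, i_true=scheme.i_true, closed_level=scheme.closed_level)
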