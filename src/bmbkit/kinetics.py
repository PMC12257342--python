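"""Closed-form kinetics of mixtures of independently decaying nuclides.

A :class:`MixtureDecay` is a weighted sum of exponentials anchored at the
end of irradiation (t = 0):  A(t) = sum_i f_i exp(-lambda_i t),  with the
fractions f_i being shares of the *initial activity* (count rate), as a
gamma-spectroscopy region-of-interest fit parameterizes them.  Everything
downstream — synthetic count series, dose-during-handling integrals, the
"effective half-life" of a mixed curve — reduces to evaluating or
integrating this sum.

All times are minutes; unit conversions happen at the boundaries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

from scipy.optimize import brentq

from .nuclear_data import Nuclide

__all__ = ["MixtureDecay", "KineticsError"]


class KineticsError(ValueError):
    """Invalid kinetics input (bad fractions, negative times, empty windows)."""


@dataclass(frozen=True)
class MixtureDecay:
    """Weighted mixture of exponential decays, normalized at t0.

    Parameters
    ----------
    components
        Sequence of ``(nuclide, fraction)`` where fractions are shares of
        the total initial activity and sum to 1.
    """

    components: tuple[tuple[Nuclide, float], ...]

    def __init__(self, components: Sequence[tuple[Nuclide, float]]):
        comps = tuple((n, float(f)) for n, f in components)
        if not comps:
            raise KineticsError("mixture needs at least one component")
        for n, f in comps:
            if f < 0:
                raise KineticsError(f"{n.name}: negative fraction {f}")
            if n.half_life_min <= 0:
                raise KineticsError(f"{n.name}: non-positive half-life")
        total = sum(f for _, f in comps)
        if abs(total - 1.0) > 1e-9:
            raise KineticsError(f"fractions sum to {total}, expected 1")
        object.__setattr__(self, "components", comps)

    @classmethod
    def from_fractions(cls, components: Sequence[tuple[Nuclide, float]]) -> "MixtureDecay":
        """Build a mixture, normalizing not-quite-unit fractions."""
        total = sum(f for _, f in components)
        if total <= 0:
            raise KineticsError("fractions sum to zero")
        return cls([(n, f / total) for n, f in components])

    @property
    def decay_constants(self) -> tuple[float, ...]:
        return tuple(n.decay_constant_per_min for n, _ in self.components)

    def activity(self, t: float) -> float:
        """Relative activity A(t) = sum f_i exp(-lambda_i t); A(0) = 1."""
        if t < 0:
            raise KineticsError(f"time must be >= 0, got {t}")
        return sum(f * math.exp(-n.decay_constant_per_min * t) for n, f in self.components)

    def integrated_activity(self, t1: float, t2: float) -> float:
        """Closed-form integral of A(t) over [t1, t2] minutes.

        Has units of minutes (time-integrated relative activity); multiplying
        by a rate at t=0 gives accumulated counts or dose.
        """
        if t1 < 0:
            raise KineticsError(f"t1 must be >= 0, got {t1}")
        if t1 > t2:
            raise KineticsError(f"empty interval: t1={t1} > t2={t2}")
        out = 0.0
        for n, f in self.components:
            lam = n.decay_constant_per_min
            out += f * (math.exp(-lam * t1) - math.exp(-lam * t2)) / lam
        return out

    def interval_fraction(self, t1: float, t2: float, t_total: float) -> float:
        """Fraction of the [0, t_total] integrated activity delivered in [t1, t2].

        Fractions over a partition of [0, t_total] sum to 1; this is the
        quantity that converts a long contact-dose measurement into the dose
        accrued during a short handling window.
        """
        if not (0 <= t1 <= t2 <= t_total):
            raise KineticsError(f"window [{t1},{t2}] not inside [0,{t_total}]")
        return self.integrated_activity(t1, t2) / self.integrated_activity(0.0, t_total)

    def halving_time(self) -> float:
        """The unique t with A(t) = 1/2 (equals T1/2 for a single component).

        A(t) is strictly decreasing from 1 to 0, so the root exists and is
        unique; it always lies between the shortest and longest component
        half-lives.  Solved by bracketing + Brent to 1e-6 min.
        """
        halves = [n.half_life_min for n, f in self.components if f > 0]
        lo, hi = min(halves), max(halves)
        if math.isclose(lo, hi, rel_tol=1e-12):
            return lo
        # widen the bracket marginally against roundoff at the endpoints
        return float(brentq(lambda t: self.activity(t) - 0.5, lo * 0.999999, hi * 1.000001, xtol=1e-6))

    def initial_rate_from_total(self, d_total: float, t_total: float) -> float:
        """Rate at t=0 (per minute) given the dose/counts accumulated over [0, t_total].

        Inverts D = rate(0) * integral of A over [0, T].
        """
        if d_total <= 0:
            raise KineticsError(f"total must be > 0, got {d_total}")
        if t_total <= 0:
            raise KineticsError(f"duration must be > 0, got {t_total}")
        return d_total / self.integrated_activity(0.0, t_total)

    def initial_rate_first_minute(self, d_total: float, t_total: float,
                                  first_minute_fraction: float | None = None) -> float:
        """First-minute estimator of the initial rate, in per-hour units.

        rate(0) ~= D_total * (fraction of D delivered in the first minute) * 60.
        The fraction may be supplied (e.g. read off a measured decay curve)
        or computed from the mixture model.
        """
        if d_total <= 0 or t_total <= 0:
            raise KineticsError("total and duration must be > 0")
        frac = (
            first_minute_fraction
            if first_minute_fraction is not None
            else self.interval_fraction(0.0, 1.0, t_total)
        )
        return d_total * frac * 60.0
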