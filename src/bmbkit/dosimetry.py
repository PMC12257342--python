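"""Occupational dose projection for staff handling an activated bolus.

Starting from a single contact measurement — either a survey-meter dose
rate (mrem/h at a reference MU) or an integrated dosimeter reading (mrem
accumulated over a stated contact duration) — project the dose a
therapist accrues over a treatment course, assuming they handle the bolus
for a short time immediately after each fraction.

Activation, and hence all doses here, scale linearly with delivered MU at
fixed beam energy.  Exposure (mR) and dose (mrem) are treated as
numerically interchangeable, as is conventional for these photon fields;
reports flag the convention.  Annual occupational limits default to the
10 CFR 20 values: 5000 mrem total effective dose equivalent (TEDE) and
50000 mrem shallow/extremity.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import pandas as pd

from .activation import fraction_buildup
from .kinetics import MixtureDecay

__all__ = [
    "ContactCalibration",
    "ExposureScenario",
    "DoseReport",
    "DoseLimits",
    "DosimetryError",
    "scale_by_mu",
    "course_dose_from_rate",
    "course_dose_from_integrated",
    "percent_of_limits",
    "distance_table",
]


class DosimetryError(ValueError):
    """Invalid dosimetry input."""


@dataclass(frozen=True)
class DoseLimits:
    """Annual occupational limits, mrem (10 CFR 20 defaults)."""

    tede_mrem: float = 5000.0
    extremity_mrem: float = 50000.0

    def __post_init__(self):
        if self.tede_mrem <= 0 or self.extremity_mrem <= 0:
            raise DosimetryError("limits must be > 0")


@dataclass(frozen=True)
class ContactCalibration:
    """A contact measurement anchoring the dose projection.

    ``kind="rate"``: ``value`` is mrem/h measured immediately after
    ``reference_mu`` MU.  ``kind="integrated"``: ``value`` is mrem
    accumulated over ``contact_duration_min`` of continuous contact after
    ``reference_mu`` MU.  ``decay_model`` describes how the dose rate
    decays after beam-off.
    """

    kind: str  # "rate" | "integrated"
    value: float
    reference_mu: float
    contact_duration_min: float | None = None
    decay_model: MixtureDecay | None = None

    def __post_init__(self):
        if self.kind not in ("rate", "integrated"):
            raise DosimetryError(f"unknown calibration kind {self.kind!r}")
        if self.value <= 0:
            raise DosimetryError("calibration value must be > 0")
        if self.reference_mu <= 0:
            raise DosimetryError("reference_mu must be > 0")
        if self.kind == "integrated" and (
            self.contact_duration_min is None or self.contact_duration_min <= 0
        ):
            raise DosimetryError("integrated calibration needs contact_duration_min > 0")


@dataclass(frozen=True)
class ExposureScenario:
    """Fractionation and handling assumptions for one treatment course."""

    mu_per_fraction: float
    n_fractions: int = 25
    handling_time_min: float = 1.0
    handling_delay_min: float = 0.0
    distance_cm: float | None = None
    full_decay_between_fractions: bool = True
    interfraction_interval_h: float = 24.0

    def __post_init__(self):
        if self.mu_per_fraction <= 0:
            raise DosimetryError("mu_per_fraction must be > 0")
        if self.n_fractions < 1:
            raise DosimetryError("n_fractions must be >= 1")
        if self.handling_time_min < 0:
            raise DosimetryError("handling_time_min must be >= 0")
        if self.handling_delay_min < 0:
            raise DosimetryError("handling_delay_min must be >= 0")
        if self.interfraction_interval_h <= 0:
            raise DosimetryError("interfraction_interval_h must be > 0")


@dataclass(frozen=True)
class DoseReport:
    """Projected dose for one course, with the assumptions echoed."""

    per_fraction_mrem: float
    course_mrem: float
    initial_rate_mrem_per_h: float | None
    percent_of_tede: float
    percent_of_extremity: float
    assumptions: dict = field(default_factory=dict)

    def summary(self) -> str:
        lines = [
            f"per-fraction dose : {self.per_fraction_mrem:.3f} mrem",
            f"course dose       : {self.course_mrem:.3f} mrem",
        ]
        if self.initial_rate_mrem_per_h is not None:
            lines.append(f"initial dose rate : {self.initial_rate_mrem_per_h:.1f} mrem/h at beam-off")
        lines.append(f"percent of TEDE limit      : {self.percent_of_tede:.3f}%")
        lines.append(f"percent of extremity limit : {self.percent_of_extremity:.3f}%")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return asdict(self)


def scale_by_mu(value: float, reference_mu: float, target_mu: float) -> float:
    """Linear MU scaling of any activation-derived quantity."""
    if reference_mu <= 0 or target_mu <= 0:
        raise DosimetryError("MU values must be > 0")
    return value * target_mu / reference_mu


def percent_of_limits(course_dose_mrem: float, limits: DoseLimits | None = None) -> tuple[float, float]:
    """(percent of TEDE limit, percent of extremity limit) for a course dose."""
    limits = limits or DoseLimits()
    if course_dose_mrem < 0:
        raise DosimetryError("dose must be >= 0")
    return (
        course_dose_mrem / limits.tede_mrem * 100.0,
        course_dose_mrem / limits.extremity_mrem * 100.0,
    )


def _course_multiplier(sc: ExposureScenario, decay_model: MixtureDecay | None) -> float:
    """Sum over fractions of the residual-activity multiplier.

    Under full inter-fraction decay this is simply n; otherwise each
    fraction k carries the buildup factor B_k of every mixture component.
    """
    if sc.full_decay_between_fractions:
        return float(sc.n_fractions)
    if decay_model is None:
        raise DosimetryError("buildup accounting needs a decay model")
    total = 0.0
    for k in range(1, sc.n_fractions + 1):
        total += sum(
            f * fraction_buildup(n, k, sc.interfraction_interval_h)
            for n, f in decay_model.components
        )
    return total


def course_dose_from_rate(
    cal: ContactCalibration,
    sc: ExposureScenario,
    limits: DoseLimits | None = None,
    decay_correct_handling: bool = False,
) -> DoseReport:
    """Course dose from a survey-meter contact rate (deep-dose pathway).

    Per fraction: the rate scaled to the fraction's MU, times the handling
    time.  ``decay_correct_handling=True`` replaces the constant-rate
    assumption with the decay-model integral over the handling window
    (always <= the uncorrected value); default off, since over a 1-minute
    handling window the correction is a few percent.
    """
    if cal.kind != "rate":
        raise DosimetryError("course_dose_from_rate needs a rate-kind calibration")
    rate_h = scale_by_mu(cal.value, cal.reference_mu, sc.mu_per_fraction)  # mrem/h at beam-off
    rate_min = rate_h / 60.0
    if decay_correct_handling:
        if cal.decay_model is None:
            raise DosimetryError("decay correction needs a decay model")
        t0 = sc.handling_delay_min
        per_fraction = rate_min * cal.decay_model.integrated_activity(t0, t0 + sc.handling_time_min)
    else:
        per_fraction = rate_min * sc.handling_time_min
    course = per_fraction * _course_multiplier(sc, cal.decay_model)
    pct_tede, pct_ext = percent_of_limits(course, limits)
    return DoseReport(
        per_fraction_mrem=per_fraction,
        course_mrem=course,
        initial_rate_mrem_per_h=rate_h,
        percent_of_tede=pct_tede,
        percent_of_extremity=pct_ext,
        assumptions={
            "calibration": "contact rate (deep dose)",
            "mrem_equals_mR": True,
            "decay_corrected_handling": decay_correct_handling,
            "mu_per_fraction": sc.mu_per_fraction,
            "n_fractions": sc.n_fractions,
            "handling_time_min": sc.handling_time_min,
            "full_decay_between_fractions": sc.full_decay_between_fractions,
        },
    )


def course_dose_from_integrated(
    cal: ContactCalibration,
    sc: ExposureScenario,
    limits: DoseLimits | None = None,
    first_interval_fraction: float | None = None,
) -> DoseReport:
    """Course dose from an integrated contact reading (skin-dose pathway).

    The dosimeter reading over the full contact duration is converted to a
    handling-window dose via the fraction of the time-integrated activity
    delivered in [delay, delay + handling]; that fraction is either
    supplied (e.g. read from a measured decay curve) or computed from the
    calibration's decay model.  The initial dose rate is the first-minute
    estimator: reading x (first-minute fraction) x 60, MU-scaled.
    """
    if cal.kind != "integrated":
        raise DosimetryError("course_dose_from_integrated needs an integrated-kind calibration")
    if sc.handling_time_min > cal.contact_duration_min:
        raise DosimetryError("handling_time_min exceeds the calibration contact duration")
    t_total = cal.contact_duration_min
    if first_interval_fraction is not None:
        if not 0.0 < first_interval_fraction <= 1.0:
            raise DosimetryError("first_interval_fraction must be in (0, 1]")
        frac = first_interval_fraction
    else:
        if cal.decay_model is None:
            raise DosimetryError("need either a supplied interval fraction or a decay model")
        frac = cal.decay_model.interval_fraction(
            sc.handling_delay_min, sc.handling_delay_min + sc.handling_time_min, t_total
        )
    mu_scale = sc.mu_per_fraction / cal.reference_mu
    per_fraction = cal.value * frac * mu_scale
    course = per_fraction * _course_multiplier(sc, cal.decay_model)

    if first_interval_fraction is not None and sc.handling_time_min == 1.0 and sc.handling_delay_min == 0.0:
        first_min_frac = first_interval_fraction
    elif cal.decay_model is not None:
        first_min_frac = cal.decay_model.interval_fraction(0.0, 1.0, t_total)
    else:
        first_min_frac = None
    initial_rate = cal.value * first_min_frac * 60.0 * mu_scale if first_min_frac is not None else None

    pct_tede, pct_ext = percent_of_limits(course, limits)
    return DoseReport(
        per_fraction_mrem=per_fraction,
        course_mrem=course,
        initial_rate_mrem_per_h=initial_rate,
        percent_of_tede=pct_tede,
        percent_of_extremity=pct_ext,
        assumptions={
            "calibration": "integrated contact reading (skin dose)",
            "contact_duration_min": t_total,
            "interval_fraction": frac,
            "interval_fraction_source": "supplied" if first_interval_fraction is not None else "decay model",
            "mrem_equals_mR": True,
            "mu_per_fraction": sc.mu_per_fraction,
            "n_fractions": sc.n_fractions,
            "handling_time_min": sc.handling_time_min,
            "full_decay_between_fractions": sc.full_decay_between_fractions,
        },
    )


def distance_table(
    rates: list[tuple[float, float]],
    sc: ExposureScenario,
) -> pd.DataFrame:
    """Per-course dose at each survey distance.

    ``rates`` are ``(distance_cm, mR/h per MU)`` rows.  Each row's hourly
    rate after one fraction is rate x MU; the course dose assumes the same
    handling time at that distance every fraction.  Columns:
    ``distance_cm``, ``rate_mRph_per_MU``, ``course_dose_mrem``.
    """
    if not rates:
        raise DosimetryError("no rates given")
    dists = [d for d, _ in rates]
    if len(set(dists)) != len(dists):
        raise DosimetryError("duplicate distances in rate table")
    rows = []
    for dist, rate_per_mu in sorted(rates):
        if dist <= 0 or rate_per_mu <= 0:
            raise DosimetryError("distances and rates must be > 0")
        hourly = rate_per_mu * sc.mu_per_fraction  # mR/h immediately after one fraction
        course = hourly * sc.handling_time_min / 60.0 * sc.n_fractions
        rows.append({"distance_cm": dist, "rate_mRph_per_MU": rate_per_mu, "course_dose_mrem": course})
    return pd.DataFrame(rows)
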