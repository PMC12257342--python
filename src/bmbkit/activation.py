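"""Predict activation products of a brass alloy and their relative activities.

Two mechanisms activate a metallic bolus in a clinical photon beam:

* thermal **neutron capture** (n,gamma) — neutrons are present both in and
  out of the primary field, so capture channels are always open;
* the **photoneutron** (gamma,n) reaction — requires primary-beam photons
  above the channel threshold, so it only operates in-field and only when
  the nominal accelerating potential (MV) exceeds the threshold (MeV).

Relative end-of-irradiation activities are computable for capture only:
A_i is proportional to N_i * sigma_i * (1 - exp(-lambda_i * t_irr)), where
N_i is the parent atom fraction in the alloy.  The neutron fluence rate
cancels in the ratios.  In the short-irradiation limit (t_irr -> 0) the
saturation factor reduces to lambda_i * t_irr, giving the N*sigma*lambda
weighting; as t_irr -> infinity it saturates to N*sigma.  Photoneutron
*relative* yields need energy-dependent (gamma,n) cross sections that are
deliberately out of scope; those fractions come from decay-curve fitting
instead (:mod:`bmbkit.fitting`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .nuclear_data import (
    AlloyComposition,
    NuclearDataError,
    NuclearDataLibrary,
    Nuclide,
    Reaction,
    default_library,
)

__all__ = [
    "IrradiationSpec",
    "ActivationInventory",
    "predict_products",
    "relative_activities",
    "fraction_buildup",
    "PhotoneutronYieldError",
]

#: Assumed clinical delivery rate used to infer an irradiation time from MU.
DEFAULT_MU_PER_MIN = 600.0


class PhotoneutronYieldError(NotImplementedError):
    """Relative photonuclear yields are not computable from bundled constants."""


@dataclass(frozen=True)
class IrradiationSpec:
    """One irradiation condition: beam energy, output, duration, geometry.

    ``beam_energy_mv`` is the nominal accelerating potential; a photoneutron
    channel is treated as open when its threshold in MeV is below this
    number (plus an optional safety margin).  ``in_field=False`` disables
    photoneutron channels entirely (no primary photons on the bolus).
    """

    beam_energy_mv: float
    mu: float = 500.0
    irradiation_time_min: float | None = None
    in_field: bool = True
    threshold_margin_mev: float = 0.0

    def __post_init__(self):
        if self.beam_energy_mv <= 0:
            raise ValueError(f"beam_energy_mv must be > 0, got {self.beam_energy_mv}")
        if self.mu <= 0:
            raise ValueError(f"mu must be > 0, got {self.mu}")
        if self.irradiation_time_min is not None and self.irradiation_time_min <= 0:
            raise ValueError("irradiation_time_min must be > 0 when given")

    @property
    def effective_irradiation_time_min(self) -> float:
        """Stated irradiation time, else MU at the default delivery rate."""
        if self.irradiation_time_min is not None:
            return self.irradiation_time_min
        return self.mu / DEFAULT_MU_PER_MIN


@dataclass(frozen=True)
class ActivationInventory:
    """Relative activities of activation products at end of irradiation."""

    entries: tuple[tuple[Nuclide, float, Reaction], ...]

    def __post_init__(self):
        seen = set()
        for nuc, act, mech in self.entries:
            if act < 0:
                raise ValueError(f"{nuc.name}: negative activity")
            key = (nuc.name, mech)
            if key in seen:
                raise ValueError(f"duplicate inventory entry {key}")
            seen.add(key)

    def normalized(self) -> "ActivationInventory":
        total = sum(act for _, act, _ in self.entries)
        if total <= 0:
            raise ValueError("inventory has zero total activity")
        return ActivationInventory(
            tuple((n, a / total, m) for n, a, m in self.entries)
        )

    def fraction_of(self, name: str) -> float:
        total = sum(act for _, act, _ in self.entries)
        return sum(a for n, a, _ in self.entries if n.name == name) / total

    def nuclides(self) -> tuple[Nuclide, ...]:
        out, seen = [], set()
        for n, _, _ in self.entries:
            if n.name not in seen:
                seen.add(n.name)
                out.append(n)
        return tuple(out)


def _sort_key(nuclide: Nuclide) -> tuple[str, int, str]:
    return (nuclide.element, nuclide.mass_number, nuclide.name)


def predict_products(
    alloy: AlloyComposition,
    spec: IrradiationSpec,
    library: NuclearDataLibrary | None = None,
) -> list[tuple[Nuclide, Reaction]]:
    """All activation products expected for an alloy under one condition.

    Capture products are always present (a neutron bath exists in and out
    of field); photoneutron products require ``in_field`` and the beam
    potential to exceed the channel threshold.  Output is deduplicated per
    (nuclide, mechanism) and deterministically ordered by element and mass
    number.
    """
    lib = library or default_library()
    out: list[tuple[Nuclide, Reaction]] = []
    for element in sorted(alloy.mass_fractions):
        if alloy.mass_fractions[element] == 0:
            continue
        for ch in lib.channels_for(element, "n_capture"):
            out.append((ch.product, "n_capture"))
        if spec.in_field:
            for ch in lib.channels_for(element, "photo_neutron"):
                if ch.threshold + spec.threshold_margin_mev < spec.beam_energy_mv:
                    out.append((ch.product, "photo_neutron"))
    dedup = {(n.name, m): (n, m) for n, m in out}
    return sorted(dedup.values(), key=lambda pair: (_sort_key(pair[0]), pair[1]))


def relative_activities(
    alloy: AlloyComposition,
    mechanism: Reaction = "n_capture",
    irradiation_time_min: float | None = None,
    library: NuclearDataLibrary | None = None,
) -> ActivationInventory:
    """Relative end-of-irradiation activities under neutron capture.

    ``irradiation_time_min=None`` selects the short-irradiation limit
    (N*sigma*lambda weighting), appropriate for clinical beam-on times of a
    minute or two, which are short against every product half-life here.

    Raises
    ------
    PhotoneutronYieldError
        For ``mechanism="photo_neutron"``: relative yields would need
        energy-dependent (gamma,n) cross sections and the photon spectrum.
    """
    if mechanism == "photo_neutron":
        raise PhotoneutronYieldError(
            "relative photonuclear yields unsupported: (gamma,n) cross-section "
            "curves are not bundled; obtain photoneutron fractions by decay-curve "
            "fitting (bmbkit.fitting.fit_fixed_mixture)"
        )
    if mechanism != "n_capture":
        raise NuclearDataError(f"unknown mechanism {mechanism!r}")
    if irradiation_time_min is not None and irradiation_time_min <= 0:
        raise ValueError("irradiation_time_min must be > 0 (or None for the short limit)")
    lib = library or default_library()
    fractions = lib.atom_fractions(alloy)
    raw: list[tuple[Nuclide, float]] = []
    for element in sorted(alloy.mass_fractions):
        for ch in lib.channels_for(element, "n_capture"):
            n_parent = fractions.get(ch.parent.name, 0.0)
            lam = ch.product.decay_constant_per_min
            if irradiation_time_min is None:
                saturation = lam  # short limit: (1 - e^{-lam t}) / t -> lam
            else:
                saturation = 1.0 - math.exp(-lam * irradiation_time_min)
            raw.append((ch.product, n_parent * ch.sigma_thermal * saturation))
    total = sum(a for _, a in raw)
    if total <= 0:
        raise NuclearDataError("alloy has no capture channels")
    entries = tuple(
        (n, a / total, "n_capture")
        for n, a in sorted(raw, key=lambda pair: _sort_key(pair[0]))
    )
    return ActivationInventory(entries)


def fraction_buildup(nuclide: Nuclide, n_fractions: int, interval_h: float) -> float:
    """Residual-activity buildup factor over identical daily irradiations.

    After the n-th of n identical irradiations separated by ``interval_h``
    hours, the activity is B_n times the single-fraction activity, with

        B_n = (1 - exp(-n*lambda*T)) / (1 - exp(-lambda*T)).

    B_1 = 1; B_n < 1 / (1 - exp(-lambda*T)).  Short-lived products decay
    fully between fractions (B ~ 1); only long-lived ones accumulate.
    """
    if n_fractions < 1:
        raise ValueError(f"n_fractions must be >= 1, got {n_fractions}")
    if interval_h <= 0:
        raise ValueError(f"interval_h must be > 0, got {interval_h}")
    lam_t = nuclide.decay_constant_per_min * interval_h * 60.0
    r = math.exp(-lam_t)
    if r == 0.0:
        return 1.0
    return (1.0 - r**n_fractions) / (1.0 - r)
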