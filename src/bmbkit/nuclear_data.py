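"""Nuclear constants for brass-alloy activation analysis.

Bundles the atom-level data every other stage of the pipeline reads:
natural abundances and atomic masses of the stable Cu/Zn/Sn isotopes,
half-lives, decay modes and gamma emission lines of their activation
products, thermal neutron-capture cross sections and photoneutron
(gamma,n) thresholds.  The default table ships as a versioned JSON file
(``data/nuclear_constants.json``); a user-supplied file with the same
schema can be loaded instead.

Conventions
-----------
* Half-lives are stored in **minutes** (the natural scale for these
  products); :func:`Nuclide.half_life_s` converts.
* Gamma lines are ``(energy_keV, photons_per_decay)``.  The 511 keV
  annihilation line is *not* stored: it is derived from
  ``positron_fraction`` (two photons per positron) so that every
  beta-plus emitter contributes it consistently.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Literal, Mapping

__all__ = [
    "Nuclide",
    "StableIsotope",
    "ActivationChannel",
    "AlloyComposition",
    "NuclearDataError",
    "UnknownNuclideError",
    "NuclearDataLibrary",
    "default_library",
    "yellow_brass",
    "white_brass",
    "ANNIHILATION_KEV",
]

ANNIHILATION_KEV = 511.0

Reaction = Literal["n_capture", "photo_neutron"]

_DECAY_MODES = {"beta_minus", "beta_plus", "electron_capture", "isomeric_transition"}

_NUCLIDE_RE = re.compile(r"^([A-Z][a-z]?)-(\d+)(m?)$")


class NuclearDataError(ValueError):
    """Invalid or inconsistent nuclear-constant data."""


class UnknownNuclideError(KeyError):
    """Lookup of a nuclide name absent from the bundled table."""

    def __init__(self, name: str):
        super().__init__(f"unknown nuclide: {name!r}")
        self.name = name


def _parse_name(name: str) -> tuple[str, int, bool]:
    m = _NUCLIDE_RE.match(name)
    if m is None:
        raise NuclearDataError(f"malformed nuclide name: {name!r}")
    return m.group(1), int(m.group(2)), m.group(3) == "m"


@dataclass(frozen=True)
class Nuclide:
    """A radioactive nuclide: half-life, decay modes and photon emissions."""

    name: str
    half_life_min: float
    decay_modes: tuple[tuple[str, float], ...]
    gamma_lines: tuple[tuple[float, float], ...] = ()
    positron_fraction: float = 0.0

    def __post_init__(self):
        if self.half_life_min <= 0:
            raise NuclearDataError(f"{self.name}: half_life must be > 0")
        total = 0.0
        for mode, frac in self.decay_modes:
            if mode not in _DECAY_MODES:
                raise NuclearDataError(f"{self.name}: unknown decay mode {mode!r}")
            if not 0.0 <= frac <= 1.0:
                raise NuclearDataError(f"{self.name}: branching {frac} outside [0,1]")
            total += frac
        if total > 1.0001:
            raise NuclearDataError(f"{self.name}: branchings sum to {total} > 1")
        for energy, intensity in self.gamma_lines:
            if energy <= 0 or intensity < 0:
                raise NuclearDataError(f"{self.name}: bad gamma line ({energy}, {intensity})")
        if not 0.0 <= self.positron_fraction <= 1.0:
            raise NuclearDataError(f"{self.name}: positron_fraction outside [0,1]")
        bplus = dict(self.decay_modes).get("beta_plus", 0.0)
        if abs(self.positron_fraction - bplus) > 1e-6:
            raise NuclearDataError(
                f"{self.name}: positron_fraction {self.positron_fraction} != beta_plus branching {bplus}"
            )

    @property
    def element(self) -> str:
        return _parse_name(self.name)[0]

    @property
    def mass_number(self) -> int:
        return _parse_name(self.name)[1]

    @property
    def half_life_s(self) -> float:
        return self.half_life_min * 60.0

    @property
    def decay_constant_per_min(self) -> float:
        import math

        return math.log(2.0) / self.half_life_min

    def emission_lines(self) -> tuple[tuple[float, float], ...]:
        """Gamma lines plus the derived 511 keV annihilation line.

        Annihilation intensity is two photons per positron-emitting decay.
        """
        lines = list(self.gamma_lines)
        if self.positron_fraction > 0:
            lines.append((ANNIHILATION_KEV, 2.0 * self.positron_fraction))
        return tuple(sorted(lines))


@dataclass(frozen=True)
class StableIsotope:
    """A stable isotope with its natural abundance and atomic mass."""

    name: str
    natural_abundance: float
    atomic_mass: float

    def __post_init__(self):
        if not 0.0 <= self.natural_abundance <= 1.0:
            raise NuclearDataError(f"{self.name}: abundance outside [0,1]")
        if self.atomic_mass <= 0:
            raise NuclearDataError(f"{self.name}: atomic mass must be > 0")

    @property
    def element(self) -> str:
        return _parse_name(self.name)[0]


@dataclass(frozen=True)
class ActivationChannel:
    """One activation pathway: stable parent -> reaction -> radioactive product.

    Exactly one of ``sigma_thermal`` (barns, thermal neutron capture) or
    ``threshold`` (MeV, photoneutron) is set, matching the reaction kind.
    """

    parent: StableIsotope
    reaction: Reaction
    product: Nuclide
    sigma_thermal: float | None = None
    threshold: float | None = None

    def __post_init__(self):
        if self.reaction == "n_capture":
            if self.sigma_thermal is None or self.threshold is not None:
                raise NuclearDataError(f"{self.parent.name}: capture channel needs sigma_thermal only")
            if self.sigma_thermal <= 0:
                raise NuclearDataError(f"{self.parent.name}: sigma_thermal must be > 0")
        elif self.reaction == "photo_neutron":
            if self.threshold is None or self.sigma_thermal is not None:
                raise NuclearDataError(f"{self.parent.name}: photoneutron channel needs threshold only")
            if self.threshold <= 0:
                raise NuclearDataError(f"{self.parent.name}: threshold must be > 0")
        else:
            raise NuclearDataError(f"unknown reaction {self.reaction!r}")


@dataclass(frozen=True)
class AlloyComposition:
    """Elemental composition of an alloy by mass fraction."""

    mass_fractions: Mapping[str, float]

    def __post_init__(self):
        if not self.mass_fractions:
            raise NuclearDataError("empty alloy composition")
        total = 0.0
        for el, frac in self.mass_fractions.items():
            if frac < 0:
                raise NuclearDataError(f"{el}: negative mass fraction")
            total += frac
        if abs(total - 1.0) > 1e-6:
            raise NuclearDataError(f"mass fractions sum to {total}, expected 1")
        object.__setattr__(self, "mass_fractions", dict(self.mass_fractions))

    def elements(self) -> tuple[str, ...]:
        return tuple(self.mass_fractions)


def yellow_brass() -> AlloyComposition:
    """Default brass: 70/30 Cu/Zn by mass (yellow brass)."""
    return AlloyComposition({"Cu": 0.70, "Zn": 0.30})


def white_brass(sn_fraction: float = 0.10) -> AlloyComposition:
    """Brass with a tin admixture (white brass); Cu/Zn keep their 70/30 ratio."""
    rest = 1.0 - sn_fraction
    return AlloyComposition({"Cu": 0.70 * rest, "Zn": 0.30 * rest, "Sn": sn_fraction})


@dataclass
class NuclearDataLibrary:
    """In-memory nuclear-constants table with lookup and derived quantities."""

    isotopes: tuple[StableIsotope, ...]
    nuclides: tuple[Nuclide, ...]
    channels: tuple[ActivationChannel, ...]
    source_path: Path | None = None
    _by_name: dict = field(default_factory=dict, repr=False)

    def __post_init__(self):
        self._by_name = {n.name: n for n in self.nuclides}
        # per-element abundance closure
        per_element: dict[str, float] = {}
        for iso in self.isotopes:
            per_element[iso.element] = per_element.get(iso.element, 0.0) + iso.natural_abundance
        for el, total in per_element.items():
            if abs(total - 1.0) > 1e-3:
                raise NuclearDataError(f"{el}: isotope abundances sum to {total}")
        # referential closure: every channel product resolves
        for ch in self.channels:
            if ch.product.name not in self._by_name:
                raise NuclearDataError(f"channel product {ch.product.name} not in nuclide table")

    # -- lookups ---------------------------------------------------------

    def get_nuclide(self, name: str) -> Nuclide:
        """Return the constant record for ``name`` (e.g. ``"Cu-64"``)."""
        try:
            return self._by_name[name]
        except KeyError:
            raise UnknownNuclideError(name) from None

    def elements(self) -> tuple[str, ...]:
        return tuple(dict.fromkeys(iso.element for iso in self.isotopes))

    def isotopes_of(self, element: str) -> tuple[StableIsotope, ...]:
        return tuple(iso for iso in self.isotopes if iso.element == element)

    def channels_for(self, element: str, reaction: Reaction) -> tuple[ActivationChannel, ...]:
        """All activation channels of ``element`` under one reaction kind."""
        if element not in self.elements():
            raise NuclearDataError(f"no channel data for element {element!r}")
        return tuple(
            ch for ch in self.channels if ch.parent.element == element and ch.reaction == reaction
        )

    def atomic_weight(self, element: str) -> float:
        """Abundance-weighted standard atomic weight from the isotope table."""
        isos = self.isotopes_of(element)
        if not isos:
            raise NuclearDataError(f"no isotope data for element {element!r}")
        return sum(iso.natural_abundance * iso.atomic_mass for iso in isos)

    def atom_fractions(self, alloy: AlloyComposition) -> dict[str, float]:
        """Per-isotope atom fractions of an alloy given by mass fractions.

        mass fraction / atomic weight gives moles of each element; isotopic
        abundance splits them; the result is normalized to sum to one.
        """
        moles = {el: frac / self.atomic_weight(el) for el, frac in alloy.mass_fractions.items()}
        total = sum(moles.values())
        if total <= 0:
            raise NuclearDataError("alloy has no atoms")
        out: dict[str, float] = {}
        for el, mol in moles.items():
            for iso in self.isotopes_of(el):
                out[iso.name] = (mol / total) * iso.natural_abundance
        return out


def _load_dict(raw: dict, source_path: Path | None = None) -> NuclearDataLibrary:
    isotopes = tuple(
        StableIsotope(d["name"], d["natural_abundance"], d["atomic_mass"]) for d in raw["isotopes"]
    )
    nuclides = tuple(
        Nuclide(
            name=d["name"],
            half_life_min=d["half_life_min"],
            decay_modes=tuple((m, f) for m, f in d["decay_modes"]),
            gamma_lines=tuple((e, i) for e, i in d.get("gamma_lines", [])),
            positron_fraction=d.get("positron_fraction", 0.0),
        )
        for d in raw["nuclides"]
    )
    iso_by_name = {iso.name: iso for iso in isotopes}
    nuc_by_name = {n.name: n for n in nuclides}
    channels = []
    for d in raw["channels"]:
        try:
            parent = iso_by_name[d["parent"]]
            product = nuc_by_name[d["product"]]
        except KeyError as exc:
            raise NuclearDataError(f"channel references unknown record: {exc}") from None
        channels.append(
            ActivationChannel(
                parent=parent,
                reaction=d["reaction"],
                product=product,
                sigma_thermal=d.get("sigma_thermal"),
                threshold=d.get("threshold"),
            )
        )
    return NuclearDataLibrary(isotopes, nuclides, tuple(channels), source_path=source_path)


def load_library(path: str | Path) -> NuclearDataLibrary:
    """Load a constants file with the bundled JSON schema."""
    path = Path(path)
    with open(path) as fh:
        return _load_dict(json.load(fh), source_path=path)


_DEFAULT: NuclearDataLibrary | None = None


def default_library() -> NuclearDataLibrary:
    """The bundled constants table (cached)."""
    global _DEFAULT
    if _DEFAULT is None:
        ref = resources.files("bmbkit.data").joinpath("nuclear_constants.json")
        _DEFAULT = _load_dict(json.loads(ref.read_text()))
    return _DEFAULT
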