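"""bmbkit: activation and occupational dosimetry of brass mesh bolus.

Brass mesh bolus (BMB) placed on the skin during high-energy photon
radiotherapy becomes radioactive, through thermal neutron capture and —
dominantly, in-field at 15 MV — the photoneutron (gamma,n) reaction.
This package predicts the activation products per mechanism, models and
fits the multi-component decay of gamma-spectrum peaks, simulates the
NaI measurements, and projects the occupational dose to staff who handle
the bolus after treatment.
"""

__version__ = "0.1.0"

from .nuclear_data import (
    ANNIHILATION_KEV,
    ActivationChannel,
    AlloyComposition,
    NuclearDataLibrary,
    Nuclide,
    StableIsotope,
    UnknownNuclideError,
    default_library,
    load_library,
    white_brass,
    yellow_brass,
)
from .activation import (
    ActivationInventory,
    IrradiationSpec,
    PhotoneutronYieldError,
    fraction_buildup,
    predict_products,
    relative_activities,
)
from .kinetics import MixtureDecay
from .spectro import (
    CountTimeSeries,
    DetectorModel,
    EnergySpectrum,
    generate_spectrum,
    identify_peaks,
    mixture_from_inventory,
    roi_timeseries,
    simulate_decay_series,
)
from .fitting import (
    DecayFitResult,
    fit_fixed_mixture,
    fit_monoexponential,
    goodness_of_fit,
    restrict_window,
)
from .dosimetry import (
    ContactCalibration,
    DoseLimits,
    DoseReport,
    ExposureScenario,
    course_dose_from_integrated,
    course_dose_from_rate,
    distance_table,
    percent_of_limits,
    scale_by_mu,
)
from .pipeline import StudyConfig, packaged_study_config, run_study, validate_config


def get_nuclide(name: str) -> Nuclide:
    """Look up a nuclide in the bundled constants table."""
    return default_library().get_nuclide(name)


def channels_for(element: str, reaction: str):
    """Activation channels of an element from the bundled table."""
    return default_library().channels_for(element, reaction)


def atom_fractions(alloy: AlloyComposition) -> dict:
    """Per-isotope atom fractions of an alloy (bundled abundances)."""
    return default_library().atom_fractions(alloy)
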