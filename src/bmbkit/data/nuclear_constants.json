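{
  "_meta": {
    "description": "Nuclear constants for brass-alloy activation analysis (Cu, Zn, Sn).",
    "source": "Standard evaluated nuclear data (ENSDF/NNDC-published half-lives, branching ratios and gamma intensities; IUPAC 2021 isotopic abundances and atomic masses; thermal (n,g) cross sections and (g,n) thresholds from standard compilations).",
    "compiled": "2026-09",
    "units": {
      "half_life": "minutes",
      "gamma_energy": "keV",
      "gamma_intensity": "photons per decay",
      "sigma_thermal": "barns",
      "threshold": "MeV",
      "atomic_mass": "u"
    }
  },
  "isotopes": [
    {"name": "Cu-63", "element": "Cu", "natural_abundance": 0.6915, "atomic_mass": 62.92960},
    {"name": "Cu-65", "element": "Cu", "natural_abundance": 0.3085, "atomic_mass": 64.92779},
    {"name": "Zn-64", "element": "Zn", "natural_abundance": 0.4917, "atomic_mass": 63.92914},
    {"name": "Zn-66", "element": "Zn", "natural_abundance": 0.2773, "atomic_mass": 65.92603},
    {"name": "Zn-67", "element": "Zn", "natural_abundance": 0.0404, "atomic_mass": 66.92713},
    {"name": "Zn-68", "element": "Zn", "natural_abundance": 0.1845, "atomic_mass": 67.92484},
    {"name": "Zn-70", "element": "Zn", "natural_abundance": 0.0061, "atomic_mass": 69.92532},
    {"name": "Sn-112", "element": "Sn", "natural_abundance": 0.0097, "atomic_mass": 111.90482},
    {"name": "Sn-114", "element": "Sn", "natural_abundance": 0.0066, "atomic_mass": 113.90278},
    {"name": "Sn-115", "element": "Sn", "natural_abundance": 0.0034, "atomic_mass": 114.90334},
    {"name": "Sn-116", "element": "Sn", "natural_abundance": 0.1454, "atomic_mass": 115.90174},
    {"name": "Sn-117", "element": "Sn", "natural_abundance": 0.0768, "atomic_mass": 116.90295},
    {"name": "Sn-118", "element": "Sn", "natural_abundance": 0.2422, "atomic_mass": 117.90161},
    {"name": "Sn-119", "element": "Sn", "natural_abundance": 0.0859, "atomic_mass": 118.90331},
    {"name": "Sn-120", "element": "Sn", "natural_abundance": 0.3258, "atomic_mass": 119.90220},
    {"name": "Sn-122", "element": "Sn", "natural_abundance": 0.0463, "atomic_mass": 121.90344},
    {"name": "Sn-124", "element": "Sn", "natural_abundance": 0.0579, "atomic_mass": 123.90527}
  ],
  "nuclides": [
    {
      "name": "Cu-62",
      "half_life_min": 9.67,
      "decay_modes": [["beta_plus", 0.978], ["electron_capture", 0.022]],
      "gamma_lines": [[875.7, 0.0015], [1173.0, 0.0034]],
      "positron_fraction": 0.978
    },
    {
      "name": "Cu-64",
      "half_life_min": 762.0,
      "decay_modes": [["beta_minus", 0.385], ["beta_plus", 0.176], ["electron_capture", 0.439]],
      "gamma_lines": [[1345.77, 0.00475]],
      "positron_fraction": 0.176
    },
    {
      "name": "Cu-66",
      "half_life_min": 5.12,
      "decay_modes": [["beta_minus", 1.0]],
      "gamma_lines": [[1039.2, 0.0923]],
      "positron_fraction": 0.0
    },
    {
      "name": "Zn-63",
      "half_life_min": 38.47,
      "decay_modes": [["beta_plus", 0.927], ["electron_capture", 0.073]],
      "gamma_lines": [[669.62, 0.082], [962.06, 0.065]],
      "positron_fraction": 0.927
    },
    {
      "name": "Zn-65",
      "half_life_min": 351259.2,
      "decay_modes": [["beta_plus", 0.0142], ["electron_capture", 0.9858]],
      "gamma_lines": [[1115.54, 0.5004]],
      "positron_fraction": 0.0142
    },
    {
      "name": "Zn-69",
      "half_life_min": 56.4,
      "decay_modes": [["beta_minus", 1.0]],
      "gamma_lines": [],
      "positron_fraction": 0.0
    },
    {
      "name": "Sn-123m",
      "half_life_min": 40.06,
      "decay_modes": [["beta_minus", 1.0]],
      "gamma_lines": [[160.33, 0.857]],
      "positron_fraction": 0.0
    }
  ],
  "channels": [
    {"parent": "Cu-63", "reaction": "n_capture", "product": "Cu-64", "sigma_thermal": 4.5},
    {"parent": "Cu-65", "reaction": "n_capture", "product": "Cu-66", "sigma_thermal": 2.17},
    {"parent": "Zn-64", "reaction": "n_capture", "product": "Zn-65", "sigma_thermal": 0.76},
    {"parent": "Zn-68", "reaction": "n_capture", "product": "Zn-69", "sigma_thermal": 0.072},
    {"parent": "Cu-63", "reaction": "photo_neutron", "product": "Cu-62", "threshold": 10.85},
    {"parent": "Cu-65", "reaction": "photo_neutron", "product": "Cu-64", "threshold": 9.91},
    {"parent": "Zn-64", "reaction": "photo_neutron", "product": "Zn-63", "threshold": 11.86},
    {"parent": "Zn-66", "reaction": "photo_neutron", "product": "Zn-65", "threshold": 11.06},
    {"parent": "Sn-124", "reaction": "photo_neutron", "product": "Sn-123m", "threshold": 8.49}
  ]
}
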