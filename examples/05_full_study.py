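"""Run the complete synthetic study from the packaged configuration.

predict -> simulate -> fit -> dose, with every artifact written to disk
and hashed in a manifest (rerunning with the same seed is byte-identical).
"""

import json
from pathlib import Path

from bmbkit.pipeline import StudyConfig, packaged_study_config, run_study

outdir = Path("study_output")
cfg = StudyConfig.from_dict(packaged_study_config())
manifest = run_study(cfg, outdir)

print(f"wrote {len(manifest['files'])} artifacts to {outdir}/ "
      f"(constants {manifest['constants_sha256'][:12]}...)")

fit = json.loads((outdir / "fit_report.json").read_text())
dose = json.loads((outdir / "dose_report.json").read_text())

print("\nDecay-curve decomposition of the simulated 511 keV series:")
for name, entry in fit["mixture"]["fractions"].items():
    print(f"  {name:6s} {entry['value'] * 100:6.2f} %")
print(f"effective half-life (full 2-h window): {fit['mono']['effective_half_life_min']:.2f} min")

print(f"\ndeep-dose course projection : {dose['deep_dose']['course_mrem']:.3f} mrem "
      f"({dose['deep_dose']['percent_of_tede']:.3f}% of TEDE limit)")
print(f"skin-dose course projection : {dose['skin_dose']['course_mrem']:.2f} mrem "
      f"({dose['skin_dose']['percent_of_extremity']:.3f}% of extremity limit)")
print("\nBoth projections assume a worst case: the same therapist handles the bolus")
print("immediately after all 25 fractions, with full decay overnight between them.")
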