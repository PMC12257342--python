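"""Recover half-lives and component fractions from noisy count series.

Demonstrates both fit models: the mono-exponential effective half-life
(window-dependent for a mixture) and the fixed-half-life mixture
decomposition that recovers the 87/13 Cu-62/Zn-63 split.
"""

import bmbkit as bk
from bmbkit.fitting import restrict_window

lib = bk.default_library()

# a pure Sn-123m series, as measured on the 160 keV peak after 10 MV irradiation
sn = bk.MixtureDecay([(lib.get_nuclide("Sn-123m"), 1.0)])
series = bk.simulate_decay_series(sn, rate_at_t0_cpm=2e5, duration_min=120, seed=42)
fit = bk.fit_monoexponential(series, fit_background=False)
print(f"Sn-123m series: fitted T1/2 = {fit.half_life_min:.3f} +/- {fit.half_life_se:.3f} min "
      f"(true 40.06; R^2 = {fit.r_squared:.5f})")

# the 511 keV peak series: a Cu-62/Zn-63 mixture
mix = bk.MixtureDecay([(lib.get_nuclide("Cu-62"), 0.87), (lib.get_nuclide("Zn-63"), 0.13)])
series511 = bk.simulate_decay_series(mix, rate_at_t0_cpm=1e5, duration_min=120, seed=7)

print("\nEffective half-life of the mixed 511 keV curve vs fitting window:")
for window in (30, 60, 120):
    f = bk.fit_monoexponential(restrict_window(series511, window), fit_background=False)
    print(f"  first {window:3d} min -> T1/2,eff = {f.half_life_min:6.2f} min")
print("(longer windows weight the slower Zn-63 more; an 'effective half-life' is")
print(" only meaningful together with its window)")

cands = [lib.get_nuclide(n) for n in ("Cu-62", "Cu-64", "Zn-63")]
mfit = bk.fit_fixed_mixture(series511, cands, allow_background=False)
print("\nFixed-mixture decomposition of the same series:")
for name, (value, se) in mfit.fractions.items():
    print(f"  {name:6s} {value * 100:6.2f} +/- {se * 100:.2f} %")
print("Cu-64's share fits to ~0: its 12.7 h half-life cannot mimic a curve that")
print("dies away within the 2-hour measurement.")
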