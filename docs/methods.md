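# Methods

## Physical model

### Activation

A brass bolus in a clinical photon beam is activated through two
channels:

* **Thermal neutron capture** (n,γ). The linac head is a neutron source
  whenever the beam runs above the photonuclear threshold of its
  high-Z components, so a thermal/epithermal neutron bath exists both in
  and out of the primary field. Capture channels are therefore always
  open. For parent isotope *i* with atom fraction N_i and thermal cross
  section σ_i producing a nuclide with decay constant λ_i, the activity
  at end of irradiation is A_i ∝ Φ·N_i·σ_i·(1−e^(−λ_i·t_irr)). The
  neutron fluence rate Φ is common to all channels and cancels in
  ratios; `bmbkit` therefore reports *relative* activities only and
  never needs Φ.
* **Photoneutron** (γ,n). Requires primary-beam photons above the
  channel threshold; a channel is treated as open when its threshold in
  MeV is below the nominal accelerating potential in MV (numerically
  equal), with a configurable per-channel margin (default 0). This rule
  marks the Cu-65 (9.91 MeV) channel as marginally open at 10 MV even
  though measured 10 MV spectra are dominated by Sn-123m; near-threshold
  (γ,n) yields are tiny, and the margin parameter exists to encode that
  if desired. Relative *yields* across photoneutron channels are not
  computed at all: they would require energy-dependent (γ,n) cross
  sections folded with the photon spectrum, which is out of scope.
  Photoneutron composition is instead *measured* from decay curves
  (fixed-mixture fitting), which is also how the bench study obtained
  it. Requesting photoneutron relative activities raises
  `PhotoneutronYieldError` by design.

The **short-irradiation limit** (saturation factor → λ_i·t_irr, i.e.
N·σ·λ weighting) is the default for capture fractions: clinical beam-on
times of 1–2 minutes are short against every product half-life here
(shortest: Cu-66 at 5.12 min). With the bundled constants this gives
Cu-66 ≈ 96.9% of capture activity for 70/30 brass. Both limits are
exposed (t_irr may be given explicitly) and tested: fractions converge
to N·σ·λ as t_irr → 0 and to N·σ as t_irr → ∞.

Multi-fraction buildup of residual activity over a course of identical
daily irradiations uses the geometric sum
B_n = (1−e^(−nλT))/(1−e^(−λT)); only long-lived products (Zn-65,
T½ 243.9 d: B_25 ≈ 24.2 at 24 h spacing) accumulate appreciably.

One known discrepancy is documented rather than forced: under the
short-limit capture model Cu-64 carries ≈3% of capture activity, while
the narrative the study inherited from earlier literature quotes a far
smaller Cu-64 share. The difference traces to the irradiation-time
assumption and the activation calculator used there; the 97% Cu-66
headline is insensitive to it.

### Decay kinetics

A measured peak's count rate is modeled as a mixture of independent
exponentials anchored at end of irradiation, A(t) = Σ f_i·e^(−λ_i t),
with f_i fractions of *initial activity* (count rate) — the same
parameterization a region-of-interest fit produces. All interval doses
and rate inversions are closed-form; `halving_time` (the t with
A(t) = ½, found by Brent bracketing between the extreme component
half-lives, tolerance 1e-6 min) is deliberately distinguished from the
*effective half-life*, which is a fit output and window-dependent.
Internal time unit: minutes everywhere; conversions at the boundary.
No Bateman parent→daughter chains: none of the products here feed each
other on the relevant timescales.

For the 87/13 Cu-62/Zn-63 mixture the model gives: A(12.16 min) ≈ 0.468,
halving time ≈ 11.07 min, a 2-h integrated activity of 18.52 min, and a
first-minute share of 5.23%. The bench decay curve gave 5.39% for that
share and an effective half-life of 12.16 min; the gaps are expected —
the measured curve contains background, dead-time and shape departures
from a pure two-exponential, and the effective half-life depends on the
(unreported) fit window — and are not tuned away. Dose projections use
the *measured* 5.39% where the point is to reproduce the study
arithmetic, and the model fraction where the point is prediction; both
paths are exposed.

## Synthetic measurements

The spectroscopy module emulates a small NaI(Tl) crystal watching the
activated mesh:

* Gaussian photopeaks with FWHM(E) = k·√E, default k = 2.0 keV^0.5
  (≈7.7% FWHM at 662 keV, typical small-crystal NaI); flat efficiency
  (default 0.05 counts/photon); flat background (counts/s/bin);
  1024 bins over 0–2000 keV, linear calibration.
* Line intensities from the bundled catalog; the 511 keV annihilation
  line is derived as 2 × positron fraction so every β⁺ emitter feeds it
  consistently.
* Expected counts per line integrate the component's decay over the
  acquisition window exactly; Poisson sampling is seeded and mandatory
  (no hidden RNG state); an expectation mode returns the noiseless mean.

Not emulated, deliberately: Compton continua (the flat background is the
stand-in), escape/sum peaks, dead time, energy-calibration drift.
Passing tests therefore demonstrate the *analysis chain* — peak finding,
absence reporting, ROI extraction, decay fitting, dose arithmetic — on
data whose idealizations are known, not detector physics. Conclusions
that rest on peak-area ratios and decay constants transfer; conclusions
about spectral shape would not.

Peak identification: local maxima of a lightly smoothed spectrum whose
net area in a ±1 FWHM window exceeds 3·√(background area), background
estimated from flanking sidebands — the conventional detection limit.
511 keV matches every positron emitter in the catalog (the ambiguity is
physical and preserved); catalog lines with no matching peak are
returned as an absence report, because the mechanism argument rests on
which predicted peaks fail to appear. When several lines fall within
tolerance, candidates are reported alphabetically.

## Decay fitting

Both fit models work on *expected counts per interval* — the exact time
integral of the rate over each bin, not the rate at the bin center — so
noiseless synthetic series are recovered to machine precision and binned
counting data introduce no discretization bias. Poisson weighting uses
var = counts with a floor of 1 for empty bins.

* **Mono-exponential** (`lmfit` Levenberg–Marquardt, bounds a ≥ 0,
  T½ > 0, b ≥ 0): reports the effective half-life with its covariance
  standard error. For mixtures this is window-dependent by construction
  (tested: 11.8 → 13.2 → 15.3 min over 30/60/120-min windows for the
  87/13 mixture), which is why no single "effective T½" value is treated
  as a constant of nature.
* **Fixed mixture**: non-negative least squares on the exponential basis
  with half-lives frozen at catalog values (plus optional constant
  background column). Freezing the λ_j is what keeps the problem
  well-posed; free multi-exponential fitting is notoriously
  ill-conditioned and is a non-goal. Candidates with half-lives within
  0.1% of each other are rejected as degenerate. Fraction standard
  errors come from the unconstrained weighted-LS covariance at the
  solution via the delta method; a seeded bootstrap is not provided in
  this version.

R² is computed on the weighted scale (1 − SS_res/SS_tot). A perfectly
fitting model gives R² = 1; the implausibly low R² sometimes quoted for
visually good decay fits is not reproducible from any statistic computed
here and is not targeted.

## Dosimetry

All projections are linear in MU (activation ∝ MU at fixed energy),
handling time (rate pathway) and number of fractions (full inter-fraction
decay, the default; otherwise per-nuclide buildup factors multiply each
fraction). Two calibration pathways:

* **rate** (survey meter at contact, deep-dose-like): per-fraction dose =
  MU-scaled rate × handling time. Decay correction during handling is
  available but off by default — over a 1-minute handling window it is a
  ≈3% effect for the 87/13 mixture, and the study's arithmetic is the
  uncorrected product.
* **integrated** (dosimeter folded in the mesh): per-fraction dose =
  MU-scaled reading × interval fraction of the decay curve over the
  handling window, supplied (measured) or computed from the mixture
  model. The initial dose rate uses the first-minute estimator
  (reading × first-minute fraction × 60), which agrees with the exact
  kinetic inversion D/∫A to within 1% for the 87/13 mixture.

Exposure (mR) and dose (mrem) are treated as numerically interchangeable,
as is conventional for these photon fields; reports carry an explicit
flag. Limits default to 10 CFR 20 (5000 mrem/yr TEDE, 50000 mrem/yr
extremity) and are configurable. Reports print at 3 decimals. The
distance table reproduces survey rows from their printed per-MU rates;
rows printed from unrounded rates can differ from the printed-rate
product by up to the rounding of that rate (≈1% at contact, worse at
distance), and agreement is asserted only within that rounding.

## Pipeline and reproducibility

`run_study` executes predict → simulate → fit → dose from one JSON
config. Every stochastic stage takes an explicit seed derived from the
config; rerunning a config yields byte-identical CSV/JSON payloads,
verified by SHA-256 in the manifest, which also records the
nuclear-constants file hash. A packaged config reproduces the 15 MV
in-field study end to end.

## Problem sizes and defaults

Defaults mirror the study conditions: 70/30 Cu/Zn brass (composition of
the commercial mesh is proprietary; a tin-bearing "white brass" variant
is provided), 25 fractions × 500 MU, 1-minute handling at zero delay,
2-hour decay measurements in 1-minute bins, full overnight decay between
fractions. Synthetic decay series for fit validation use initial rates
of 1e5–2e5 cpm; at 2e5 cpm a 2-h Sn-123m series carries ≈1.2e7 counts,
putting the fitted half-life's statistical standard error near 0.06% —
comfortably below the 0.2% agreement such series are used to
demonstrate. Seed-ensemble properties (parameter recovery, Poisson
calibration) use 200 seeds. The whole test suite runs in a few seconds
on one CPU.

## Known limitations

* No absolute activities (Bq) or fluence modeling; ratios only.
* Photoneutron yields are measured (fitted), never predicted.
* Detector response is idealized (see above); no MCA file formats.
* The in/out-of-field activation ratio (~27×) and the
  isocenter-to-out-of-field neutron fluence ratio (~3.3) are treated as
  external observations, not model outputs.
* Patient dose and painted-vs-unpainted alloy comparisons are out of
  scope.
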