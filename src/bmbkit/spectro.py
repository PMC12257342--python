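"""Synthetic NaI(Tl) gamma spectra and region-of-interest count series.

Stands in for the bench measurements: given an activation inventory and a
detector model, it produces energy spectra (Gaussian-broadened emission
lines over a flat background, Poisson counting noise) and counts-per-minute
time series in an energy region of interest (ROI).  Peak identification
matches detected spectral peaks against the nuclide catalog and reports
catalog lines that are *absent* — the in-field/out-of-field comparison that
distinguishes photoneutron from neutron-capture activation rests on which
predicted peaks fail to appear.

Simplifications (documented, deliberate): detector efficiency is flat in
energy; the Compton continuum is approximated by the flat background; no
escape/sum peaks or dead time.  Peak-area ratios and decay curves, not the
detailed spectral shape, carry the analysis.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import erf

from .activation import ActivationInventory
from .kinetics import MixtureDecay
from .nuclear_data import Nuclide

__all__ = [
    "DetectorModel",
    "EnergySpectrum",
    "CountTimeSeries",
    "PeakMatch",
    "PeakIdentification",
    "generate_spectrum",
    "identify_peaks",
    "roi_timeseries",
    "simulate_decay_series",
    "mixture_from_inventory",
    "default_bin_edges",
    "SpectroError",
]

_FWHM_TO_SIGMA = 2.0 * math.sqrt(2.0 * math.log(2.0))


class SpectroError(ValueError):
    """Invalid spectroscopy input."""


@dataclass(frozen=True)
class DetectorModel:
    """Idealized NaI(Tl) detector response.

    ``resolution_k`` sets FWHM(E) = k * sqrt(E) in keV (default 2.0, about
    7.7% FWHM at 662 keV, typical for small NaI crystals).  ``efficiency``
    is a flat counts-per-emitted-photon factor; ``background_rate`` is a
    flat continuum in counts per second per bin.
    """

    resolution_k: float = 2.0
    efficiency: float = 0.05
    background_rate: float = 0.0

    def __post_init__(self):
        if self.resolution_k <= 0:
            raise SpectroError("resolution_k must be > 0")
        if not 0.0 < self.efficiency <= 1.0:
            raise SpectroError("efficiency must be in (0, 1]")
        if self.background_rate < 0:
            raise SpectroError("background_rate must be >= 0")

    def fwhm(self, energy_kev: float) -> float:
        return self.resolution_k * math.sqrt(energy_kev)

    def sigma(self, energy_kev: float) -> float:
        return self.fwhm(energy_kev) / _FWHM_TO_SIGMA


def default_bin_edges(n_bins: int = 1024, e_max_kev: float = 2000.0) -> np.ndarray:
    """Linear energy calibration: ``n_bins`` bins over [0, e_max) keV."""
    return np.linspace(0.0, e_max_kev, n_bins + 1)


@dataclass(frozen=True)
class EnergySpectrum:
    """Binned gamma spectrum: half-open [lo, hi) energy bins and counts.

    ``counts`` are integers in sampled spectra and may be non-integral in
    expectation mode.  ``start_min`` is the acquisition start relative to
    end of irradiation.
    """

    bin_edges: np.ndarray
    counts: np.ndarray
    live_time_s: float
    start_min: float = 0.0

    def __post_init__(self):
        edges = np.asarray(self.bin_edges, dtype=float)
        counts = np.asarray(self.counts, dtype=float)
        if counts.shape != (edges.size - 1,):
            raise SpectroError("len(counts) must equal len(bin_edges) - 1")
        if np.any(np.diff(edges) <= 0):
            raise SpectroError("bin_edges must be strictly increasing")
        if np.any(counts < 0):
            raise SpectroError("counts must be >= 0")
        if self.live_time_s <= 0:
            raise SpectroError("live_time_s must be > 0")
        object.__setattr__(self, "bin_edges", edges)
        object.__setattr__(self, "counts", counts)

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    def total_counts(self) -> float:
        return float(self.counts.sum())

    def to_csv(self, path: str | Path) -> None:
        """Write ``e_lo_keV,e_hi_keV,counts`` plus a JSON sidecar of metadata."""
        path = Path(path)
        pd.DataFrame(
            {
                "e_lo_keV": self.bin_edges[:-1],
                "e_hi_keV": self.bin_edges[1:],
                "counts": self.counts,
            }
        ).to_csv(path, index=False)
        sidecar = path.with_suffix(path.suffix + ".json")
        sidecar.write_text(
            json.dumps({"live_time_s": self.live_time_s, "start_min": self.start_min}) + "\n"
        )

    @classmethod
    def from_csv(cls, path: str | Path) -> "EnergySpectrum":
        path = Path(path)
        df = pd.read_csv(path)
        meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
        edges = np.append(df["e_lo_keV"].to_numpy(), df["e_hi_keV"].to_numpy()[-1])
        return cls(edges, df["counts"].to_numpy(), meta["live_time_s"], meta["start_min"])


@dataclass(frozen=True)
class CountTimeSeries:
    """ROI counts per acquisition interval over time.

    ``times_min`` are interval start times (minutes after end of
    irradiation); ``live_times_s`` the per-interval live times.
    """

    times_min: np.ndarray
    counts: np.ndarray
    live_times_s: np.ndarray
    roi_kev: tuple[float, float] | None = None

    def __post_init__(self):
        t = np.asarray(self.times_min, dtype=float)
        c = np.asarray(self.counts, dtype=float)
        lt = np.broadcast_to(np.asarray(self.live_times_s, dtype=float), t.shape).copy()
        if t.ndim != 1 or c.shape != t.shape:
            raise SpectroError("times and counts must be 1-D and equal length")
        if np.any(np.diff(t) <= 0):
            raise SpectroError("times must be strictly increasing")
        if np.any(c < 0):
            raise SpectroError("counts must be >= 0")
        if np.any(lt <= 0):
            raise SpectroError("live times must be > 0")
        object.__setattr__(self, "times_min", t)
        object.__setattr__(self, "counts", c)
        object.__setattr__(self, "live_times_s", lt)

    def __len__(self) -> int:
        return self.times_min.size

    @property
    def cpm(self) -> np.ndarray:
        """Counts per minute per interval."""
        return self.counts * 60.0 / self.live_times_s

    @property
    def bin_widths_min(self) -> np.ndarray:
        return self.live_times_s / 60.0

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {"t_min": self.times_min, "counts": self.counts, "live_time_s": self.live_times_s}
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, roi_kev: tuple[float, float] | None = None) -> "CountTimeSeries":
        df = pd.read_csv(path)
        return cls(df["t_min"].to_numpy(), df["counts"].to_numpy(), df["live_time_s"].to_numpy(), roi_kev)


def mixture_from_inventory(inv: ActivationInventory) -> MixtureDecay:
    """Decay mixture whose fractions are the inventory's normalized activities."""
    norm = inv.normalized()
    merged: dict[str, tuple[Nuclide, float]] = {}
    for n, a, _ in norm.entries:
        prev = merged.get(n.name)
        merged[n.name] = (n, a + (prev[1] if prev else 0.0))
    return MixtureDecay(list(merged.values()))


def generate_spectrum(
    inv: ActivationInventory,
    det: DetectorModel,
    window_min: tuple[float, float],
    *,
    seed: int | None = None,
    mode: str = "poisson",
    rate_at_t0_cpm: float = 1e5,
    bin_edges: np.ndarray | None = None,
) -> EnergySpectrum:
    """Simulate one acquisition of the activated sample.

    Each inventory component decays with its own constant; expected counts
    for an emission line are the component's time-integrated activity over
    the acquisition window, times line intensity and detector efficiency,
    spread as a Gaussian of FWHM k*sqrt(E) across the bins (annihilation at
    511 keV carries two photons per positron decay).  A flat background is
    added; in ``mode="poisson"`` counts are drawn Poisson with the given
    seed (mandatory), in ``mode="expectation"`` the noiseless expectation
    is returned.

    ``rate_at_t0_cpm`` scales the total decay rate registered at t=0.
    """
    t1, t2 = window_min
    if t1 < 0 or t2 <= t1:
        raise SpectroError(f"bad acquisition window [{t1}, {t2}]")
    if mode not in ("poisson", "expectation"):
        raise SpectroError(f"unknown mode {mode!r}")
    if mode == "poisson" and seed is None:
        raise SpectroError("poisson mode requires an explicit seed")
    edges = default_bin_edges() if bin_edges is None else np.asarray(bin_edges, dtype=float)
    live_time_s = (t2 - t1) * 60.0

    norm = inv.normalized() if inv.entries else inv
    expected = np.zeros(edges.size - 1)
    for nuc, frac, _ in norm.entries:
        lam = nuc.decay_constant_per_min
        integral = frac * (math.exp(-lam * t1) - math.exp(-lam * t2)) / lam  # minutes
        for energy, intensity in nuc.emission_lines():
            line_counts = rate_at_t0_cpm * integral * intensity * det.efficiency
            if line_counts <= 0:
                continue
            sigma = det.sigma(energy)
            z = (edges - energy) / (sigma * math.sqrt(2.0))
            cdf = 0.5 * (1.0 + erf(z))
            expected += line_counts * np.diff(cdf)
    expected += det.background_rate * live_time_s

    if mode == "expectation":
        counts = expected
    else:
        rng = np.random.default_rng(seed)
        counts = rng.poisson(expected).astype(float)
    return EnergySpectrum(edges, counts, live_time_s, start_min=t1)


@dataclass(frozen=True)
class PeakMatch:
    """One detected peak with its candidate nuclides (alphabetical)."""

    energy_kev: float
    net_area: float
    candidates: tuple[str, ...]


@dataclass(frozen=True)
class PeakIdentification:
    """Detected peaks matched to the catalog, plus unmatched catalog lines."""

    peaks: tuple[PeakMatch, ...]
    absent_lines: tuple[tuple[str, float], ...]  # (nuclide name, energy keV)

    def matched_nuclides(self) -> tuple[str, ...]:
        names = sorted({c for p in self.peaks for c in p.candidates})
        return tuple(names)

    def peak_near(self, energy_kev: float, tolerance_kev: float) -> PeakMatch | None:
        for p in self.peaks:
            if abs(p.energy_kev - energy_kev) <= tolerance_kev:
                return p
        return None


def _detect_peaks(spec: EnergySpectrum, det: DetectorModel, min_sig: float) -> list[tuple[float, float]]:
    """Significant local maxima as (centroid energy, net area)."""
    counts = spec.counts
    n = counts.size
    width = np.diff(spec.bin_edges)
    centers = spec.bin_centers
    # light smoothing so Poisson jitter does not spawn a maximum per bin
    kernel = np.ones(5) / 5.0
    smooth = np.convolve(counts, kernel, mode="same")
    peaks = []
    for i in range(2, n - 2):
        if not (smooth[i] >= smooth[i - 1] and smooth[i] >= smooth[i + 1] and smooth[i] > 0):
            continue
        if smooth[i - 1] == smooth[i] and smooth[i + 1] == smooth[i]:
            continue  # flat plateau (pure background)
        energy = centers[i]
        half_window = max(det.fwhm(energy), 2.0 * float(width[i]))
        in_win = np.abs(centers - energy) <= half_window
        side = (np.abs(centers - energy) > half_window) & (np.abs(centers - energy) <= 3 * half_window)
        if not side.any():
            continue
        bg_per_bin = float(np.median(counts[side]))
        area = float(counts[in_win].sum())
        bg_area = bg_per_bin * int(in_win.sum())
        net = area - bg_area
        if net <= 0 or net < min_sig * math.sqrt(max(bg_area, 1.0)):
            continue
        w = np.clip(counts[in_win] - bg_per_bin, 0.0, None)
        centroid = float(np.average(centers[in_win], weights=w)) if w.sum() > 0 else energy
        peaks.append((centroid, net, i))
    # merge maxima that fall inside one resolution element, keep the largest
    peaks.sort(key=lambda p: -p[1])
    kept: list[tuple[float, float]] = []
    for centroid, net, _ in peaks:
        if all(abs(centroid - e) > det.fwhm(centroid) for e, _ in kept):
            kept.append((centroid, net))
    kept.sort()
    return kept


def identify_peaks(
    spec: EnergySpectrum,
    catalog: Sequence[Nuclide],
    tolerance_kev: float = 15.0,
    det: DetectorModel | None = None,
    min_significance: float = 3.0,
) -> PeakIdentification:
    """Match significant spectral peaks to catalog emission lines.

    A peak is a local maximum whose net area exceeds ``min_significance``
    times the Poisson uncertainty of the local background in a +/-1 FWHM
    window.  A 511 keV peak matches *every* positron emitter in the catalog
    (the ambiguity is real and preserved).  Catalog lines with no matching
    peak are returned as the absence report — the evidence that a predicted
    activation mechanism is not operating.
    """
    if tolerance_kev <= 0:
        raise SpectroError("tolerance must be > 0")
    if spec.counts.size == 0 or spec.total_counts() == 0:
        raise SpectroError("empty spectrum")
    det = det or DetectorModel()
    detected = _detect_peaks(spec, det, min_significance)

    matches: list[PeakMatch] = []
    matched_lines: set[tuple[str, float]] = set()
    for energy, net in detected:
        cands = set()
        for nuc in catalog:
            for line_e, intensity in nuc.emission_lines():
                if intensity > 0 and abs(line_e - energy) <= tolerance_kev:
                    cands.add(nuc.name)
                    matched_lines.add((nuc.name, line_e))
        matches.append(PeakMatch(energy, net, tuple(sorted(cands))))

    absent = []
    for nuc in sorted(catalog, key=lambda n: n.name):
        for line_e, intensity in nuc.emission_lines():
            if intensity > 0 and (nuc.name, line_e) not in matched_lines:
                absent.append((nuc.name, line_e))
    return PeakIdentification(tuple(matches), tuple(absent))


def roi_timeseries(spectra: Sequence[EnergySpectrum], roi_kev: tuple[float, float]) -> CountTimeSeries:
    """Sum counts in an energy ROI across a sequence of spectra.

    All spectra must share the same binning; the ROI is snapped *outward*
    to bin edges so no partial bins are counted.
    """
    if not spectra:
        raise SpectroError("no spectra given")
    edges = spectra[0].bin_edges
    for s in spectra[1:]:
        if s.bin_edges.shape != edges.shape or not np.allclose(s.bin_edges, edges):
            raise SpectroError("spectra do not share a common binning")
    lo, hi = roi_kev
    if hi <= lo:
        raise SpectroError("ROI upper edge must exceed lower edge")
    i_lo = int(np.searchsorted(edges, lo, side="right") - 1)
    i_hi = int(np.searchsorted(edges, hi, side="left"))
    i_lo = max(i_lo, 0)
    i_hi = min(i_hi, edges.size - 1)
    if i_hi <= i_lo:
        raise SpectroError("ROI does not cover any bin")
    ordered = sorted(spectra, key=lambda s: s.start_min)
    times = np.array([s.start_min for s in ordered])
    counts = np.array([float(s.counts[i_lo:i_hi].sum()) for s in ordered])
    live = np.array([s.live_time_s for s in ordered])
    return CountTimeSeries(times, counts, live, roi_kev=(float(edges[i_lo]), float(edges[i_hi])))


def simulate_decay_series(
    mixture: MixtureDecay,
    rate_at_t0_cpm: float,
    duration_min: float,
    dt_min: float = 1.0,
    *,
    background_cpm: float = 0.0,
    seed: int | None = None,
    mode: str = "poisson",
) -> CountTimeSeries:
    """Synthetic ROI count series for a decay mixture.

    Expected counts in each interval are the mixture activity integrated
    over the interval (times the t=0 rate) plus a flat background; Poisson
    noise is applied unless ``mode="expectation"``.
    """
    if rate_at_t0_cpm <= 0 or duration_min <= 0 or dt_min <= 0:
        raise SpectroError("rate, duration and dt must be > 0")
    if background_cpm < 0:
        raise SpectroError("background must be >= 0")
    if mode not in ("poisson", "expectation"):
        raise SpectroError(f"unknown mode {mode!r}")
    if mode == "poisson" and seed is None:
        raise SpectroError("poisson mode requires an explicit seed")
    n = int(round(duration_min / dt_min))
    starts = np.arange(n) * dt_min
    expected = np.array(
        [rate_at_t0_cpm * mixture.integrated_activity(t, t + dt_min) for t in starts]
    )
    expected += background_cpm * dt_min
    if mode == "expectation":
        counts = expected
    else:
        rng = np.random.default_rng(seed)
        counts = rng.poisson(expected).astype(float)
    return CountTimeSeries(starts, counts, np.full(n, dt_min * 60.0))
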