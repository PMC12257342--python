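"""Synthetic spectra, peak identification and ROI extraction."""

import math

import numpy as np
import pytest

import bmbkit as bk
from bmbkit.activation import ActivationInventory
from bmbkit.kinetics import MixtureDecay
from bmbkit.spectro import (
    CountTimeSeries,
    DetectorModel,
    EnergySpectrum,
    SpectroError,
    default_bin_edges,
    generate_spectrum,
    identify_peaks,
    mixture_from_inventory,
    roi_timeseries,
    simulate_decay_series,
)


@pytest.fixture(scope="module")
def photoneutron_inventory(cu62, zn63):
    """In-field 15 MV inventory at the fitted 87/13 activity split."""
    return ActivationInventory(((cu62, 0.87, "photo_neutron"), (zn63, 0.13, "photo_neutron")))


@pytest.fixture(scope="module")
def capture_inventory(brass):
    return bk.relative_activities(brass, "n_capture")


@pytest.fixture(scope="module")
def detector():
    return DetectorModel(background_rate=0.2)


def _catalog(lib, *names):
    return [lib.get_nuclide(n) for n in names]


class TestGenerateSpectrum:
    def test_photoneutron_spectrum_dominated_by_annihilation_peak(
        self, photoneutron_inventory, detector
    ):
        spec = generate_spectrum(
            photoneutron_inventory, detector, (0, 5), seed=11, rate_at_t0_cpm=2e5
        )
        centers = spec.bin_centers
        bg = detector.background_rate * spec.live_time_s
        peak_bin = int(np.argmax(spec.counts - bg))
        assert abs(centers[peak_bin] - 511.0) < detector.fwhm(511.0)

    def test_tin_only_inventory_peaks_at_160_kev(self, sn123m):
        inv = ActivationInventory(((sn123m, 1.0, "photo_neutron"),))
        spec = generate_spectrum(inv, DetectorModel(), (0, 10), seed=2, rate_at_t0_cpm=1e5)
        assert abs(spec.bin_centers[int(np.argmax(spec.counts))] - 160.33) < 10.0

    def test_empty_inventory_zero_background_is_all_zero(self):
        inv = ActivationInventory(())
        spec = generate_spectrum(inv, DetectorModel(), (0, 5), mode="expectation")
        assert spec.total_counts() == 0.0

    def test_expectation_mode_conserves_line_counts(self, photoneutron_inventory):
        det = DetectorModel(efficiency=0.05)
        spec = generate_spectrum(
            photoneutron_inventory, det, (0, 5), mode="expectation", rate_at_t0_cpm=2e5
        )
        expected = 0.0
        for nuc, frac, _ in photoneutron_inventory.normalized().entries:
            lam = nuc.decay_constant_per_min
            integral = frac * (1 - math.exp(-lam * 5)) / lam
            expected += 2e5 * integral * det.efficiency * sum(i for _, i in nuc.emission_lines())
        assert spec.total_counts() == pytest.approx(expected, rel=1e-4)

    def test_poisson_mode_matches_expectation_across_seeds(self, cu62):
        inv = ActivationInventory(((cu62, 1.0, "photo_neutron"),))
        det = DetectorModel(background_rate=0.1)
        edges = default_bin_edges(n_bins=64, e_max_kev=1280.0)
        exp = generate_spectrum(inv, det, (0, 2), mode="expectation",
                                rate_at_t0_cpm=5e4, bin_edges=edges)
        n_seeds = 200
        acc = np.zeros_like(exp.counts)
        for s in range(n_seeds):
            acc += generate_spectrum(inv, det, (0, 2), seed=s,
                                     rate_at_t0_cpm=5e4, bin_edges=edges).counts
        mean = acc / n_seeds
        se = np.sqrt(np.maximum(exp.counts, 1e-12) / n_seeds)
        z = np.abs(mean - exp.counts) / se
        assert np.mean(z < 3.0) > 0.99

    def test_seed_determinism(self, photoneutron_inventory, detector):
        a = generate_spectrum(photoneutron_inventory, detector, (0, 5), seed=4)
        b = generate_spectrum(photoneutron_inventory, detector, (0, 5), seed=4)
        assert np.array_equal(a.counts, b.counts)

    def test_poisson_mode_requires_seed(self, photoneutron_inventory, detector):
        with pytest.raises(SpectroError, match="seed"):
            generate_spectrum(photoneutron_inventory, detector, (0, 5))

    def test_bad_window_rejected(self, photoneutron_inventory, detector):
        with pytest.raises(SpectroError):
            generate_spectrum(photoneutron_inventory, detector, (-1, 5), seed=1)
        with pytest.raises(SpectroError):
            generate_spectrum(photoneutron_inventory, detector, (5, 5), seed=1)


class TestIdentifyPeaks:
    def test_in_field_spectrum_reports_missing_cu66_line(
        self, lib, photoneutron_inventory, detector
    ):
        spec = generate_spectrum(
            photoneutron_inventory, detector, (0, 5), seed=11, rate_at_t0_cpm=2e5
        )
        catalog = _catalog(lib, "Cu-62", "Cu-64", "Cu-66", "Zn-63", "Zn-65", "Zn-69")
        pid = identify_peaks(spec, catalog, det=detector)
        assert pid.peak_near(1039.2, 15.0) is None
        assert ("Cu-66", 1039.2) in pid.absent_lines

    def test_out_of_field_spectrum_shows_cu66(self, lib, capture_inventory, detector):
        spec = generate_spectrum(
            capture_inventory, detector, (0, 5), seed=12, rate_at_t0_cpm=5e5
        )
        pid = identify_peaks(spec, _catalog(lib, "Cu-66"), det=detector)
        match = pid.peak_near(1039.2, 15.0)
        assert match is not None and "Cu-66" in match.candidates

    def test_511_matches_every_positron_emitter_in_catalog(
        self, lib, photoneutron_inventory, detector
    ):
        spec = generate_spectrum(
            photoneutron_inventory, detector, (0, 5), seed=11, rate_at_t0_cpm=2e5
        )
        catalog = _catalog(lib, "Cu-62", "Cu-64", "Cu-66", "Zn-63", "Zn-65")
        pid = identify_peaks(spec, catalog, det=detector)
        match = pid.peak_near(511.0, 15.0)
        assert match is not None
        assert set(match.candidates) >= {"Cu-62", "Cu-64", "Zn-63", "Zn-65"}
        assert "Cu-66" not in match.candidates  # pure beta-minus emitter

    def test_single_synthetic_peak_exact_coincidence(self, lib, sn123m):
        inv = ActivationInventory(((sn123m, 1.0, "photo_neutron"),))
        spec = generate_spectrum(inv, DetectorModel(), (0, 10), seed=3, rate_at_t0_cpm=1e5)
        pid = identify_peaks(spec, [sn123m], det=DetectorModel())
        assert len([p for p in pid.peaks if p.candidates]) == 1
        assert pid.peaks[0].candidates == ("Sn-123m",)

    def test_empty_spectrum_rejected(self, lib):
        spec = EnergySpectrum(default_bin_edges(), np.zeros(1024), live_time_s=60.0)
        with pytest.raises(SpectroError, match="empty"):
            identify_peaks(spec, _catalog(lib, "Cu-66"))

    def test_nonpositive_tolerance_rejected(self, lib, sn123m):
        inv = ActivationInventory(((sn123m, 1.0, "photo_neutron"),))
        spec = generate_spectrum(inv, DetectorModel(), (0, 10), seed=3)
        with pytest.raises(SpectroError):
            identify_peaks(spec, [sn123m], tolerance_kev=0.0)


class TestRoiTimeseries:
    def test_all_zero_spectra_give_zero_series(self):
        inv = ActivationInventory(())
        specs = [
            generate_spectrum(inv, DetectorModel(), (t, t + 1), mode="expectation")
            for t in range(3)
        ]
        series = roi_timeseries(specs, (480, 545))
        assert np.all(series.counts == 0)

    def test_single_spectrum_degenerate_series(self, sn123m):
        inv = ActivationInventory(((sn123m, 1.0, "photo_neutron"),))
        spec = generate_spectrum(inv, DetectorModel(), (0, 1), seed=9)
        series = roi_timeseries([spec], (140, 180))
        assert len(series) == 1

    def test_expectation_series_tracks_mixture_activity(self, photoneutron_inventory):
        mix = mixture_from_inventory(photoneutron_inventory)
        specs = [
            generate_spectrum(photoneutron_inventory, DetectorModel(), (t, t + 1),
                              mode="expectation", rate_at_t0_cpm=1e5)
            for t in range(0, 40, 2)
        ]
        series = roi_timeseries(specs, (460, 560))
        # each component emits into the 511 keV ROI at 2 x its positron fraction
        comps = dict((n.name, (n, f)) for n, f in mix.components)
        expected = np.array([
            sum(f * 2 * n.positron_fraction
                * (np.exp(-n.decay_constant_per_min * t) - np.exp(-n.decay_constant_per_min * (t + 1)))
                / n.decay_constant_per_min
                for n, f in comps.values())
            for t in range(0, 40, 2)
        ])
        ratio = series.counts / expected
        assert np.ptp(ratio) / ratio.mean() < 1e-6  # proportional to the ROI emission curve

    def test_pure_nuclide_log_series_recovers_half_life(self, sn123m):
        inv = ActivationInventory(((sn123m, 1.0, "photo_neutron"),))
        specs = [
            generate_spectrum(inv, DetectorModel(), (t, t + 1), mode="expectation",
                              rate_at_t0_cpm=1e5)
            for t in range(0, 120)
        ]
        series = roi_timeseries(specs, (100, 220))
        # counts_i = C * integral of exp(-lam t) over bin i: log is linear with slope -lam
        slope = np.polyfit(series.times_min, np.log(series.counts), 1)[0]
        assert math.log(2) / -slope == pytest.approx(40.06, rel=1e-6)

    def test_roi_snaps_outward_to_bin_edges(self, sn123m):
        inv = ActivationInventory(((sn123m, 1.0, "photo_neutron"),))
        spec = generate_spectrum(inv, DetectorModel(), (0, 1), seed=9)
        series = roi_timeseries([spec], (100.7, 220.3))
        lo, hi = series.roi_kev
        width = spec.bin_edges[1] - spec.bin_edges[0]
        assert lo <= 100.7 and hi >= 220.3
        assert lo % width == pytest.approx(0.0, abs=1e-9)

    def test_mismatched_binning_rejected(self, sn123m):
        inv = ActivationInventory(((sn123m, 1.0, "photo_neutron"),))
        a = generate_spectrum(inv, DetectorModel(), (0, 1), seed=1)
        b = generate_spectrum(inv, DetectorModel(), (1, 2), seed=2,
                              bin_edges=default_bin_edges(n_bins=512))
        with pytest.raises(SpectroError, match="binning"):
            roi_timeseries([a, b], (140, 180))

    def test_cpm_conversion(self):
        series = CountTimeSeries(np.array([0.0, 1.0]), np.array([120.0, 60.0]),
                                 np.array([60.0, 60.0]))
        assert series.cpm == pytest.approx([120.0, 60.0])


class TestSimulateDecaySeries:
    def test_expectation_matches_closed_form(self, annihilation_mixture):
        series = simulate_decay_series(annihilation_mixture, 1e4, 10, 1, mode="expectation")
        expected = [1e4 * annihilation_mixture.integrated_activity(t, t + 1) for t in range(10)]
        assert series.counts == pytest.approx(expected)

    def test_seeded_reproducibility(self, annihilation_mixture):
        a = simulate_decay_series(annihilation_mixture, 1e4, 30, 1, seed=8)
        b = simulate_decay_series(annihilation_mixture, 1e4, 30, 1, seed=8)
        assert np.array_equal(a.counts, b.counts)

    def test_background_adds_flat_rate(self, annihilation_mixture):
        with_bg = simulate_decay_series(annihilation_mixture, 1e4, 10, 1,
                                        background_cpm=50.0, mode="expectation")
        without = simulate_decay_series(annihilation_mixture, 1e4, 10, 1, mode="expectation")
        assert with_bg.counts - without.counts == pytest.approx(np.full(10, 50.0))

    def test_poisson_requires_seed(self, annihilation_mixture):
        with pytest.raises(SpectroError, match="seed"):
            simulate_decay_series(annihilation_mixture, 1e4, 10, 1)


class TestCsvRoundTrips:
    def test_spectrum_round_trip(self, tmp_path, sn123m):
        inv = ActivationInventory(((sn123m, 1.0, "photo_neutron"),))
        spec = generate_spectrum(inv, DetectorModel(), (2, 4), seed=5)
        path = tmp_path / "spec.csv"
        spec.to_csv(path)
        back = EnergySpectrum.from_csv(path)
        assert np.array_equal(back.counts, spec.counts)
        assert back.live_time_s == spec.live_time_s
        assert back.start_min == spec.start_min

    def test_series_round_trip(self, tmp_path, annihilation_mixture):
        series = simulate_decay_series(annihilation_mixture, 1e4, 20, 1, seed=6)
        path = tmp_path / "series.csv"
        series.to_csv(path)
        back = CountTimeSeries.from_csv(path)
        assert np.array_equal(back.counts, series.counts)
        assert np.array_equal(back.times_min, series.times_min)
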