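"""Occupational dose projections: MU scaling, course doses, limits, distances."""

import numpy as np
import pytest

import bmbkit as bk
from bmbkit.dosimetry import (
    ContactCalibration,
    DoseLimits,
    DosimetryError,
    ExposureScenario,
    course_dose_from_integrated,
    course_dose_from_rate,
    distance_table,
    percent_of_limits,
    scale_by_mu,
)

TABLE_RATES = [(5, 0.0017), (10, 0.0011), (20, 0.0005), (30, 0.0004), (40, 0.0003)]


@pytest.fixture
def rate_cal(annihilation_mixture):
    """Survey-meter contact rate: 1.70 mrem/h after 1000 MU."""
    return ContactCalibration("rate", 1.70, 1000.0, decay_model=annihilation_mixture)


@pytest.fixture
def skin_cal(annihilation_mixture):
    """Dosimeter reading: 17.13 mrem over 2 h of contact after 1000 MU."""
    return ContactCalibration("integrated", 17.13, 1000.0, contact_duration_min=120.0,
                              decay_model=annihilation_mixture)


@pytest.fixture
def course_500():
    return ExposureScenario(mu_per_fraction=500.0, n_fractions=25, handling_time_min=1.0)


class TestScaleByMu:
    def test_halving_the_mu_halves_the_rate(self):
        assert scale_by_mu(1.70, 1000.0, 500.0) == pytest.approx(0.85)

    def test_identity(self):
        assert scale_by_mu(1.70, 1000.0, 1000.0) == 1.70

    def test_per_mu_rate_times_mu(self):
        assert scale_by_mu(0.0017, 1.0, 400.0) == pytest.approx(0.68)

    def test_nonpositive_mu_rejected(self):
        with pytest.raises(DosimetryError):
            scale_by_mu(1.0, 0.0, 500.0)


class TestCourseDoseFromRate:
    def test_deep_dose_course(self, rate_cal, course_500):
        rep = course_dose_from_rate(rate_cal, course_500)
        assert rep.course_mrem == pytest.approx(0.354, abs=0.0005)
        assert rep.initial_rate_mrem_per_h == pytest.approx(0.85)

    def test_zero_handling_time_gives_zero_dose(self, rate_cal):
        sc = ExposureScenario(mu_per_fraction=500.0, handling_time_min=0.0)
        assert course_dose_from_rate(rate_cal, sc).course_mrem == 0.0

    def test_half_handling_time_halves_dose(self, rate_cal, course_500):
        sc = ExposureScenario(mu_per_fraction=500.0, n_fractions=25, handling_time_min=0.5)
        rep = course_dose_from_rate(rate_cal, sc)
        assert rep.course_mrem == pytest.approx(0.177, abs=0.0005)

    def test_mixed_calibration_kind_rejected(self, skin_cal, course_500):
        with pytest.raises(DosimetryError):
            course_dose_from_rate(skin_cal, course_500)

    def test_decay_correction_reduces_dose(self, rate_cal, course_500):
        plain = course_dose_from_rate(rate_cal, course_500)
        corrected = course_dose_from_rate(rate_cal, course_500, decay_correct_handling=True)
        assert corrected.course_mrem < plain.course_mrem

    def test_decay_correction_equality_limit_for_long_half_life(self, lib, course_500):
        # effectively constant rate over 1 min when T1/2 is 244 d
        mix = bk.MixtureDecay([(lib.get_nuclide("Zn-65"), 1.0)])
        cal = ContactCalibration("rate", 1.70, 1000.0, decay_model=mix)
        plain = course_dose_from_rate(cal, course_500)
        corrected = course_dose_from_rate(cal, course_500, decay_correct_handling=True)
        assert corrected.course_mrem == pytest.approx(plain.course_mrem, rel=1e-5)

    def test_linearity_in_mu_and_fractions(self, rate_cal):
        base = course_dose_from_rate(
            rate_cal, ExposureScenario(mu_per_fraction=250.0, n_fractions=5)
        ).course_mrem
        doubled_mu = course_dose_from_rate(
            rate_cal, ExposureScenario(mu_per_fraction=500.0, n_fractions=5)
        ).course_mrem
        tripled_n = course_dose_from_rate(
            rate_cal, ExposureScenario(mu_per_fraction=250.0, n_fractions=15)
        ).course_mrem
        assert doubled_mu == pytest.approx(2 * base, rel=1e-12)
        assert tripled_n == pytest.approx(3 * base, rel=1e-12)

    def test_buildup_mode_exceeds_full_decay_for_long_lived(self, lib):
        mix = bk.MixtureDecay([(lib.get_nuclide("Zn-65"), 1.0)])
        cal = ContactCalibration("rate", 1.70, 1000.0, decay_model=mix)
        full_decay = course_dose_from_rate(
            cal, ExposureScenario(mu_per_fraction=500.0, n_fractions=25)
        )
        buildup = course_dose_from_rate(
            cal, ExposureScenario(mu_per_fraction=500.0, n_fractions=25,
                                  full_decay_between_fractions=False)
        )
        assert buildup.course_mrem > full_decay.course_mrem


class TestCourseDoseFromIntegrated:
    def test_skin_dose_with_measured_first_minute_fraction(self, skin_cal, course_500):
        rep = course_dose_from_integrated(skin_cal, course_500, first_interval_fraction=0.0539)
        assert rep.course_mrem == pytest.approx(11.54, abs=0.005)

    def test_skin_dose_at_400_mu(self, skin_cal):
        sc = ExposureScenario(mu_per_fraction=400.0, n_fractions=25, handling_time_min=1.0)
        rep = course_dose_from_integrated(skin_cal, sc, first_interval_fraction=0.0539)
        assert rep.course_mrem == pytest.approx(9.23, abs=0.005)

    def test_initial_rate_after_500_mu(self, skin_cal, course_500):
        rep = course_dose_from_integrated(skin_cal, course_500, first_interval_fraction=0.0539)
        assert rep.initial_rate_mrem_per_h == pytest.approx(27.7, abs=0.05)

    def test_model_fraction_close_to_measured(self, skin_cal, course_500):
        # decay-model fraction ~5.2% vs the measured 5.39%
        rep = course_dose_from_integrated(skin_cal, course_500)
        assert rep.assumptions["interval_fraction"] == pytest.approx(0.052, abs=0.001)
        assert rep.course_mrem == pytest.approx(11.2, abs=0.1)

    def test_initial_rate_consistent_with_kinetics_inversion(
        self, skin_cal, course_500, annihilation_mixture
    ):
        rep = course_dose_from_integrated(skin_cal, course_500, first_interval_fraction=0.0539)
        rate_model = annihilation_mixture.initial_rate_from_total(17.13, 120.0) * 60.0 * 0.5
        assert rep.initial_rate_mrem_per_h == pytest.approx(rate_model, rel=0.01)

    def test_fraction_outside_unit_interval_rejected(self, skin_cal, course_500):
        with pytest.raises(DosimetryError):
            course_dose_from_integrated(skin_cal, course_500, first_interval_fraction=1.2)

    def test_handling_longer_than_contact_rejected(self, skin_cal):
        sc = ExposureScenario(mu_per_fraction=500.0, handling_time_min=200.0)
        with pytest.raises(DosimetryError):
            course_dose_from_integrated(skin_cal, sc, first_interval_fraction=0.5)


class TestPercentOfLimits:
    def test_deep_dose_against_tede(self):
        pct, _ = percent_of_limits(0.354)
        assert round(pct, 3) == 0.007

    def test_skin_dose_against_extremity(self):
        _, pct = percent_of_limits(11.54)
        assert round(pct, 3) == 0.023

    def test_zero_dose(self):
        assert percent_of_limits(0.0) == (0.0, 0.0)

    def test_custom_limits(self):
        pct, _ = percent_of_limits(100.0, DoseLimits(tede_mrem=2000.0))
        assert pct == pytest.approx(5.0)


class TestDistanceTable:
    def test_contact_row_matches_course_projection(self, course_500):
        tbl = distance_table(TABLE_RATES, course_500)
        row = tbl[tbl.distance_cm == 5].iloc[0]
        # printed row 0.3539 reflects an unrounded rate; agree within 1%
        assert row.course_dose_mrem == pytest.approx(0.3539, rel=0.01)

    def test_far_row_reflects_rounded_printed_rate(self, course_500):
        tbl = distance_table(TABLE_RATES, course_500)
        row = tbl[tbl.distance_cm == 40].iloc[0]
        assert row.course_dose_mrem == pytest.approx(0.0625, abs=0.0001)

    def test_single_fraction_is_one_twenty_fifth_of_course(self, course_500):
        sc1 = ExposureScenario(mu_per_fraction=500.0, n_fractions=1, handling_time_min=1.0)
        full = distance_table(TABLE_RATES, course_500).course_dose_mrem.to_numpy()
        single = distance_table(TABLE_RATES, sc1).course_dose_mrem.to_numpy()
        assert single == pytest.approx(full / 25.0)

    def test_duplicate_distances_rejected(self, course_500):
        with pytest.raises(DosimetryError, match="duplicate"):
            distance_table([(5, 0.0017), (5, 0.0011)], course_500)

    def test_all_rows_linear_in_handling_time(self):
        sc_a = ExposureScenario(mu_per_fraction=500.0, n_fractions=25, handling_time_min=1.0)
        sc_b = ExposureScenario(mu_per_fraction=500.0, n_fractions=25, handling_time_min=2.0)
        a = distance_table(TABLE_RATES, sc_a).course_dose_mrem.to_numpy()
        b = distance_table(TABLE_RATES, sc_b).course_dose_mrem.to_numpy()
        assert b == pytest.approx(2 * a)


def test_report_summary_mentions_limits(skin_cal, course_500):
    rep = course_dose_from_integrated(skin_cal, course_500, first_interval_fraction=0.0539)
    text = rep.summary()
    assert "extremity" in text and "mrem" in text
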