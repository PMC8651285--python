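"""Digital immunoassay model: occupancy correction, simulation, calibration."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from evcompare import (
    BeadAssayParams,
    CalibrationStandard,
    WellArrayReading,
    aeb_from_fraction_on,
    average_technical_replicates,
    concentration_from_reading,
    fit_calibration,
    simulate_digital_readout,
)
from evcompare.assay import CalibrationCurve, ConcentrationEstimate
from evcompare.errors import (
    ConfigurationError,
    DomainError,
    FitError,
    SaturatedArrayError,
)


class TestPoissonOccupancy:
    @pytest.mark.parametrize(
        "f_on,expected",
        [
            (0.0, 0.0),
            (1 - math.exp(-1), 1.0),
            (0.1, -math.log(0.9)),
        ],
    )
    def test_closed_form_values(self, f_on, expected):
        assert aeb_from_fraction_on(f_on) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("bad", [-0.1, 1.0, 1.5])
    def test_domain_errors(self, bad):
        with pytest.raises(DomainError):
            aeb_from_fraction_on(bad)

    @given(st.floats(min_value=1e-4, max_value=5.0))
    def test_inverts_poisson_occupancy(self, lam):
        f = -math.expm1(-lam)
        assert aeb_from_fraction_on(f) == pytest.approx(lam, rel=1e-12)

    def test_monte_carlo_partition_oracle(self, rng):
        # independent oracle: drop Poisson(lam)-many labels per well and
        # count occupied wells; the occupancy fraction must invert to lam
        lam = 0.105361
        n_wells = 10**6
        occupied = (rng.poisson(lam, size=n_wells) > 0).mean()
        assert aeb_from_fraction_on(occupied) == pytest.approx(lam, rel=0.02)


class TestSimulateReadout:
    PARAMS = BeadAssayParams(
        n_beads=500_000,
        n_wells_loaded=100_000,
        capture_efficiency=1.0,
        background_aeb=0.0,
        dilution_factor=1.0,
    )

    def test_zero_concentration_zero_background_is_dark(self):
        reading = simulate_digital_readout(0.0, self.PARAMS, seed=1)
        assert reading.n_on == 0
        assert reading.aeb == 0.0

    def test_mean_fraction_on_matches_binomial(self):
        # lambda_eff = 0.5 -> p_on = 1 - exp(-0.5)
        reading = simulate_digital_readout(0.5, self.PARAMS, seed=42)
        p = 1 - math.exp(-0.5)
        sd = math.sqrt(p * (1 - p) / self.PARAMS.n_wells_loaded)
        assert abs(reading.fraction_on - p) < 5 * sd

    def test_deterministic_given_seed(self):
        a = simulate_digital_readout(3.0, self.PARAMS, seed=7)
        b = simulate_digital_readout(3.0, self.PARAMS, seed=7)
        assert (a.n_on, a.n_total) == (b.n_on, b.n_total)

    def test_mean_fraction_on_monotone_in_concentration(self):
        concs = [0.0, 0.05, 0.2, 0.5, 1.0, 2.0]
        fractions = [
            np.mean(
                [
                    simulate_digital_readout(c, self.PARAMS, seed=100 * i + j).fraction_on
                    for j in range(5)
                ]
            )
            for i, c in enumerate(concs)
        ]
        assert all(a <= b + 1e-12 for a, b in zip(fractions, fractions[1:]))

    def test_negative_concentration_rejected(self):
        with pytest.raises(DomainError):
            simulate_digital_readout(-1.0, self.PARAMS, seed=0)


class TestWellArrayReading:
    def test_fraction_on_is_exact_ratio(self):
        r = WellArrayReading(n_on=250, n_total=1000)
        assert r.fraction_on == 0.25

    def test_aeb_zero_iff_dark(self):
        assert WellArrayReading(0, 1000).aeb == 0.0
        assert WellArrayReading(1, 1000).aeb > 0.0

    def test_fully_on_array_raises_on_aeb(self):
        with pytest.raises(SaturatedArrayError):
            WellArrayReading(1000, 1000).aeb

    def test_saturation_flag_threshold(self):
        assert WellArrayReading(70_000, 100_000).saturated
        assert not WellArrayReading(69_999, 100_000).saturated


def _exact_standards(marker, lower, upper, midpoint, slope, concs):
    def resp(c):
        if c == 0:
            return lower
        frac = c**slope / (midpoint**slope + c**slope)
        return lower + (upper - lower) * frac

    return [CalibrationStandard(marker, c, (resp(c),)) for c in concs]


class TestCalibration:
    TRUE = dict(lower=0.01, upper=5.0, midpoint=1.3, slope=1.4)
    CONCS = [0.0, 0.01, 0.05, 0.2, 1.0, 5.0, 25.0, 200.0]

    def test_exact_parameter_recovery(self):
        stds = _exact_standards("CD9", concs=self.CONCS, **self.TRUE)
        curve = fit_calibration(stds)
        for name, truth in self.TRUE.items():
            assert getattr(curve, name) == pytest.approx(truth, rel=1e-6)
        assert curve.fit_residual < 1e-9

    def test_too_few_concentrations_rejected(self):
        stds = _exact_standards("CD9", concs=[0.0, 1.0, 10.0], **self.TRUE)
        with pytest.raises(ConfigurationError):
            fit_calibration(stds)

    def test_blank_required(self):
        stds = _exact_standards("CD9", concs=[0.1, 1.0, 10.0, 100.0], **self.TRUE)
        with pytest.raises(ConfigurationError):
            fit_calibration(stds)

    def test_all_blank_standards_degenerate(self):
        stds = [
            CalibrationStandard("CD9", c, (0.02,)) for c in [0.0, 0.1, 1.0, 10.0]
        ]
        with pytest.raises(FitError):
            fit_calibration(stds)

    def test_mixed_markers_rejected(self):
        stds = _exact_standards("CD9", concs=self.CONCS, **self.TRUE)
        stds[0] = CalibrationStandard("CD63", 0.0, (0.01,))
        with pytest.raises(ConfigurationError):
            fit_calibration(stds)

    def test_simulated_backcalculation_within_5pct_midrange(self):
        params = BeadAssayParams(
            n_beads=500_000,
            n_wells_loaded=100_000,
            capture_efficiency=0.5,
            background_aeb=0.003,
            dilution_factor=1.0,
        )
        rng = np.random.default_rng(11)
        cal_concs = [0.0, 0.003, 0.01, 0.03, 0.1, 0.3, 1.0, 3.0]  # 3 logs
        stds = [
            CalibrationStandard(
                "CD9",
                c,
                tuple(simulate_digital_readout(c, params, rng).aeb for _ in range(2)),
            )
            for c in cal_concs
        ]
        curve = fit_calibration(stds)
        for c in [0.1, 0.3, 0.6]:
            reading = simulate_digital_readout(c, params, rng)
            est = concentration_from_reading(reading, curve, 1.0)
            assert est.value_pM == pytest.approx(c, rel=0.05)


class TestConcentrationFromReading:
    CURVE = CalibrationCurve(
        marker="CD9",
        lower=0.01,
        upper=5.0,
        midpoint=1.3,
        slope=1.4,
        valid_range=(0.01, 200.0),
        fit_residual=0.0,
    )

    def test_dilution_correction(self):
        # AEB equal to the response at 10 pM with 4x dilution reads 40 pM;
        # that point sits high on this curve (f_on ~ 0.99), so the counting
        # regime warning may accompany the still-valid inversion
        aeb_at_10 = self.CURVE.response(10.0)
        n_total = 10**9  # synthetic huge array to hit an exact AEB
        n_on = round(n_total * (1 - math.exp(-aeb_at_10)))
        est = concentration_from_reading(
            WellArrayReading(n_on, n_total), self.CURVE, dilution_factor=4.0
        )
        assert est.value_pM == pytest.approx(40.0, rel=1e-6)
        assert est.flags <= {"saturated"}

    def test_midcurve_inversion_is_unflagged(self):
        aeb_mid = self.CURVE.response(0.5)
        n_total = 10**9
        n_on = round(n_total * (1 - math.exp(-aeb_mid)))
        est = concentration_from_reading(
            WellArrayReading(n_on, n_total), self.CURVE, dilution_factor=4.0
        )
        assert est.value_pM == pytest.approx(2.0, rel=1e-6)
        assert not est.flags

    def test_blank_level_flag_clamps_to_zero(self):
        est = concentration_from_reading(
            WellArrayReading(0, 100_000), self.CURVE, dilution_factor=4.0
        )
        assert est.value_pM == 0.0
        assert "blank_level" in est.flags

    def test_saturated_reading_clamped_to_curve_top(self):
        est = concentration_from_reading(
            WellArrayReading(99_999, 100_000), self.CURVE, dilution_factor=1.0
        )
        assert "above_curve" in est.flags
        assert est.value_pM == pytest.approx(200.0)

    def test_roundtrip_at_50pm_with_dilution(self):
        params = BeadAssayParams(
            n_beads=500_000,
            n_wells_loaded=100_000,
            capture_efficiency=0.02,
            background_aeb=0.003,
            dilution_factor=4.0,
        )
        rng = np.random.default_rng(5)
        cal_params = BeadAssayParams(
            n_beads=params.n_beads,
            n_wells_loaded=params.n_wells_loaded,
            capture_efficiency=params.capture_efficiency,
            background_aeb=params.background_aeb,
            dilution_factor=1.0,
        )
        stds = [
            CalibrationStandard(
                "CD9",
                c,
                tuple(simulate_digital_readout(c, cal_params, rng).aeb for _ in range(2)),
            )
            for c in [0.0, 0.5, 2.0, 8.0, 30.0, 120.0]
        ]
        curve = fit_calibration(stds)
        reading = simulate_digital_readout(50.0, params, rng)
        est = concentration_from_reading(reading, curve, params.dilution_factor)
        assert est.value_pM == pytest.approx(50.0, rel=0.05)


class TestTechnicalReplicates:
    def _est(self, v, marker="CD9"):
        return ConcentrationEstimate(marker=marker, value_pM=v)

    def test_identical_replicates(self):
        out = average_technical_replicates([self._est(10.0), self._est(10.0)])
        assert out.value_pM == 10.0
        assert out.cv == 0.0
        assert out.n_replicates == 2

    def test_hand_computed_cv(self):
        # sd([8, 12], ddof=1) = 2*sqrt(2) -> cv = 0.28284...
        out = average_technical_replicates([self._est(8.0), self._est(12.0)])
        assert out.value_pM == pytest.approx(10.0)
        assert out.cv == pytest.approx(0.28284271, rel=1e-6)

    def test_single_replicate_passthrough(self):
        out = average_technical_replicates([self._est(3.2)])
        assert out.value_pM == 3.2
        assert out.cv == 0.0

    def test_mixed_markers_rejected(self):
        with pytest.raises(ConfigurationError):
            average_technical_replicates([self._est(1.0), self._est(1.0, "ALB")])

    def test_flags_are_unioned(self):
        a = ConcentrationEstimate("CD9", 0.0, flags=frozenset({"blank_level"}))
        b = ConcentrationEstimate("CD9", 1.0)
        assert average_technical_replicates([a, b]).flags == frozenset({"blank_level"})
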