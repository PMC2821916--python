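import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rab5feedback import (
    AbundanceMeasurement,
    CalibrationError,
    CellConstants,
    DomainError,
    ExtrapolationError,
    estimate_affinity_ratio,
    estimate_beta,
    fg_per_cell_to_molar,
    fit_standard_curve,
    intensity_to_fg_per_cell,
    molar_to_fg_per_cell,
    round_sig,
)
from rab5feedback.quantify import DEFAULT_STANDARD_AMOUNTS_NG


class TestStandardCurve:
    def test_exact_line_recovered(self):
        amounts = np.array(DEFAULT_STANDARD_AMOUNTS_NG)
        curve = fit_standard_curve(amounts, 2.0 * amounts)
        assert curve.slope == pytest.approx(2.0)
        assert curve.intercept == pytest.approx(0.0, abs=1e-9)
        assert curve.r_squared == pytest.approx(1.0)
        assert curve.amount_at(0.0) == pytest.approx(0.0, abs=1e-9)

    def test_noisy_line_slope_within_five_percent(self):
        rng = np.random.default_rng(0)
        amounts = np.array(DEFAULT_STANDARD_AMOUNTS_NG)
        intensities = 3.5 * amounts * rng.lognormal(0, 0.05, amounts.size)
        curve = fit_standard_curve(amounts, intensities)
        assert curve.slope == pytest.approx(3.5, rel=0.05)

    def test_rejects_degenerate_calibrations(self):
        with pytest.raises(CalibrationError):
            fit_standard_curve([10, 20], [1, 2])
        with pytest.raises(CalibrationError):
            fit_standard_curve([10, 10, 20], [1, 1, 2])
        with pytest.raises(CalibrationError):
            fit_standard_curve([10, 20, 30], [3, 2, 1])  # negative slope

    def test_refuses_extrapolation_by_default(self):
        amounts = np.array([10.0, 100.0, 1000.0])
        curve = fit_standard_curve(amounts, amounts)
        with pytest.raises(ExtrapolationError):
            curve.amount_at(5000.0)
        assert curve.amount_at(5000.0, allow_extrapolation=True) == pytest.approx(5000.0)


class TestPerCellAbundance:
    @pytest.mark.parametrize(
        "efficiency, expected_fg",
        [(1.0, 100.0), (0.2, 500.0), (0.8, 125.0)],
    )
    def test_transfection_efficiency_correction(self, efficiency, expected_fg):
        """100 ng over 1e6 cells: untransfected cells dilute the per-cell mass."""
        amounts = np.array([10.0, 100.0, 1000.0])
        curve = fit_standard_curve(amounts, amounts)  # identity calibration
        meas = AbundanceMeasurement(
            band_intensity=100.0, lysate_cell_count=1e6, transfection_efficiency=efficiency
        )
        assert intensity_to_fg_per_cell(curve, meas) == pytest.approx(expected_fg)

    def test_measurement_validation(self):
        with pytest.raises(DomainError):
            AbundanceMeasurement(band_intensity=1, lysate_cell_count=1e6, transfection_efficiency=0.0)
        with pytest.raises(DomainError):
            AbundanceMeasurement(band_intensity=1, lysate_cell_count=0, transfection_efficiency=0.5)


class TestUnitConversion:
    @pytest.mark.parametrize(
        "fg, mw, vol, expected",
        [
            (32.0, 40.0, 80.0, 1.0e-5),  # feedback-construct onset level, BHK plateau
            (12.0, 40.0, 80.0, 3.75e-6),  # NF73 onset level
            (12.0, 24.0, 80.0, 6.25e-6),  # endogenous Rab5, ~6e-6 M at 1 s.f.
            (0.0, 40.0, 80.0, 0.0),
        ],
    )
    def test_fg_per_cell_to_molar(self, fg, mw, vol, expected):
        assert fg_per_cell_to_molar(fg, mw, vol) == pytest.approx(expected, rel=1e-12)

    def test_invalid_inputs(self):
        with pytest.raises(DomainError):
            fg_per_cell_to_molar(1.0, 0.0, 80.0)
        with pytest.raises(DomainError):
            fg_per_cell_to_molar(-1.0, 40.0, 80.0)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        fg=st.floats(1e-3, 1e3),
        mw=st.floats(1.0, 500.0),
        vol=st.floats(1.0, 1e4),
        k=st.floats(0.1, 10.0),
    )
    def test_round_trip_and_scaling(self, fg, mw, vol, k):
        m = fg_per_cell_to_molar(fg, mw, vol)
        assert molar_to_fg_per_cell(m, mw, vol) == pytest.approx(fg, rel=1e-12)
        assert fg_per_cell_to_molar(k * fg, mw, vol) == pytest.approx(k * m, rel=1e-12)
        assert fg_per_cell_to_molar(fg, k * mw, vol) == pytest.approx(m / k, rel=1e-12)
        assert fg_per_cell_to_molar(fg, mw, k * vol) == pytest.approx(m / k, rel=1e-12)


class TestRateAndAffinityEstimates:
    def test_gap_enhanced_hydrolysis_rate(self):
        assert estimate_beta(2e-3, 100) == pytest.approx(0.2)
        assert estimate_beta(0.37, 1) == pytest.approx(0.37)
        # a stronger GAP raises beta/alpha and scales lam/gamma down in step
        strong = estimate_beta(2e-3, 1e5)
        assert strong == pytest.approx(200.0)
        alpha = 2e4
        conservative_ratio = estimate_affinity_ratio(3.75e-6, 2.5e-5, estimate_beta(2e-3, 100) / alpha)
        strong_ratio = estimate_affinity_ratio(3.75e-6, 2.5e-5, strong / alpha)
        assert conservative_ratio / strong_ratio == pytest.approx(1e3, rel=1e-9)

    def test_affinity_ratio_worked_examples(self):
        nf73 = estimate_affinity_ratio(3.75e-6, 2.5e-5, 1e-5)
        assert nf73 == pytest.approx(9.375e-6, rel=1e-12)
        assert round_sig(nf73, 1) == pytest.approx(9e-6)
        assert abs(nf73 - 1e-5) <= 0.5e-5  # the value prints as ~1e-5 M
        bhk_bound = estimate_affinity_ratio(1e-5, 6e-6, 1e-5)
        assert bhk_bound == pytest.approx(6e-6, rel=1e-12)
        with pytest.raises(DomainError):
            estimate_affinity_ratio(0.0, 1e-5, 1e-5)

    def test_full_chain_reproduces_in_cell_affinity(self):
        """Standard curve -> fg/cell -> molar -> lam/gamma lands on ~1e-5 M."""
        amounts = np.array(DEFAULT_STANDARD_AMOUNTS_NG)
        curve = fit_standard_curve(amounts, 1.7 * amounts + 5.0)
        intensity = curve.intensity_at(120.0)  # a 120 ng band
        meas = AbundanceMeasurement(
            band_intensity=intensity, lysate_cell_count=2e6, transfection_efficiency=0.2
        )
        fg = intensity_to_fg_per_cell(curve, meas)  # 120e6 fg over 4e5 transfected cells
        assert fg == pytest.approx(300.0, rel=1e-9)
        # scale to the 12 fg/cell onset reading and convert
        x_m = fg_per_cell_to_molar(12.0, 40.0, CellConstants().cell_volume_fl)
        ratio = estimate_affinity_ratio(x_m, 2.5e-5, 1e-5)
        assert round_sig(ratio, 1) == pytest.approx(9e-6)
        assert 0.5e-5 <= ratio <= 1.5e-5

    def test_cell_constants_defaults_and_validation(self):
        const = CellConstants()
        assert const.cell_volume_fl == 80.0
        assert const.molecular_masses_kda["rabex5_135_480"] == 40.0
        with pytest.raises(DomainError):
            CellConstants(cell_volume_fl=-1.0)
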