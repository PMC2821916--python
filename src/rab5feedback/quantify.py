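"""Densitometry calibration and per-cell abundance arithmetic.

Immunoblot band intensities are calibrated against a dilution series of
purified protein (a linear standard curve), corrected for the number of
cells in the lysate and the transfection efficiency, and expressed as
femtograms of protein per cell. Abundances convert to molar concentration
through the protein's molecular mass and a mean cell volume (~80 fL), and
the onset threshold of the feedback loop then yields the in-cell
dissociation constant lam/gamma of the Rabex-5/Rabaptin-5/Rab5-GTP complex
via ``lam/gamma = x_threshold * z_tot / (beta/alpha)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .model import DomainError

__all__ = [
    "CalibrationError",
    "ExtrapolationError",
    "StandardCurve",
    "AbundanceMeasurement",
    "CellConstants",
    "fit_standard_curve",
    "intensity_to_fg_per_cell",
    "fg_per_cell_to_molar",
    "molar_to_fg_per_cell",
    "estimate_beta",
    "estimate_affinity_ratio",
    "round_sig",
]


class CalibrationError(ValueError):
    """The standard-curve data cannot support a usable calibration."""


class ExtrapolationError(ValueError):
    """An intensity falls outside the calibrated range."""


#: the dilution series used for blot calibration (ng)
DEFAULT_STANDARD_AMOUNTS_NG = (1000.0, 500.0, 250.0, 200.0, 150.0, 100.0, 50.0, 25.0, 10.0)


@dataclass(frozen=True)
class StandardCurve:
    """Linear calibration of background-corrected band intensity vs amount."""

    amounts_ng: np.ndarray
    intensities: np.ndarray
    slope: float  # intensity per ng
    intercept: float
    r_squared: float

    def intensity_at(self, amount_ng: float) -> float:
        return self.slope * amount_ng + self.intercept

    def amount_at(self, intensity: float, *, allow_extrapolation: bool = False) -> float:
        """Inverse-predict the protein amount (ng) for an intensity."""
        lo = self.intensity_at(self.amounts_ng.min())
        hi = self.intensity_at(self.amounts_ng.max())
        if not allow_extrapolation and not (min(lo, 0.0) <= intensity <= hi):
            raise ExtrapolationError(
                f"intensity {intensity!r} outside calibrated range [{lo:.4g}, {hi:.4g}]"
            )
        return (intensity - self.intercept) / self.slope


def fit_standard_curve(amounts_ng, intensities) -> StandardCurve:
    """Least-squares linear fit of intensity against known protein amount."""
    a = np.asarray(amounts_ng, dtype=float)
    i = np.asarray(intensities, dtype=float)
    if a.size < 3 or a.size != i.size:
        raise CalibrationError("need at least 3 paired (amount, intensity) points")
    if np.any(a <= 0) or len(np.unique(a)) != a.size:
        raise CalibrationError("amounts must be strictly positive and distinct")
    fit = stats.linregress(a, i)
    if fit.slope <= 0:
        raise CalibrationError(f"non-positive slope {fit.slope!r}: unusable calibration")
    return StandardCurve(
        amounts_ng=a,
        intensities=i,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
    )


@dataclass(frozen=True)
class AbundanceMeasurement:
    """One blot band from a lysate of counted, partially transfected cells."""

    band_intensity: float
    lysate_cell_count: float
    transfection_efficiency: float
    protein_id: str = ""

    def __post_init__(self) -> None:
        if not 0 < self.transfection_efficiency <= 1:
            raise DomainError(
                f"transfection_efficiency {self.transfection_efficiency!r} not in (0, 1]"
            )
        if self.lysate_cell_count <= 0:
            raise DomainError("lysate_cell_count must be positive")


@dataclass(frozen=True)
class CellConstants:
    """Cell volume and molecular masses used for unit conversion.

    The Rabex-5(135-480) mass (40 kDa) and the 80 fL mean cell volume are
    measured values; Rab5 (~24 kDa, canonical sequence) and GFP-Rab5
    (~51 kDa) are sequence-based defaults and can be overridden.
    """

    cell_volume_fl: float = 80.0
    molecular_masses_kda: dict = field(
        default_factory=lambda: {
            "rabex5_135_480": 40.0,
            "rab5": 24.0,
            "gfp_rab5": 51.0,
        }
    )

    def __post_init__(self) -> None:
        if self.cell_volume_fl <= 0:
            raise DomainError("cell volume must be positive")
        for k, v in self.molecular_masses_kda.items():
            if v <= 0:
                raise DomainError(f"molecular mass for {k!r} must be positive")


def intensity_to_fg_per_cell(curve: StandardCurve, meas: AbundanceMeasurement, *, allow_extrapolation: bool = False) -> float:
    """Per-cell protein abundance (fg/cell) from a calibrated band intensity.

    Inverse-predicts nanograms from the standard curve, then corrects by
    the number of cells in the lysate and the transfection efficiency
    (only the transfected fraction contributes protein).
    """
    ng = curve.amount_at(meas.band_intensity, allow_extrapolation=allow_extrapolation)
    return ng * 1e6 / (meas.lysate_cell_count * meas.transfection_efficiency)


def fg_per_cell_to_molar(mass_fg_per_cell: float, mw_kda: float, volume_fl: float) -> float:
    """Convert fg/cell to molar: (m*1e-15 g)/(mw*1e3 g/mol)/(V*1e-15 L)."""
    if mw_kda <= 0 or volume_fl <= 0:
        raise DomainError("molecular mass and cell volume must be positive")
    if mass_fg_per_cell < 0:
        raise DomainError("mass per cell must be non-negative")
    return mass_fg_per_cell / (mw_kda * 1e3 * volume_fl)


def molar_to_fg_per_cell(concentration_m: float, mw_kda: float, volume_fl: float) -> float:
    """Inverse of :func:`fg_per_cell_to_molar`."""
    if mw_kda <= 0 or volume_fl <= 0:
        raise DomainError("molecular mass and cell volume must be positive")
    return concentration_m * mw_kda * 1e3 * volume_fl


def estimate_beta(intrinsic_rate_per_s: float, gap_enhancement_fold: float) -> float:
    """Effective hydrolysis rate: intrinsic GTPase rate times GAP speed-up.

    With the measured intrinsic rate 2e-3 /s and a conservative 100-fold
    GAP enhancement this gives beta = 0.2 /s; a stronger GAP scales beta
    up and the inferred lam/gamma down proportionally.
    """
    if intrinsic_rate_per_s <= 0 or gap_enhancement_fold <= 0:
        raise DomainError("intrinsic rate and enhancement must be positive")
    return intrinsic_rate_per_s * gap_enhancement_fold


def estimate_affinity_ratio(x_threshold_m: float, z_tot_m: float, beta_over_alpha_m: float) -> float:
    """In-cell dissociation constant lam/gamma (M) of the tripartite complex.

    Inverts the onset condition ``x_threshold = (lam/gamma)*(beta/alpha)/z_tot``.
    When ``x_threshold_m`` is a level at which no onset was observed, the
    result is a lower bound on lam/gamma rather than a point estimate.
    """
    if x_threshold_m <= 0 or z_tot_m <= 0 or beta_over_alpha_m <= 0:
        raise DomainError("all inputs to the affinity ratio must be positive")
    return x_threshold_m * z_tot_m / beta_over_alpha_m


def round_sig(x: float, digits: int = 1) -> float:
    """Round to the given number of significant figures (0 stays 0)."""
    if x == 0:
        return 0.0
    return round(x, -int(math.floor(math.log10(abs(x)))) + digits - 1)
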