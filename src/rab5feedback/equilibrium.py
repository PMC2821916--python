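"""Steady-state response curves, onset threshold, and Hill analysis.

The steady state of the activation kinetics, titrated against total
Rabex-5 ``x_tot``, takes three closed forms:

* direct pathway only (``gamma = 0``): a hyperbola
  ``z = alpha*x1*z_tot / (alpha*x1 + beta)`` with
  ``x1 = sigma*x_tot/(1+sigma)`` — Michaelis-Menten-like, Hill
  coefficient 1, half-maximal at ``x_tot = beta*(1+sigma)/(alpha*sigma)``;
* indirect (feedback) pathway only (``sigma = 0``): a delayed-onset curve
  ``z = (gamma*alpha*x_tot*z_tot - lam*beta) / (gamma*(alpha*x_tot + beta))``
  clamped to the stable ``z = 0`` branch below the onset threshold
  ``x_tot = lam*beta/(gamma*alpha*z_tot)``;
* both pathways: the stable non-negative root of a quadratic in ``z``
  (see :func:`steady_state_general`).

Sensitivity is quantified with the generalized Hill coefficient computed
by the 10-90% rule, ``n_H = ln(81)/ln(x90/x10)``: 1 for the direct
hyperbola, between 1 and 2 for the feedback curve, approaching 2 when the
complex dissociation constant ``lam/gamma`` greatly exceeds total Rab5.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import json

import numpy as np
import pandas as pd

from .model import DomainError, KineticParameters

__all__ = [
    "BracketError",
    "ResponseCurve",
    "steady_state_direct_only",
    "midpoint_direct",
    "steady_state_indirect_only",
    "onset_threshold",
    "steady_state_general",
    "response_curve",
    "hill_coefficient",
    "normalized_slope_sensitivity",
]

Mode = Literal["direct_only", "indirect_only", "combined"]
_MODES = ("direct_only", "indirect_only", "combined")


class BracketError(ValueError):
    """The response curve does not bracket a requested activation level."""


def steady_state_direct_only(params: KineticParameters) -> float:
    """Steady-state Rab5-GTP (M) with the feedback pathway disabled.

    Hyperbolic in ``x_tot``; returns 0 when ``sigma = 0`` (no membrane
    enzyme at all), ``z_tot`` in the saturating limit.
    """
    x1 = params.sigma * params.x_tot / (1.0 + params.sigma)
    drive = params.alpha * x1
    if drive == 0.0:
        return 0.0
    if params.beta == 0.0:
        return params.z_tot
    return drive * params.z_tot / (drive + params.beta)


def midpoint_direct(params: KineticParameters) -> float:
    """Total Rabex-5 (M) at which the direct-only response is half-maximal.

    Equals ``beta*(1+sigma)/(alpha*sigma)``; undefined for ``sigma = 0``.
    """
    if params.sigma <= 0:
        raise DomainError("direct-pathway midpoint undefined for sigma = 0")
    if params.alpha <= 0:
        raise DomainError("direct-pathway midpoint undefined for alpha = 0")
    return params.beta * (1.0 + params.sigma) / (params.alpha * params.sigma)


def onset_threshold(params: KineticParameters) -> float:
    """Total Rabex-5 (M) at the onset of feedback activation.

    ``lam*beta/(gamma*alpha*z_tot)`` — inversely proportional to total
    Rab5, the model's central experimental prediction.
    """
    denom = params.gamma * params.alpha * params.z_tot
    if denom == 0.0:
        raise DomainError(
            "onset threshold requires gamma, alpha and z_tot all positive"
        )
    return params.lam * params.beta / denom


def steady_state_indirect_only(params: KineticParameters) -> float:
    """Steady-state Rab5-GTP (M) via the feedback pathway alone (sigma=0).

    The non-trivial root is negative (unphysical) below the onset
    threshold; there the stable branch is ``z = 0`` and the clamped value
    is returned.
    """
    p = params
    if p.gamma == 0.0:
        return 0.0
    z = (p.gamma * p.alpha * p.x_tot * p.z_tot - p.lam * p.beta) / (
        p.gamma * (p.alpha * p.x_tot + p.beta)
    )
    return max(0.0, z)


def _general_quadratic(params: KineticParameters) -> tuple[float, float, float]:
    """Coefficients (a2, a1, a0) of the steady-state quadratic in z.

    Obtained by eliminating ``x2`` at steady state
    (``x2 = gamma*x_tot*z / (lam*(1+sigma) + gamma*z)``) and clearing
    denominators in ``dz/dt = 0``.
    """
    p = params
    x = p.x_tot
    a2 = p.gamma * (p.alpha * x + p.beta)
    a1 = (
        p.beta * p.lam * (1.0 + p.sigma)
        + p.alpha * x * p.sigma * p.lam
        - p.alpha * x * p.gamma * p.z_tot
    )
    a0 = -p.alpha * x * p.sigma * p.lam * p.z_tot
    return a2, a1, a0


def steady_state_general(params: KineticParameters) -> float:
    """Stable non-negative steady-state Rab5-GTP (M) with both pathways.

    Reduces to :func:`steady_state_direct_only` when ``gamma = 0`` and to
    :func:`steady_state_indirect_only` when ``sigma = 0``. The stable
    branch is the larger root of the steady-state quadratic, clamped to
    ``[0, z_tot]``.
    """
    p = params
    if p.x_tot == 0.0:
        return 0.0
    if p.gamma == 0.0:
        return steady_state_direct_only(p)
    if p.lam == 0.0:
        raise DomainError("steady state undefined for lam = 0 with gamma > 0")
    a2, a1, a0 = _general_quadratic(p)
    disc = a1 * a1 - 4.0 * a2 * a0
    if disc < 0:
        raise RuntimeError(
            "internal inconsistency: steady-state quadratic has no real root"
        )
    # larger root, evaluated in a cancellation-safe form
    sq = np.sqrt(disc)
    if a1 <= 0:
        z = (-a1 + sq) / (2.0 * a2)
    else:
        z = (2.0 * a0) / (-a1 - sq) if (a0 != 0 or sq != a1) else 0.0
    return float(min(max(z, 0.0), p.z_tot))


def _steady_values(params: KineticParameters, x_grid: np.ndarray, mode: Mode):
    fns = {
        "direct_only": steady_state_direct_only,
        "indirect_only": steady_state_indirect_only,
        "combined": steady_state_general,
    }
    fn = fns[mode]
    return np.array([fn(params.replace(x_tot=float(x))) for x in x_grid])


@dataclass(frozen=True)
class ResponseCurve:
    """Steady-state Rab5-GTP versus total Rabex-5 for one pathway mode."""

    mode: Mode
    x_grid: np.ndarray
    z_values: np.ndarray
    params: KineticParameters

    def to_csv(self, path: str | Path, sidecar: str | Path | None = None) -> None:
        pd.DataFrame({"x_tot_M": self.x_grid, "z_M": self.z_values}).to_csv(
            path, index=False
        )
        if sidecar is not None:
            meta: dict = {"mode": self.mode, "params": self.params.to_dict()}
            if self.params.sigma > 0 and self.params.alpha > 0:
                meta["midpoint_direct_M"] = midpoint_direct(self.params)
            try:
                meta["onset_threshold_M"] = onset_threshold(self.params)
            except DomainError:
                meta["onset_threshold_M"] = None
            try:
                meta["hill_coefficient"] = hill_coefficient(self)
            except BracketError:
                meta["hill_coefficient"] = None
            Path(sidecar).write_text(json.dumps(meta, indent=2) + "\n")


def response_curve(
    params: KineticParameters, x_grid, mode: Mode = "combined"
) -> ResponseCurve:
    """Evaluate the steady-state response over a grid of total Rabex-5."""
    if mode not in _MODES:
        raise ValueError(f"unknown mode {mode!r}; expected one of {_MODES}")
    x = np.asarray(x_grid, dtype=float)
    if x.size and (np.any(np.diff(x) <= 0) or x[0] < 0):
        raise DomainError("x_grid must be non-negative and strictly increasing")
    return ResponseCurve(mode=mode, x_grid=x, z_values=_steady_values(params, x, mode), params=params)


def _crossing(curve: ResponseCurve, level: float) -> float:
    """x_tot at which the curve crosses ``level``, by monotone interpolation.

    Linear in log10(x) (the curves span decades); falls back to linear in x
    when the bracketing segment touches x = 0.
    """
    x, z = curve.x_grid, curve.z_values
    above = np.nonzero(z >= level)[0]
    if above.size == 0 or above[0] == 0:
        raise BracketError(
            f"curve does not bracket level {level}; widen the x_tot grid"
        )
    i = above[0]
    x0, x1, z0, z1 = x[i - 1], x[i], z[i - 1], z[i]
    if z1 == z0:
        return float(x1)
    frac = (level - z0) / (z1 - z0)
    if x0 <= 0:
        return float(x0 + frac * (x1 - x0))
    return float(10 ** (np.log10(x0) + frac * (np.log10(x1) - np.log10(x0))))


def hill_coefficient(curve: ResponseCurve, lower: float = 0.1, upper: float = 0.9) -> float:
    """Generalized Hill coefficient by the 10-90% rule.

    ``n_H = ln(81) / ln(x90/x10)`` with ``x10``/``x90`` the total Rabex-5
    at 10% and 90% of maximal activation ``z_tot``. Requires the curve to
    span both levels (:class:`BracketError` otherwise).
    """
    z_tot = curve.params.z_tot
    x_lo = _crossing(curve, lower * z_tot)
    x_hi = _crossing(curve, upper * z_tot)
    ratio = (upper * (1 - lower)) / (lower * (1 - upper))  # 81 for 10-90%
    return float(np.log(ratio) / np.log(x_hi / x_lo))


def normalized_slope_sensitivity(curve: ResponseCurve) -> float:
    """Midpoint slope normalized by midpoint location (secondary diagnostic).

    ``(dz/dx_tot) * x50 / z_tot`` at the half-activation point: the change
    in fractional activation per fractional change in enzyme level. The
    10-90% rule (:func:`hill_coefficient`) is the primary sensitivity
    measure; this diagnostic exposes the underlying slope-at-midpoint
    notion directly.
    """
    z_tot = curve.params.z_tot
    x50 = _crossing(curve, 0.5 * z_tot)
    h = 1e-4 * x50
    p = curve.params
    fn = {
        "direct_only": steady_state_direct_only,
        "indirect_only": steady_state_indirect_only,
        "combined": steady_state_general,
    }[curve.mode]
    dzdx = (fn(p.replace(x_tot=x50 + h)) - fn(p.replace(x_tot=x50 - h))) / (2 * h)
    return float(dzdx * x50 / z_tot)
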