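"""Steady-state enumeration, linear stability, and bifurcation structure.

Without the direct pathway (``sigma = 0``) the system has two steady-state
branches: the origin ``z = 0`` and a rational branch that is positive only
above the onset threshold ``lam*beta/(gamma*alpha*z_tot)``. The branches
cross at the threshold and exchange stability there — a *transcritical*
bifurcation, not the saddle-node fold that underlies true bistability. With
``sigma > 0`` there is a single smooth stable branch for all enzyme levels.
At no parameter values do two stable physical states coexist.

Stability is classified from the eigenvalues of the analytic 2x2 Jacobian
of the kinetics at each root.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .equilibrium import (
    _general_quadratic,
    onset_threshold,
    steady_state_direct_only,
    steady_state_general,
)
from .model import DomainError, KineticParameters, jacobian, time_derivatives

__all__ = [
    "SteadyStateReport",
    "BifurcationDiagram",
    "find_steady_states",
    "classify_stability",
    "bifurcation_scan",
]

Stability = Literal["stable", "unstable", "marginal"]


def _complex_at(params: KineticParameters, z: float) -> float:
    """Steady-state tripartite complex x2 corresponding to a z-root."""
    p = params
    if p.gamma == 0.0:
        return 0.0
    return p.gamma * p.x_tot * z / (p.lam * (1.0 + p.sigma) + p.gamma * z)


def _z_roots(params: KineticParameters) -> list[float]:
    """All real roots in z of the steady-state system, physical or not."""
    p = params
    if p.gamma == 0.0 or p.x_tot == 0.0:
        roots = {0.0} if p.sigma == 0.0 or p.x_tot == 0.0 else set()
        roots.add(steady_state_direct_only(p))
        return sorted(roots)
    a2, a1, a0 = _general_quadratic(p)
    if a2 == 0.0:
        return [0.0] if a1 == 0.0 else [-a0 / a1]
    rts = np.roots([a2, a1, a0])
    rts = rts[np.abs(rts.imag) < 1e-12 * max(1.0, np.abs(rts).max())].real
    # collapse the numerically-zero root exactly onto the origin for sigma=0
    if p.sigma == 0.0:
        rts = np.where(np.abs(rts) < 1e-300, 0.0, rts)
    return sorted(float(r) for r in rts)


def classify_stability(
    params: KineticParameters,
    state: tuple[float, float],
    *,
    residual_tol: float = 1e-8,
    marginal_tol: float = 1e-9,
) -> Stability:
    """Classify a steady state by the Jacobian eigenvalue real parts.

    ``state`` must actually be a root: the residual of the kinetics is
    checked against ``residual_tol`` times a characteristic rate scale.
    Eigenvalues whose largest real part is within ``marginal_tol`` times
    the hydrolysis rate ``beta`` of zero are reported as ``"marginal"``
    (the transcritical exchange point).
    """
    p = params
    z, x2 = state
    rate = max(p.beta, p.alpha * p.z_tot, p.lam, 1e-300)
    flux_scale = rate * max(p.z_tot, p.x_tot, 1e-300)
    dz, dx2 = _derivatives_unchecked(p, z, x2)
    residual = max(abs(dz), abs(dx2))
    if residual > residual_tol * flux_scale:
        raise DomainError(
            f"state {state!r} is not a steady state (residual {residual:.3e})"
        )
    eig = np.linalg.eigvals(jacobian(p, (z, x2)))
    top = float(eig.real.max())
    char = p.beta if p.beta > 0 else rate
    if abs(top) < marginal_tol * char:
        return "marginal"
    return "stable" if top < 0 else "unstable"


def _derivatives_unchecked(params: KineticParameters, z: float, x2: float):
    """Kinetics RHS without domain checks (used for off-domain roots)."""
    p = params
    x0 = (p.x_tot - x2) / (1.0 + p.sigma)
    x1 = p.sigma * x0
    dz = p.alpha * (x1 + x2) * (p.z_tot - z) - p.beta * z
    dx2 = p.gamma * x0 * z - p.lam * x2
    return dz, dx2


@dataclass(frozen=True)
class SteadyStateReport:
    """All steady states of one parameter set, with stability and physicality."""

    states: list[tuple[float, float]]
    stability: list[Stability]
    physical: list[bool]
    params: KineticParameters

    @property
    def stable_physical(self) -> list[tuple[float, float]]:
        return [
            s
            for s, st, ph in zip(self.states, self.stability, self.physical)
            if ph and st == "stable"
        ]


def find_steady_states(params: KineticParameters) -> SteadyStateReport:
    """Enumerate all steady states, including non-physical (negative) roots.

    For ``sigma = 0`` the origin is always a root; the companion root of
    the quadratic is negative exactly when ``x_tot`` is below the onset
    threshold, in which case the origin is the stable state.
    """
    states, stab, phys = [], [], []
    for z in _z_roots(params):
        x2 = _complex_at(params, z)
        states.append((z, x2))
        stab.append(classify_stability(params, (z, x2)))
        phys.append(0.0 <= z <= params.z_tot and 0.0 <= x2 <= params.x_tot)
    return SteadyStateReport(states=states, stability=stab, physical=phys, params=params)


@dataclass(frozen=True)
class BifurcationDiagram:
    """Root branches with stability along an x_tot scan."""

    x_grid: np.ndarray
    branch_z: list[np.ndarray]  # one array per branch, aligned to x_grid
    branch_stability: list[list[Stability]]
    crossing: float | None  # transcritical point (M), sigma=0 only
    saddle_node_detected: bool
    params: KineticParameters

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for b, (zb, sb) in enumerate(zip(self.branch_z, self.branch_stability)):
            for x, z, s in zip(self.x_grid, zb, sb):
                rows.append((x, b, z, s))
        return pd.DataFrame(rows, columns=["x_tot_M", "branch_id", "z_M", "stability"])

    def to_csv(self, path: str | Path, sidecar: str | Path | None = None) -> None:
        self.to_frame().to_csv(path, index=False)
        if sidecar is not None:
            Path(sidecar).write_text(
                json.dumps(
                    {
                        "crossing_M": self.crossing,
                        "bistable": False,
                        "saddle_node_detected": self.saddle_node_detected,
                        "params": self.params.to_dict(),
                    },
                    indent=2,
                )
                + "\n"
            )


def bifurcation_scan(
    params: KineticParameters,
    x_range: tuple[float, float],
    n_points: int = 201,
) -> BifurcationDiagram:
    """Track steady-state branches and their stability across ``x_range``.

    Asserts exactly one stable physical root at every grid point. For
    ``sigma = 0`` the transcritical crossing is located by bisection on the
    non-origin branch to relative precision better than 1e-6; for
    ``sigma > 0`` there is no crossing. A saddle-node would appear as a
    fold (sign change of dz/dx_tot) along the stable branch; its absence
    over the scan is the "no bistability" assertion.
    """
    lo, hi = x_range
    if not (0 < lo < hi) or n_points < 10:
        raise DomainError("x_range must satisfy 0 < lo < hi with n_points >= 10")
    x_grid = np.geomspace(lo, hi, n_points)

    lower_z, upper_z = [], []
    lower_s, upper_s = [], []
    for x in x_grid:
        rep = find_steady_states(params.replace(x_tot=float(x)))
        n_stable = sum(
            1 for st, ph in zip(rep.stability, rep.physical) if ph and st == "stable"
        )
        n_marginal = sum(1 for st in rep.stability if st == "marginal")
        if n_stable > 1:
            raise RuntimeError(
                f"two stable physical states at x_tot={x}: bistability should "
                "be impossible in this model"
            )
        if n_stable == 0 and n_marginal == 0:
            raise RuntimeError(f"no stable physical state found at x_tot={x}")
        zs = sorted(zip((s[0] for s in rep.states), rep.stability))
        lower_z.append(zs[0][0])
        lower_s.append(zs[0][1])
        upper_z.append(zs[-1][0])
        upper_s.append(zs[-1][1])

    branches = [np.array(lower_z)]
    stabs = [lower_s]
    if any(u != l for u, l in zip(upper_z, lower_z)):
        branches.append(np.array(upper_z))
        stabs.append(upper_s)

    crossing: float | None = None
    if params.sigma == 0.0 and params.gamma > 0 and params.alpha > 0 and params.z_tot > 0:

        def nonorigin_root(x: float) -> float:
            roots = _z_roots(params.replace(x_tot=x))
            nz = [r for r in roots if r != 0.0]
            return nz[-1] if nz else 0.0

        f_lo, f_hi = nonorigin_root(lo), nonorigin_root(hi)
        if f_lo < 0 < f_hi:
            crossing = float(brentq(nonorigin_root, lo, hi, rtol=1e-12))

    # fold (saddle-node) detection along the stable branch
    stable_z = np.array(
        [steady_state_general(params.replace(x_tot=float(x))) for x in x_grid]
    )
    dz = np.diff(stable_z)
    tol = 1e-12 * max(params.z_tot, 1e-300)
    fold = bool(np.any(dz < -tol))

    return BifurcationDiagram(
        x_grid=x_grid,
        branch_z=branches,
        branch_stability=stabs,
        crossing=crossing,
        saddle_node_detected=fold,
        params=params,
    )
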