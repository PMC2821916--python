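"""Two-variable kinetic model of Rab5 activation by Rabex-5.

Rab5 cycles between a GDP-bound (inactive) and a GTP-bound (active) form on
the early endosomal membrane. Its exchange factor Rabex-5 reaches the
membrane through two routes:

* a **direct** route, an equilibrium between cytosolic and membrane-bound
  enzyme described by a dimensionless constant ``sigma``;
* an **indirect** route, in which the cytosolic Rabex-5/Rabaptin-5 complex
  is recruited by Rab5-GTP itself, forming a tripartite
  Rabex-5/Rabaptin-5/Rab5-GTP complex and closing a positive feedback loop.

With ``z`` the Rab5-GTP concentration and ``x2`` the tripartite-complex
concentration, the remaining enzyme pools follow from conservation,
``x0 = (x_tot - x2)/(1 + sigma)`` (cytosolic) and ``x1 = sigma * x0``
(directly membrane-bound), and the dynamics are

.. math::

    dz/dt   &= \\alpha (x_1 + x_2)(z_{tot} - z) - \\beta z \\\\
    dx_2/dt &= \\gamma x_0 z - \\lambda x_2

``alpha`` is the GEF catalytic rate constant per unit enzyme, ``beta`` the
effective GAP-driven hydrolysis rate (GAP concentration absorbed), and
``gamma``/``lam`` the formation/dissociation rate constants of the
tripartite complex (cytosolic Rabaptin-5 absorbed into ``gamma``).

Units are molar and seconds everywhere in this module; femtograms per cell
and hours appear only at the quantification and synthetic-data boundaries.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

__all__ = [
    "DomainError",
    "IntegrationError",
    "KineticParameters",
    "SystemState",
    "Trajectory",
    "partition_enzyme",
    "time_derivatives",
    "jacobian",
    "simulate",
]


class DomainError(ValueError):
    """An input lies outside the physically meaningful domain."""


class IntegrationError(RuntimeError):
    """The ODE solver failed or produced an invalid trajectory."""


_PARAM_KEYS = ("alpha", "beta", "gamma", "lam", "sigma", "z_tot", "x_tot")


@dataclass(frozen=True)
class KineticParameters:
    """Rate constants and totals of the Rab5 activation cycle.

    Parameters
    ----------
    alpha : float
        GEF catalytic rate constant per enzyme concentration (M^-1 s^-1).
    beta : float
        Effective GAP-driven hydrolysis rate constant (s^-1); the cellular
        GAP concentration is absorbed into it.
    gamma : float
        Tripartite-complex formation rate constant (M^-1 s^-1); the
        cytosolic Rabaptin-5 concentration is absorbed into it.
    lam : float
        Tripartite-complex dissociation rate constant (s^-1).
    sigma : float
        Dimensionless equilibrium constant of direct membrane targeting.
        ``sigma = 0`` disables the direct pathway; ``gamma = 0`` disables
        the indirect one.
    z_tot : float
        Total Rab5 concentration (M).
    x_tot : float
        Total Rabex-5 concentration (M). Response-curve operations supply
        this from a grid and ignore the stored value.
    """

    alpha: float
    beta: float
    gamma: float
    lam: float
    sigma: float
    z_tot: float
    x_tot: float = 0.0

    def __post_init__(self) -> None:
        for key in _PARAM_KEYS:
            value = getattr(self, key)
            if not math.isfinite(value):
                raise DomainError(f"parameter {key}={value!r} must be finite")
            if value < 0:
                raise DomainError(f"parameter {key}={value!r} must be >= 0")

    # -- convenience -------------------------------------------------------
    def replace(self, **changes: float) -> "KineticParameters":
        return dataclasses.replace(self, **changes)

    @property
    def beta_over_alpha(self) -> float:
        """beta/alpha (M), the GAP/GEF balance of the activation cycle."""
        if self.alpha == 0:
            raise DomainError("beta/alpha undefined for alpha = 0")
        return self.beta / self.alpha

    @property
    def lam_over_gamma(self) -> float:
        """lam/gamma (M), the dissociation constant of the tripartite complex."""
        if self.gamma == 0:
            raise DomainError("lam/gamma undefined for gamma = 0")
        return self.lam / self.gamma

    # -- JSON round trip ---------------------------------------------------
    def to_dict(self) -> dict[str, float]:
        return {key: float(getattr(self, key)) for key in _PARAM_KEYS}

    @classmethod
    def from_dict(cls, data: dict) -> "KineticParameters":
        missing = [k for k in _PARAM_KEYS if k not in data]
        if missing:
            raise DomainError(f"parameter JSON missing keys: {missing}")
        return cls(**{k: float(data[k]) for k in _PARAM_KEYS})

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "KineticParameters":
        return cls.from_dict(json.loads(Path(path).read_text()))


class SystemState(NamedTuple):
    """Dynamic variables: Rab5-GTP ``z`` and tripartite complex ``x2`` (M)."""

    z: float
    x2: float


def partition_enzyme(params: KineticParameters, x2: float) -> tuple[float, float]:
    """Split the non-complexed Rabex-5 into cytosolic and membrane pools.

    Conservation ``x0 + x1 + x2 = x_tot`` with the rapid-equilibrium
    constraint ``x1 = sigma * x0`` gives ``x0 = (x_tot - x2)/(1 + sigma)``.

    Returns
    -------
    (x0, x1) : tuple of float
        Cytosolic and directly membrane-bound Rabex-5 (M).
    """
    if x2 < 0 or x2 > params.x_tot:
        raise DomainError(
            f"complex concentration x2={x2!r} outside [0, x_tot={params.x_tot!r}]"
        )
    x0 = (params.x_tot - x2) / (1.0 + params.sigma)
    return x0, params.sigma * x0


def time_derivatives(
    params: KineticParameters, state: SystemState | tuple[float, float]
) -> tuple[float, float]:
    """Right-hand side (dz/dt, dx2/dt) of the activation kinetics (M/s)."""
    z, x2 = state
    x0, x1 = partition_enzyme(params, x2)
    dz = params.alpha * (x1 + x2) * (params.z_tot - z) - params.beta * z
    dx2 = params.gamma * x0 * z - params.lam * x2
    return dz, dx2


def jacobian(
    params: KineticParameters, state: SystemState | tuple[float, float]
) -> np.ndarray:
    """Analytic 2x2 Jacobian of :func:`time_derivatives` at ``state``."""
    z, x2 = state
    p = params
    x0 = (p.x_tot - x2) / (1.0 + p.sigma)
    x1 = p.sigma * x0
    return np.array(
        [
            [-p.alpha * (x1 + x2) - p.beta, p.alpha * (p.z_tot - z) / (1.0 + p.sigma)],
            [p.gamma * x0, -p.gamma * z / (1.0 + p.sigma) - p.lam],
        ]
    )


@dataclass(frozen=True)
class Trajectory:
    """A simulated time course of the activation kinetics.

    ``times`` are in seconds; ``z`` and ``x2`` are molar arrays aligned to
    ``times``. The enzyme pools ``x0``/``x1`` are derived on demand.
    """

    times: np.ndarray
    z: np.ndarray
    x2: np.ndarray
    params: KineticParameters

    @property
    def x0(self) -> np.ndarray:
        return (self.params.x_tot - self.x2) / (1.0 + self.params.sigma)

    @property
    def x1(self) -> np.ndarray:
        return self.params.sigma * self.x0

    def final_state(self) -> SystemState:
        return SystemState(float(self.z[-1]), float(self.x2[-1]))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_s": self.times,
                "z_M": self.z,
                "x2_M": self.x2,
                "x0_M": self.x0,
                "x1_M": self.x1,
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def simulate(
    params: KineticParameters,
    init: SystemState | tuple[float, float] = (0.0, 0.0),
    t_grid: Sequence[float] | np.ndarray = None,
    *,
    rtol: float = 1e-8,
    atol: float = 1e-12,
    method: str = "LSODA",
) -> Trajectory:
    """Integrate the kinetics over ``t_grid`` (seconds, strictly increasing).

    A stiff-capable solver with an analytic Jacobian is used because the
    complex dissociation rate ``lam`` may exceed the other rates by orders
    of magnitude. Small negative excursions (within 100*atol) are clamped
    to zero; anything larger raises :class:`IntegrationError`.

    The default initial state (0, 0) mirrors a Dox-suppressed start with no
    active Rab5 and no tripartite complex.
    """
    if t_grid is None:
        raise DomainError("t_grid is required")
    t = np.asarray(t_grid, dtype=float)
    if t.ndim != 1 or t.size < 2 or np.any(np.diff(t) <= 0):
        raise DomainError("t_grid must be a strictly increasing 1-D grid")
    z0, x20 = init
    if not (0.0 <= z0 <= params.z_tot and 0.0 <= x20 <= params.x_tot):
        raise DomainError(f"initial state {(z0, x20)!r} outside physical bounds")

    def rhs(_t: float, y: np.ndarray) -> list[float]:
        z, x2 = y
        x0 = (params.x_tot - x2) / (1.0 + params.sigma)
        x1 = params.sigma * x0
        return [
            params.alpha * (x1 + x2) * (params.z_tot - z) - params.beta * z,
            params.gamma * x0 * z - params.lam * x2,
        ]

    def jac(_t: float, y: np.ndarray) -> np.ndarray:
        return jacobian(params, tuple(y))

    sol = solve_ivp(
        rhs,
        (t[0], t[-1]),
        [z0, x20],
        t_eval=t,
        method=method,
        rtol=rtol,
        atol=atol,
        jac=jac,
    )
    if not sol.success:
        raise IntegrationError(f"ODE integration failed: {sol.message}")

    z, x2 = sol.y
    slack = 100.0 * atol
    for name, arr, upper in (("z", z, params.z_tot), ("x2", x2, params.x_tot)):
        if arr.min() < -slack or arr.max() > upper + slack:
            raise IntegrationError(
                f"{name} left its physical range [0, {upper}] by more than "
                f"{slack} (min {arr.min()}, max {arr.max()})"
            )
    z = np.clip(z, 0.0, params.z_tot)
    x2 = np.clip(x2, 0.0, params.x_tot)
    return Trajectory(times=t, z=z, x2=x2, params=params)
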