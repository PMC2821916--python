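"""Seeded synthetic Tet-Off induction experiments.

The experiments this module emulates follow enzyme induction after
doxycycline removal: Rabex-5 construct abundance rises from a leaky
baseline (~1/10 of plateau) along a saturating exponential, Rab5-GTP is
read out by a pull-down assay (signal proportional to z plus a small assay
background), and endosome enlargement is scored as the diameters of the 90
largest labeled endosomes across 30 cells. Replicate arms (three, matching
SEM-from-three-blots reporting) carry multiplicative lognormal noise, as
densitometry and fluorescence signals are positive and scale-proportional.

Activity is generated from the quasi-steady-state response
``z(t) = steady_state_general(x_tot(t))``: induction takes hours while the
activation cycle relaxes in seconds-to-minutes, a timescale separation of
order 1e3. A full-ODE mode exists to validate that approximation.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .equilibrium import steady_state_general
from .model import DomainError, KineticParameters, simulate
from .quantify import fg_per_cell_to_molar

__all__ = [
    "InductionProfile",
    "NoiseModel",
    "TimeCourseDataset",
    "induction_timecourse",
    "generate_dataset",
    "quasi_steady_activity",
    "ode_activity",
]


@dataclass(frozen=True)
class InductionProfile:
    """Saturating-exponential enzyme induction after Dox removal.

    ``x(t) = baseline + (plateau - baseline) * (1 - 2**(-t/half_time))``

    baseline_fg : leaky pre-induction level (fg/cell)
    plateau_fg : steady-state level (fg/cell)
    half_time_h : time to half of the rise (h)
    plateau_time_h : approximate saturation time (h); the profile must
        reach at least 95% of plateau there.
    """

    baseline_fg: float
    plateau_fg: float
    half_time_h: float
    plateau_time_h: float

    def __post_init__(self) -> None:
        if not 0 <= self.baseline_fg < self.plateau_fg:
            raise DomainError("require 0 <= baseline < plateau")
        if not 0 < self.half_time_h < self.plateau_time_h:
            raise DomainError("require 0 < half_time < plateau_time")
        if self.level_at(self.plateau_time_h) < 0.95 * self.plateau_fg:
            raise DomainError(
                "profile does not reach 95% of plateau by plateau_time_h"
            )

    def level_at(self, t_h: float) -> float:
        rise = 1.0 - 2.0 ** (-t_h / self.half_time_h)
        return self.baseline_fg + (self.plateau_fg - self.baseline_fg) * rise

    def time_to_level(self, level_fg: float) -> float:
        """Invert the profile (h); raises if the level is never reached."""
        if not self.baseline_fg < level_fg < self.plateau_fg:
            raise DomainError(
                f"level {level_fg} fg/cell outside (baseline, plateau)"
            )
        frac = (level_fg - self.baseline_fg) / (self.plateau_fg - self.baseline_fg)
        return -self.half_time_h * np.log2(1.0 - frac)


def induction_timecourse(profile: InductionProfile, times_h) -> np.ndarray:
    """Noise-free enzyme abundance (fg/cell) along a time grid (hours)."""
    t = np.asarray(times_h, dtype=float)
    if t.size and (np.any(t < 0) or np.any(np.diff(t) <= 0)):
        raise DomainError("times must be non-negative and strictly increasing")
    return profile.baseline_fg + (profile.plateau_fg - profile.baseline_fg) * (
        1.0 - 2.0 ** (-t / profile.half_time_h)
    )


@dataclass(frozen=True)
class NoiseModel:
    """Observation model for the synthetic assays.

    cv : multiplicative lognormal coefficient of variation (densitometry
        and fluorescence; default 15%).
    n_replicates : independent experimental arms per condition (three,
        matching the reported SEM-of-three convention).
    activity_scale : pull-down signal (a.u.) at full activation z = z_tot.
    activity_background : assay background (a.u.); keeps the control arm's
        variance positive so a mean + k*SD onset rule is meaningful.
    endosome_d0_um / endosome_k_um : baseline endosome diameter and the
        gain of the monotone size map d = d0 + k*(z/z_tot)**(1/3), a
        volume-proportional enlargement heuristic. Only monotonicity is
        relied on downstream, never the exponent.
    n_cells, endosomes_per_cell, n_largest : the max-of-sample protocol —
        report the ``n_largest`` diameters among all simulated endosomes
        in ``n_cells`` cells.
    """

    cv: float = 0.15
    n_replicates: int = 3
    activity_scale: float = 1.0
    activity_background: float = 0.02
    endosome_d0_um: float = 0.5
    endosome_k_um: float = 1.0
    n_cells: int = 30
    endosomes_per_cell: int = 20
    n_largest: int = 90

    def __post_init__(self) -> None:
        if self.cv < 0:
            raise DomainError("cv must be >= 0")
        if self.n_replicates < 1:
            raise DomainError("need at least one replicate")
        if self.n_largest > self.n_cells * self.endosomes_per_cell:
            raise DomainError("n_largest exceeds the number of simulated endosomes")


def _lognoise(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Multiplicative lognormal factors with unit mean and the given CV."""
    if cv == 0:
        return np.ones(size)
    s = np.sqrt(np.log1p(cv * cv))
    return rng.lognormal(mean=-0.5 * s * s, sigma=s, size=size)


def quasi_steady_activity(
    params: KineticParameters, x_tot_m: np.ndarray
) -> np.ndarray:
    """Fractional activation z/z_tot at each enzyme level (quasi-steady state)."""
    return np.array(
        [steady_state_general(params.replace(x_tot=float(x))) for x in x_tot_m]
    ) / params.z_tot


def ode_activity(
    params: KineticParameters,
    profile: InductionProfile,
    times_h: np.ndarray,
    mw_kda: float,
    volume_fl: float,
    *,
    init: tuple[float, float] | None = None,
    basal_exchange_per_s: float = 1e-5,
) -> np.ndarray:
    """Fractional activation by full ODE integration with time-varying x_tot.

    Validates the quasi-steady-state shortcut; the enzyme total follows the
    induction profile while z and x2 evolve under the kinetics, starting
    from the pre-induction steady state at the leaky baseline (or ``init``).

    Below threshold with ``sigma = 0`` the deterministic steady state is the
    origin, which remains a fixed point even after the threshold is crossed
    — a trajectory sitting exactly at z = 0 would never activate. Real Rab5
    exchanges nucleotide at a slow intrinsic, GEF-independent rate, so the
    ODE mode includes that basal production term
    ``basal_exchange_per_s * (z_tot - z)``. The default 1e-5 /s is orders
    of magnitude below the GAP-driven hydrolysis rate: it parks the
    below-threshold state at ~1e-4 of z_tot and nucleates the feedback
    within minutes of the threshold crossing, without visibly moving the
    response anywhere else.
    """
    from scipy.integrate import solve_ivp

    t_s = np.asarray(times_h, dtype=float) * 3600.0
    if init is None:
        x_base = fg_per_cell_to_molar(profile.baseline_fg, mw_kda, volume_fl)
        p0 = params.replace(x_tot=x_base)
        z0 = steady_state_general(p0)
        if params.beta > 0:
            z0 = max(z0, basal_exchange_per_s / params.beta * params.z_tot)
        x2_0 = (
            p0.gamma * x_base * z0 / (p0.lam * (1 + p0.sigma) + p0.gamma * z0)
            if p0.gamma > 0
            else 0.0
        )
        init = (z0, x2_0)

    def rhs(t: float, y):
        z, x2 = y
        x_tot = fg_per_cell_to_molar(
            profile.level_at(t / 3600.0), mw_kda, volume_fl
        )
        x0 = (x_tot - x2) / (1.0 + params.sigma)
        x1 = params.sigma * x0
        production = (
            params.alpha * (x1 + x2) + basal_exchange_per_s
        ) * (params.z_tot - z)
        return [
            production - params.beta * z,
            params.gamma * x0 * z - params.lam * x2,
        ]

    sol = solve_ivp(
        rhs,
        (0.0, t_s[-1]),
        list(init),
        t_eval=t_s,
        method="LSODA",
        rtol=1e-8,
        atol=1e-14,
    )
    if not sol.success:
        raise RuntimeError(f"full-ODE generation failed: {sol.message}")
    return np.clip(sol.y[0], 0.0, params.z_tot) / params.z_tot


@dataclass(frozen=True)
class TimeCourseDataset:
    """One synthetic induction experiment with control arm and ground truth.

    Replicate arrays have shape (n_times, n_replicates); endosome arrays
    have shape (n_times, n_largest). ``z_frac_true`` (induced) and
    ``z_frac_control`` are the noise-free fractional activations used to
    generate the observations, kept for recovery tests; they are not part
    of the on-disk CSV bundle.
    """

    times_h: np.ndarray
    enzyme_fg_reps: np.ndarray
    activity_reps: np.ndarray
    control_activity_reps: np.ndarray
    endosome_diameters_um: np.ndarray
    control_endosome_diameters_um: np.ndarray
    seed: int
    params: KineticParameters
    profile: InductionProfile
    noise: NoiseModel
    enzyme_mw_kda: float
    cell_volume_fl: float
    z_frac_true: np.ndarray | None = None
    z_frac_control: float | None = None

    # -- summaries ---------------------------------------------------------
    @property
    def enzyme_fg_mean(self) -> np.ndarray:
        return self.enzyme_fg_reps.mean(axis=1)

    @property
    def enzyme_fg_sem(self) -> np.ndarray:
        n = self.enzyme_fg_reps.shape[1]
        return self.enzyme_fg_reps.std(axis=1, ddof=1) / np.sqrt(n)

    @property
    def activity_mean(self) -> np.ndarray:
        return self.activity_reps.mean(axis=1)

    @property
    def activity_sem(self) -> np.ndarray:
        n = self.activity_reps.shape[1]
        return self.activity_reps.std(axis=1, ddof=1) / np.sqrt(n)

    @property
    def enzyme_molar_mean(self) -> np.ndarray:
        return self.enzyme_fg_mean / (self.enzyme_mw_kda * 1e3 * self.cell_volume_fl)

    @property
    def endosome_mean_um(self) -> np.ndarray:
        return self.endosome_diameters_um.mean(axis=1)

    # -- on-disk bundle ----------------------------------------------------
    def to_csv_bundle(self, directory: str | Path) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        nr = self.activity_reps.shape[1]
        cols = {"time_h": self.times_h}
        for r in range(nr):
            cols[f"enzyme_fg_per_cell_rep{r + 1}"] = self.enzyme_fg_reps[:, r]
        for r in range(nr):
            cols[f"activity_au_rep{r + 1}"] = self.activity_reps[:, r]
        pd.DataFrame(cols).to_csv(d / "timecourse.csv", index=False)

        ctrl = {"time_h": self.times_h}
        for r in range(nr):
            ctrl[f"activity_au_rep{r + 1}"] = self.control_activity_reps[:, r]
        pd.DataFrame(ctrl).to_csv(d / "control.csv", index=False)

        rows = []
        for arm, arr in (
            ("induced", self.endosome_diameters_um),
            ("control", self.control_endosome_diameters_um),
        ):
            for i, t in enumerate(self.times_h):
                for dia in arr[i]:
                    rows.append((t, arm, dia))
        pd.DataFrame(rows, columns=["time_h", "arm", "diameter_um"]).to_csv(
            d / "endosomes.csv", index=False
        )

        manifest = {
            "seed": self.seed,
            "params": self.params.to_dict(),
            "profile": asdict(self.profile),
            "noise": asdict(self.noise),
            "enzyme_mw_kda": self.enzyme_mw_kda,
            "cell_volume_fl": self.cell_volume_fl,
        }
        (d / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")

    @classmethod
    def from_csv_bundle(cls, directory: str | Path) -> "TimeCourseDataset":
        d = Path(directory)
        manifest = json.loads((d / "manifest.json").read_text())
        tc = pd.read_csv(d / "timecourse.csv")
        ctrl = pd.read_csv(d / "control.csv")
        endo = pd.read_csv(d / "endosomes.csv")
        enz_cols = sorted(c for c in tc.columns if c.startswith("enzyme_"))
        act_cols = sorted(c for c in tc.columns if c.startswith("activity_"))
        times = tc["time_h"].to_numpy()

        def pivot(arm: str) -> np.ndarray:
            sub = endo[endo["arm"] == arm]
            return np.array(
                [sub[sub["time_h"] == t]["diameter_um"].to_numpy() for t in times]
            )

        return cls(
            times_h=times,
            enzyme_fg_reps=tc[enz_cols].to_numpy(),
            activity_reps=tc[act_cols].to_numpy(),
            control_activity_reps=ctrl[
                sorted(c for c in ctrl.columns if c.startswith("activity_"))
            ].to_numpy(),
            endosome_diameters_um=pivot("induced"),
            control_endosome_diameters_um=pivot("control"),
            seed=int(manifest["seed"]),
            params=KineticParameters.from_dict(manifest["params"]),
            profile=InductionProfile(**manifest["profile"]),
            noise=NoiseModel(**manifest["noise"]),
            enzyme_mw_kda=float(manifest["enzyme_mw_kda"]),
            cell_volume_fl=float(manifest["cell_volume_fl"]),
        )


def _endosome_sample(
    rng: np.random.Generator, noise: NoiseModel, z_frac: float
) -> np.ndarray:
    """The n_largest diameters among all endosomes simulated in n_cells."""
    n = noise.n_cells * noise.endosomes_per_cell
    base = noise.endosome_d0_um + noise.endosome_k_um * np.cbrt(max(z_frac, 0.0))
    diam = base * _lognoise(rng, noise.cv, n)
    return np.sort(diam)[-noise.n_largest :][::-1]


def generate_dataset(
    params: KineticParameters,
    profile: InductionProfile,
    noise: NoiseModel = NoiseModel(),
    seed: int = 0,
    *,
    times_h=(0.0, 3.0, 6.0, 9.0, 12.0),
    enzyme_mw_kda: float = 40.0,
    cell_volume_fl: float = 80.0,
    mode: str = "qss",
) -> TimeCourseDataset:
    """Generate one seeded induction experiment with a no-induction control.

    At each sampling time the enzyme level from ``profile`` is converted to
    molar and mapped to fractional activation z/z_tot through the
    steady-state response (``mode="qss"``, the default) or by full ODE
    integration with time-varying enzyme (``mode="ode"``). Observations are
    then drawn replicate by replicate: enzyme bands and pull-down activity
    with multiplicative lognormal noise, endosome diameters by the
    max-of-sample protocol. The control arm keeps the enzyme fixed at the
    leaky baseline. Identical seeds give identical datasets.
    """
    t = np.asarray(times_h, dtype=float)
    x_fg = induction_timecourse(profile, t)
    x_m = x_fg / (enzyme_mw_kda * 1e3 * cell_volume_fl)
    x_base_m = profile.baseline_fg / (enzyme_mw_kda * 1e3 * cell_volume_fl)

    if mode == "qss":
        z_frac = quasi_steady_activity(params, x_m)
    elif mode == "ode":
        z_frac = ode_activity(params, profile, t, enzyme_mw_kda, cell_volume_fl)
    else:
        raise ValueError(f"unknown mode {mode!r}; expected 'qss' or 'ode'")
    z_frac_ctrl = float(
        steady_state_general(params.replace(x_tot=x_base_m)) / params.z_tot
    )

    rng = np.random.default_rng(seed)
    nr = noise.n_replicates
    shape = (t.size, nr)

    enzyme_reps = x_fg[:, None] * _lognoise(rng, noise.cv, shape)
    signal = noise.activity_scale * z_frac + noise.activity_background
    activity_reps = signal[:, None] * _lognoise(rng, noise.cv, shape)
    ctrl_signal = noise.activity_scale * z_frac_ctrl + noise.activity_background
    control_reps = ctrl_signal * _lognoise(rng, noise.cv, shape)

    endo = np.array([_endosome_sample(rng, noise, z) for z in z_frac])
    endo_ctrl = np.array(
        [_endosome_sample(rng, noise, z_frac_ctrl) for _ in range(t.size)]
    )

    return TimeCourseDataset(
        times_h=t,
        enzyme_fg_reps=enzyme_reps,
        activity_reps=activity_reps,
        control_activity_reps=control_reps,
        endosome_diameters_um=endo,
        control_endosome_diameters_um=endo_ctrl,
        seed=seed,
        params=params,
        profile=profile,
        noise=noise,
        enzyme_mw_kda=enzyme_mw_kda,
        cell_volume_fl=cell_volume_fl,
        z_frac_true=z_frac,
        z_frac_control=z_frac_ctrl,
    )
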