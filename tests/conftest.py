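import numpy as np
import pytest

from rab5feedback import KineticParameters, simulate, time_derivatives


@pytest.fixture
def fig2_params() -> KineticParameters:
    """The illustrative response-curve constants (z_tot as inferred)."""
    from rab5feedback.presets import FIG2

    return FIG2


def long_time_z(params: KineticParameters, z_init_frac: float = 1e-3) -> float:
    """Independent ODE oracle: integrate until the derivatives vanish.

    Starts from a small z perturbation so that the unstable origin (the
    sigma=0, above-threshold case) is left rather than sat upon, and keeps
    quadrupling the horizon until the state is stationary.
    """
    rates = [r for r in (params.beta, params.alpha * params.z_tot, params.lam) if r > 0]
    t_end = 50.0 / min(rates) if rates else 1e3
    state = (z_init_frac * params.z_tot, 0.0)
    scale = max(params.beta, params.alpha * params.z_tot, 1e-300) * params.z_tot
    for _ in range(14):
        traj = simulate(params, state, np.linspace(0.0, t_end, 60))
        state = traj.final_state()
        dz, dx2 = time_derivatives(params, state)
        if max(abs(dz), abs(dx2)) < 1e-10 * scale:
            break
        t_end *= 4.0
    return state[0]


def random_params(rng: np.random.Generator, **fixed) -> KineticParameters:
    """Log-uniform random rate constants over 1e-2..1e2 (totals 1e-1..1e1)."""
    draw = lambda lo, hi: float(10 ** rng.uniform(lo, hi))
    values = dict(
        alpha=draw(-2, 2),
        beta=draw(-2, 2),
        gamma=draw(-2, 2),
        lam=draw(-2, 2),
        sigma=draw(-2, 1),
        z_tot=draw(-1, 1),
        x_tot=draw(-2, 2),
    )
    values.update(fixed)
    return KineticParameters(**values)
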