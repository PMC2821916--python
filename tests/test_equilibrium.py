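import numpy as np
import pytest
from scipy.optimize import brentq

from rab5feedback import (
    BracketError,
    DomainError,
    KineticParameters,
    hill_coefficient,
    midpoint_direct,
    normalized_slope_sensitivity,
    onset_threshold,
    response_curve,
    steady_state_direct_only,
    steady_state_general,
    steady_state_indirect_only,
)
from conftest import long_time_z, random_params


def brentq_steady_state(p: KineticParameters) -> float:
    """Independent oracle: bracketed root of dz/dt=0 with x2 eliminated."""

    def f(z):
        x2 = p.gamma * p.x_tot * z / (p.lam * (1 + p.sigma) + p.gamma * z) if p.gamma else 0.0
        x0 = (p.x_tot - x2) / (1 + p.sigma)
        return p.alpha * (p.sigma * x0 + x2) * (p.z_tot - z) - p.beta * z

    if f(0.0) <= 0.0:  # origin is the (stable) root or below threshold
        return 0.0
    return brentq(f, 0.0, p.z_tot, xtol=1e-18, rtol=1e-14)


class TestDirectPathway:
    def test_hyperbola_examples(self):
        p = KineticParameters(alpha=1, beta=1, gamma=0, lam=1, sigma=0.1, z_tot=1, x_tot=11)
        assert steady_state_direct_only(p) == pytest.approx(0.5, rel=1e-12)
        assert steady_state_direct_only(p.replace(x_tot=0)) == 0.0
        assert steady_state_direct_only(p.replace(x_tot=1e9)) == pytest.approx(1.0, rel=1e-6)
        # sigma=0 shuts the pathway off entirely (documented, not an error)
        assert steady_state_direct_only(p.replace(sigma=0.0)) == 0.0

    def test_midpoint_formula_and_scaling(self):
        p = KineticParameters(alpha=1, beta=1, gamma=0, lam=1, sigma=0.1, z_tot=1)
        assert midpoint_direct(p) == pytest.approx(11.0, rel=1e-12)
        assert midpoint_direct(p.replace(sigma=1e9)) == pytest.approx(1.0, rel=1e-6)
        assert midpoint_direct(p.replace(beta=2.0)) == pytest.approx(22.0, rel=1e-12)
        with pytest.raises(DomainError):
            midpoint_direct(p.replace(sigma=0.0))

    def test_half_activation_at_midpoint(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            p = random_params(rng, gamma=0.0)
            p = p.replace(x_tot=midpoint_direct(p))
            assert steady_state_direct_only(p) == pytest.approx(p.z_tot / 2, rel=1e-12)


class TestIndirectPathway:
    def test_branch_examples(self):
        p = KineticParameters(alpha=1, beta=1, gamma=1, lam=100, sigma=0, z_tot=200, x_tot=1)
        assert steady_state_indirect_only(p) == pytest.approx(50.0, rel=1e-12)
        # exactly at the onset point the response is zero
        p0 = p.replace(x_tot=onset_threshold(p))
        assert steady_state_indirect_only(p0) == pytest.approx(0.0, abs=1e-12)
        # below threshold the physical branch is the clamped zero
        assert steady_state_indirect_only(p.replace(x_tot=0.25)) == 0.0
        assert long_time_z(p.replace(x_tot=0.25), z_init_frac=1e-4) == pytest.approx(0.0, abs=1e-9)

    def test_threshold_formula_and_inverse_rab5_scaling(self):
        p = KineticParameters(alpha=1, beta=1, gamma=1, lam=100, sigma=0, z_tot=10)
        assert onset_threshold(p) == pytest.approx(10.0, rel=1e-12)
        assert onset_threshold(p.replace(z_tot=200)) == pytest.approx(0.5, rel=1e-12)
        assert onset_threshold(p.replace(z_tot=20)) == pytest.approx(5.0, rel=1e-12)
        with pytest.raises(DomainError):
            onset_threshold(p.replace(z_tot=0.0))

    def test_zero_crossing_brackets_threshold_for_random_params(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            p = random_params(rng, sigma=0.0)
            thr = onset_threshold(p)
            grid = np.geomspace(thr / 10, thr * 10, 400)
            z = np.array([steady_state_indirect_only(p.replace(x_tot=float(x))) for x in grid])
            first = grid[np.argmax(z > 0)]
            below = grid[np.searchsorted(grid, first) - 1]
            assert below <= thr <= first


class TestGeneralSteadyState:
    def test_reduces_to_single_pathway_forms(self):
        rng = np.random.default_rng(5)
        for _ in range(30):
            p = random_params(rng, gamma=0.0)
            assert steady_state_general(p) == pytest.approx(steady_state_direct_only(p), rel=1e-10)
            q = random_params(rng, sigma=0.0)
            assert steady_state_general(q) == pytest.approx(
                steady_state_indirect_only(q), rel=1e-10, abs=1e-14 * q.z_tot
            )

    def test_agrees_with_brentq_and_ode_oracles(self):
        p = KineticParameters(alpha=1, beta=1, gamma=1, lam=100, sigma=0.1, z_tot=10, x_tot=20)
        z = steady_state_general(p)
        assert z == pytest.approx(brentq_steady_state(p), rel=1e-9)
        assert z == pytest.approx(long_time_z(p), rel=1e-5)

    def test_matches_brentq_oracle_on_random_params(self):
        rng = np.random.default_rng(13)
        for _ in range(100):
            p = random_params(rng)
            assert steady_state_general(p) == pytest.approx(
                brentq_steady_state(p), rel=1e-8, abs=1e-12 * p.z_tot
            )

    def test_continuous_and_nondecreasing_in_enzyme(self):
        rng = np.random.default_rng(17)
        for _ in range(20):
            p = random_params(rng)
            grid = np.geomspace(1e-3, 1e3, 200)
            z = np.array([steady_state_general(p.replace(x_tot=float(x))) for x in grid])
            assert np.all(np.diff(z) >= -1e-12 * p.z_tot)
            assert np.all(np.abs(np.diff(z)) < 0.25 * p.z_tot)  # no jumps on a fine grid


class TestResponseCurves:
    def test_modes_and_invariants(self, fig2_params):
        grid = np.geomspace(0.01, 1e4, 300)
        for mode in ("direct_only", "indirect_only", "combined"):
            c = response_curve(fig2_params, grid, mode)
            assert np.all((c.z_values >= 0) & (c.z_values <= fig2_params.z_tot))
            assert np.all(np.diff(c.z_values) >= -1e-12)
        thr = onset_threshold(fig2_params)
        c = response_curve(fig2_params, grid, "indirect_only")
        assert np.all(c.z_values[grid < thr] == 0.0)

    def test_empty_grid_and_unknown_mode(self, fig2_params):
        assert response_curve(fig2_params, [], "combined").z_values.size == 0
        with pytest.raises(ValueError, match="mode"):
            response_curve(fig2_params, [1.0, 2.0], "sideways")

    def test_csv_and_sidecar(self, fig2_params, tmp_path):
        c = response_curve(fig2_params, np.geomspace(0.1, 1e4, 200), "combined")
        c.to_csv(tmp_path / "curve.csv", sidecar=tmp_path / "curve.json")
        header = (tmp_path / "curve.csv").read_text().splitlines()[0]
        assert header == "x_tot_M,z_M"
        import json

        meta = json.loads((tmp_path / "curve.json").read_text())
        assert meta["mode"] == "combined"
        assert meta["onset_threshold_M"] == pytest.approx(10.0)


class TestHillCoefficient:
    def test_direct_pathway_is_hyperbolic(self):
        rng = np.random.default_rng(23)
        for _ in range(10):
            p = random_params(rng, gamma=0.0)
            mid = midpoint_direct(p)
            c = response_curve(p, np.geomspace(mid * 1e-3, mid * 1e3, 3000), "direct_only")
            assert hill_coefficient(c) == pytest.approx(1.0, abs=0.01)

    @pytest.mark.parametrize(
        "lam, expected, tol",
        [(1e4, 2.0, 0.02), (1e-4, 1.0, 0.02)],
    )
    def test_feedback_sensitivity_limits(self, lam, expected, tol):
        """n_H -> 2 when lam/gamma >> z_tot and -> 1 when lam/gamma << z_tot."""
        p = KineticParameters(alpha=1, beta=1, gamma=1, lam=lam, sigma=0, z_tot=1)
        lo = max(onset_threshold(p) * 1e-2, 1e-6)
        c = response_curve(p, np.geomspace(lo, 1e8, 5000), "indirect_only")
        assert hill_coefficient(c) == pytest.approx(expected, abs=tol)

    def test_monotone_in_affinity_over_rab5(self):
        values = []
        for lam in 10.0 ** np.arange(-3, 4):
            p = KineticParameters(alpha=1, beta=1, gamma=1, lam=lam, sigma=0, z_tot=1)
            c = response_curve(p, np.geomspace(1e-6, 1e9, 4000), "indirect_only")
            values.append(hill_coefficient(c))
        assert all(b >= a - 1e-6 for a, b in zip(values, values[1:]))
        assert all(1.0 - 0.02 <= v <= 2.0 + 0.02 for v in values)

    def test_matches_analytic_crossing_points(self):
        """x10/x90 from interpolation equal the closed-form crossings of Eq-7-type branch."""
        p = KineticParameters(alpha=1, beta=1, gamma=1, lam=50.0, sigma=0, z_tot=2.0)
        c = response_curve(p, np.geomspace(1e-2, 1e5, 6000), "indirect_only")

        def x_at(frac):  # invert the rising branch: f z_tot (a x + b) = a x z_tot - lam b / g
            f = frac
            return (f * p.z_tot * p.beta + p.lam * p.beta / p.gamma) / (p.z_tot * p.alpha * (1 - f))

        expected = np.log(81) / np.log(x_at(0.9) / x_at(0.1))
        assert hill_coefficient(c) == pytest.approx(expected, rel=1e-3)

    def test_bracket_error_when_grid_too_narrow(self, fig2_params):
        c = response_curve(fig2_params, np.geomspace(0.01, 0.1, 50), "direct_only")
        with pytest.raises(BracketError, match="widen"):
            hill_coefficient(c)

    def test_normalized_slope_diagnostic_positive_and_larger_for_feedback(self, fig2_params):
        grid = np.geomspace(0.01, 1e5, 4000)
        s_direct = normalized_slope_sensitivity(response_curve(fig2_params, grid, "direct_only"))
        s_feedback = normalized_slope_sensitivity(response_curve(fig2_params, grid, "indirect_only"))
        assert s_direct > 0
        assert s_feedback > s_direct
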