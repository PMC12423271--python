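"""Integral-equation solver: free density, kernel, recursion, interpolation."""

import numpy as np
import pytest
from scipy.integrate import quad

from hsdm import (
    KernelContext,
    ThresholdSpec,
    density_at,
    free_density,
    kernel_psi,
    series_fpt_density,
    solve_fpt,
)


class TestFreeDensity:
    def test_origin_start_is_exponential_for_n2(self):
        # small-argument limit of I_0 turns the kernel into exp(-y/2t)/(2t)
        t = 0.7
        y = np.linspace(0.0, 10.0, 50)
        expected = np.exp(-y / (2 * t)) / (2 * t)
        assert np.allclose(free_density(y, t, 0.0, 0.0, 2), expected,
                           rtol=1e-12)

    @pytest.mark.parametrize("n", [2, 3, 4])
    def test_normalization(self, n):
        rng = np.random.default_rng(n)
        for _ in range(3):
            y0 = rng.uniform(0.0, 4.0)
            tau = rng.uniform(0.0, 1.0)
            t = tau + rng.uniform(0.1, 2.0)
            total, _ = quad(lambda y: free_density(y, t, y0, tau, n),
                            0.0, np.inf, limit=200)
            assert total == pytest.approx(1.0, abs=1e-8)

    def test_chapman_kolmogorov(self):
        # f[y,t|y0,tau] = int f[y,t|z,s] f[z,s|y0,tau] dz on a test triple
        n, y0, tau, s, t, y = 3, 0.5, 0.0, 0.4, 1.1, 2.3
        direct = free_density(y, t, y0, tau, n)
        composed, _ = quad(
            lambda z: free_density(y, t, z, s, n) * free_density(z, s, y0, tau, n),
            0.0, np.inf, limit=200,
        )
        assert composed == pytest.approx(direct, abs=1e-6)

    def test_time_ordering_enforced(self):
        with pytest.raises(ValueError):
            free_density(1.0, 0.5, 0.0, 0.5, 2)


class TestKernel:
    def test_vanishing_as_tau_approaches_t(self):
        # on the boundary (y = S) the kernel must vanish as the gap closes
        thr = ThresholdSpec.constant(1.5)
        ctx = KernelContext(n=2, threshold=thr)
        t = 1.0
        vals = [abs(kernel_psi(t, t - gap, thr.S(t), ctx))
                for gap in (1e-2, 1e-3, 1e-4)]
        assert vals[0] > vals[1] > vals[2]
        assert vals[2] < 1e-3

    def test_first_step_density_nonnegative(self):
        # g(dt) = -2 Psi[S(dt), dt | 0, 0] is a density value
        ctx = KernelContext(n=2, threshold=ThresholdSpec.constant(1.0))
        for dt in (0.01, 0.02, 0.05):
            assert -2.0 * kernel_psi(dt, 0.0, 0.0, ctx) >= 0.0

    def test_constant_threshold_drift_term(self):
        # with dS/dt = 0 the kernel reduces to the K = (n-1)/2 form; check
        # against a directly coded evaluation of that reduced expression
        from scipy.special import ive

        b, n, t, tau, y = 1.3, 3, 0.9, 0.4, 0.8
        ctx = KernelContext(n=n, threshold=ThresholdSpec.constant(b))
        S, d, nu = b * b, t - tau, n / 2 - 1
        z = np.sqrt(y * S) / d
        reduced = (
            0.5 / d * (S / y) ** (nu / 2)
            * np.exp(-(S + y) / (2 * d))
            * ((0.5 * (n - 1) - S / d) * ive(nu, z) * np.exp(z)
               + z * ive(nu + 1, z) * np.exp(z))
        )
        assert kernel_psi(t, tau, y, ctx) == pytest.approx(reduced, rel=1e-10)

    def test_rejects_singular_times(self):
        ctx = KernelContext(n=2, threshold=ThresholdSpec.linear(2.0, 1.0))
        with pytest.raises(ValueError):
            kernel_psi(2.5, 0.5, 1.0, ctx)


class TestSolver:
    @pytest.mark.parametrize(("n", "b"), [(2, 1.0), (2, 2.0), (3, 1.0),
                                          (4, 2.0)])
    def test_matches_bessel_series(self, n, b):
        ctx = KernelContext(n=n, threshold=ThresholdSpec.constant(b))
        grid = solve_fpt(ctx, 0.01, 6.0)
        mask = grid.times >= 0.3
        oracle = series_fpt_density(grid.times[mask], b, 1.0, n)
        assert np.max(np.abs(grid.g[mask] - oracle)) < 1e-3

    def test_error_decreases_with_step(self):
        ctx = KernelContext(n=3, threshold=ThresholdSpec.constant(1.0))
        errs = []
        for dt in (0.1, 0.05, 0.025):
            grid = solve_fpt(ctx, dt, 4.0)
            mask = grid.times >= 0.3
            oracle = series_fpt_density(grid.times[mask], 1.0, 1.0, 3)
            errs.append(np.max(np.abs(grid.g[mask] - oracle)))
        assert errs[0] > errs[1] > errs[2]

    def test_first_order_convergence_rate(self):
        # rectangle scheme: log-log slope of error vs dt close to 1
        ctx = KernelContext(n=2, threshold=ThresholdSpec.constant(1.0))
        dts = np.array([0.1, 0.05, 0.025, 0.0125])
        errs = []
        for dt in dts:
            grid = solve_fpt(ctx, dt, 4.0)
            mask = grid.times >= 0.5
            oracle = series_fpt_density(grid.times[mask], 1.0, 1.0, 2)
            errs.append(np.max(np.abs(grid.g[mask] - oracle)))
        slope = np.polyfit(np.log(dts), np.log(errs), 1)[0]
        assert 0.7 < slope < 1.5

    def test_normalization_and_nonnegativity(self):
        ctx = KernelContext(n=2, threshold=ThresholdSpec.constant(1.0))
        grid = solve_fpt(ctx, 0.02, 5.0)  # covers >99.9% of the mass
        total = np.trapezoid(np.concatenate(([0.0], grid.g)),
                             np.concatenate(([0.0], grid.times)))
        assert 0.99 <= total <= 1.005
        assert grid.g.min() > -1e-4

    def test_collapse_matches_zero_drift_simulation(self):
        # linear collapse b0=3, lam=1.5: grid CDF vs empirical CDF of
        # simulated zero-drift first-passage times
        from hsdm import HSDMParameters, SimConfig, simulate_trials

        thr = ThresholdSpec.linear(3.0, 1.5)
        p = HSDMParameters(n=2, mu=np.zeros(2), t0=0.0, threshold=thr)
        tr = simulate_trials(p, SimConfig(n_trials=100_000, seed=7,
                                          dt_sim=3e-4))
        grid = solve_fpt(KernelContext(n=2, threshold=thr), 0.005, 1.95)
        cdf = grid.cdf()
        xs = np.sort(tr.rt)
        f_model = np.interp(xs, grid.times, cdf)
        f_emp = np.arange(1, len(xs) + 1) / len(xs)
        ks = np.max(np.abs(f_emp - f_model))
        assert ks < 0.01

    def test_horizon_must_stay_below_singular_time(self):
        ctx = KernelContext(n=2, threshold=ThresholdSpec.linear(2.0, 1.0))
        with pytest.raises(ValueError, match="singular"):
            solve_fpt(ctx, 0.01, 2.0)

    def test_grid_spec_validation(self):
        ctx = KernelContext(n=2, threshold=ThresholdSpec.constant(1.0))
        with pytest.raises(ValueError):
            solve_fpt(ctx, -0.01, 1.0)
        with pytest.raises(ValueError):
            solve_fpt(ctx, 0.03, 1.0)  # not an integer number of steps


@pytest.fixture(scope="module")
def grid():
    ctx = KernelContext(n=2, threshold=ThresholdSpec.constant(1.0))
    return solve_fpt(ctx, 0.05, 3.0)


class TestDensityAt:
    def test_node_identity(self, grid):
        i = 10
        assert density_at(grid, grid.times[i]) == pytest.approx(grid.g[i])

    def test_midpoint_is_mean_of_neighbours(self, grid):
        mid = 0.5 * (grid.times[3] + grid.times[4])
        assert density_at(grid, mid) == pytest.approx(
            0.5 * (grid.g[3] + grid.g[4]))

    def test_out_of_range(self, grid):
        assert density_at(grid, -0.1) == 0.0
        assert density_at(grid, 0.0) == 0.0
        assert density_at(grid, grid.t_max + 1.0) == 0.0
        assert density_at(grid, grid.t_max + 1.0, right=1e-10) == 1e-10
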