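"""Girsanov joint density of response time and angle, and the NLL objective."""

import numpy as np
import pytest

from hsdm import (
    LIKELIHOOD_FLOOR,
    HSDMParameters,
    ThresholdSpec,
    TrialTable,
    density_at,
    joint_density,
    neg_log_likelihood,
    solve_for_params,
    sphere_surface_area,
    spherical_to_cartesian,
)


@pytest.fixture(scope="module")
def circle_grid(circle_params):
    return solve_for_params(circle_params, 0.01)


class TestJointDensity:
    def test_zero_drift_is_uniform_over_angles(self):
        p = HSDMParameters(n=2, mu=np.zeros(2), t0=0.1,
                           threshold=ThresholdSpec.constant(1.5))
        grid = solve_for_params(p, 0.01)
        rt = 0.8
        vals = [joint_density(rt, np.array([phi]), p, grid)
                for phi in (0.0, 1.0, np.pi, 5.0)]
        expected = density_at(grid, rt - p.t0) / sphere_surface_area(2)
        assert np.allclose(vals, expected, rtol=1e-12)

    def test_girsanov_wrapper_is_algebraically_exact(self, circle_params,
                                                     circle_grid):
        # same g input: joint must equal exp(mu.X - ||mu||^2 T/2) g(T)/A
        p = circle_params
        rt, phi = 0.9, np.array([0.7])
        T = rt - p.t0
        X = spherical_to_cartesian(p.threshold.b(T), phi)
        manual = (np.exp(p.mu @ X - 0.5 * (p.mu @ p.mu) * T)
                  * density_at(circle_grid, T) / sphere_surface_area(2))
        assert joint_density(rt, phi, p, circle_grid) == pytest.approx(
            manual, rel=1e-10)

    def test_drift_aligned_angle_is_more_likely(self, circle_params,
                                                circle_grid):
        p = circle_params
        aligned = float(np.mod(np.arctan2(p.mu[1], p.mu[0]), 2 * np.pi))
        opposed = float(np.mod(aligned + np.pi, 2 * np.pi))
        rt = 1.0
        assert joint_density(rt, np.array([aligned]), p, circle_grid) > \
            joint_density(rt, np.array([opposed]), p, circle_grid)

    def test_normalizes_over_time_and_angle(self):
        # kappa = 2*sqrt(5) <= 10; double integral over (T, phi) ~ 1
        p = HSDMParameters(n=2, mu=np.array([2.0, 1.0]), t0=0.0,
                           threshold=ThresholdSpec.constant(2.0))
        grid = solve_for_params(p, 0.005)
        phis = np.linspace(0.0, 2 * np.pi, 256, endpoint=False)
        slice_integrals = [
            joint_density(np.full(phis.shape, rt), np.c_[phis], p, grid,
                          floor=0.0).sum() * (2 * np.pi / len(phis))
            for rt in grid.times
        ]
        total = np.trapezoid(slice_integrals, grid.times)
        assert total == pytest.approx(1.0, abs=1e-2)

    def test_rotation_invariance(self):
        # rotating mu together with all observed angles leaves the
        # likelihood unchanged (isotropy of the model)
        rng = np.random.default_rng(3)
        rt = rng.uniform(0.4, 2.0, 50)
        phi = rng.uniform(0.0, 2 * np.pi, (50, 1))
        alpha = 1.234
        thr = ThresholdSpec.constant(2.0)
        p1 = HSDMParameters(n=2, mu=np.array([2.0, 0.5]), t0=0.2, threshold=thr)
        rot = np.array([[np.cos(alpha), -np.sin(alpha)],
                        [np.sin(alpha), np.cos(alpha)]])
        p2 = HSDMParameters(n=2, mu=rot @ p1.mu, t0=0.2, threshold=thr)
        t1 = TrialTable(rt=rt, phi=phi)
        t2 = TrialTable(rt=rt, phi=np.mod(phi + alpha, 2 * np.pi))
        nll1 = neg_log_likelihood(t1, p1, 0.01)
        nll2 = neg_log_likelihood(t2, p2, 0.01)
        assert nll1 == pytest.approx(nll2, abs=1e-8)

    def test_collapsing_threshold_uses_stopping_time_radius(self):
        # the Girsanov factor must evaluate the boundary at T, not at 0
        p = HSDMParameters(n=2, mu=np.array([1.0, 0.0]), t0=0.0,
                           threshold=ThresholdSpec.linear(3.0, 1.5))
        grid = solve_for_params(p, 0.01)
        rt, phi = 1.0, np.array([0.0])
        T = rt - p.t0
        b_T = 3.0 - 1.5 * T  # = 1.5, not b(0) = 3
        manual = (np.exp(p.mu[0] * b_T - 0.5 * T)
                  * density_at(grid, T) / sphere_surface_area(2))
        assert joint_density(rt, phi, p, grid) == pytest.approx(manual,
                                                                rel=1e-10)

    def test_floor_for_pre_t0_times(self, circle_params, circle_grid):
        val = joint_density(0.1, np.array([0.0]), circle_params, circle_grid)
        assert val == LIKELIHOOD_FLOOR

    def test_dimension_mismatch_rejected(self, circle_params, circle_grid):
        with pytest.raises(ValueError):
            joint_density(1.0, np.array([0.5, 0.5]), circle_params,
                          circle_grid)


class TestNegLogLikelihood:
    def test_all_trials_before_t0_hit_the_floor(self, circle_params):
        trials = TrialTable(rt=np.full(5, 0.05), phi=np.zeros((5, 1)))
        nll = neg_log_likelihood(trials, circle_params, 0.02)
        assert nll == pytest.approx(-5 * np.log(LIKELIHOOD_FLOOR))

    def test_truth_beats_perturbed_threshold(self, circle_params):
        from hsdm import SimConfig, simulate_trials

        trials = simulate_trials(circle_params,
                                 SimConfig(n_trials=1000, seed=12))
        nll_true = neg_log_likelihood(trials, circle_params, 0.02)
        for factor in (0.8, 1.2):
            b = circle_params.threshold.params["b"] * factor
            perturbed = HSDMParameters(
                n=2, mu=circle_params.mu, t0=circle_params.t0,
                threshold=ThresholdSpec.constant(b))
            assert nll_true < neg_log_likelihood(trials, perturbed, 0.02)

    def test_empty_table_rejected(self, circle_params):
        with pytest.raises(ValueError):
            TrialTable(rt=np.array([]), phi=np.empty((0, 1)))


class TestTrialTableIO:
    def test_csv_round_trip(self, tmp_path):
        rng = np.random.default_rng(5)
        t = TrialTable(rt=rng.uniform(0.3, 2.0, 20),
                       phi=np.column_stack([rng.uniform(0, np.pi, 20),
                                            rng.uniform(0, 2 * np.pi, 20)]))
        path = tmp_path / "trials.csv"
        t.to_csv(path)
        back = TrialTable.read_csv(path)
        assert back.n == 3
        assert np.allclose(back.rt, t.rt)
        assert np.allclose(back.phi, t.phi)

    def test_validation_names_the_offending_row(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("rt,phi_1\n0.5,1.0\n0.7,7.0\n")
        with pytest.raises(ValueError, match="row 2"):
            TrialTable.read_csv(path)
        path.write_text("rt,phi_1\n-0.5,1.0\n")
        with pytest.raises(ValueError, match="row 1"):
            TrialTable.read_csv(path)

    def test_missing_columns_rejected(self, tmp_path):
        path = tmp_path / "cols.csv"
        path.write_text("time,angle\n0.5,1.0\n")
        with pytest.raises(ValueError, match="rt"):
            TrialTable.read_csv(path)
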