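"""Shared fixtures and helpers for the hsdm test suite."""

from __future__ import annotations

import numpy as np
import pytest

from hsdm import (
    HSDMParameters,
    ThresholdSpec,
    marginal_rt_density,
    solve_for_params,
)


def ks_distance_to_model(rts: np.ndarray, params: HSDMParameters,
                         delta_t: float = 0.005) -> float:
    """Kolmogorov–Smirnov distance between sampled RTs and the IE marginal."""
    grid = solve_for_params(params, delta_t, max_rt=float(np.max(rts)))
    m = marginal_rt_density(params, grid)
    times = grid.times + params.t0
    cdf = np.concatenate(
        ([0.0], np.cumsum(0.5 * (m[1:] + m[:-1]) * np.diff(grid.times)))
    )
    cdf = cdf / cdf[-1]
    xs = np.sort(np.asarray(rts, dtype=float))
    f_model = np.interp(xs, times, cdf)
    f_emp_hi = np.arange(1, len(xs) + 1) / len(xs)
    f_emp_lo = f_emp_hi - 1.0 / len(xs)
    return float(np.max(np.maximum(np.abs(f_emp_hi - f_model),
                                   np.abs(f_emp_lo - f_model))))


@pytest.fixture(scope="session")
def circle_params() -> HSDMParameters:
    """2D constant-threshold model with moderate drift."""
    return HSDMParameters(n=2, mu=np.array([2.0, 1.0]), t0=0.3,
                          threshold=ThresholdSpec.constant(2.0))


@pytest.fixture(scope="session")
def collapse_params() -> HSDMParameters:
    """2D linearly collapsing model (boundary reaches zero at t=2)."""
    return HSDMParameters(n=2, mu=np.array([1.0, 1.0]), t0=0.2,
                          threshold=ThresholdSpec.linear(3.0, 1.5))
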