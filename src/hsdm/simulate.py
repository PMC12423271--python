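"""Euler–Maruyama simulation of the accumulation process on an absorbing sphere.

Trajectories follow ``X(t+dt) = X(t) + mu dt + sigma sqrt(dt) Z`` from the
origin and stop at the first step with ``||X|| >= b(t)``.  The exiting
point is projected radially onto the boundary sphere for the reported
angle (no Brownian-bridge correction; the discretization bias is
controlled by the default step of 1 ms and quantified by the refinement
property in the test suite).  For a linear collapse the boundary reaches
zero at ``t_singular = b0/lambda``, where any state is absorbed: surviving
trials are forced to stop there, mirroring the fast-guess behaviour of
strongly collapsed thresholds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .likelihood import TrialTable
from .model import HSDMParameters, cartesian_to_spherical

__all__ = ["SimConfig", "simulate_trials"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SimConfig:
    """Simulation settings: step size, trial count, seed, bailout horizon."""

    n_trials: int
    seed: int
    dt_sim: float = 1e-3
    max_time: float = 30.0

    def __post_init__(self):
        if self.dt_sim <= 0:
            raise ValueError("dt_sim must be positive")
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        if self.max_time <= 0:
            raise ValueError("max_time must be positive")


def simulate_trials(params: HSDMParameters, cfg: SimConfig) -> TrialTable:
    """Simulate first-passage trials; reproducible under a fixed seed.

    Returns a :class:`TrialTable` with ``rt = hitting time + t0`` and the
    hitting angles.  Trials still running at ``max_time`` are censored:
    excluded from the table, counted in ``n_censored`` and logged.
    """
    rng = np.random.default_rng(cfg.seed)
    n, dt = params.n, cfg.dt_sim
    mu_step = params.mu * dt
    noise_scale = params.sigma * np.sqrt(dt)
    thr = params.threshold
    t_sing = thr.t_singular

    m = cfg.n_trials
    x = np.zeros((m, n))
    active = np.arange(m)
    hit_time = np.full(m, np.nan)
    hit_x = np.zeros((m, n))

    max_steps = int(np.ceil(cfg.max_time / dt))
    step = 0
    while active.size and step < max_steps:
        step += 1
        t = step * dt
        x[active] += mu_step + noise_scale * rng.standard_normal(
            (active.size, n))
        if t >= t_sing:
            # boundary has collapsed to zero: everything is absorbed
            hit_time[active] = t_sing
            hit_x[active] = x[active]
            active = active[:0]
            break
        b_t = float(np.asarray(thr.b(t)))
        r = np.linalg.norm(x[active], axis=1)
        crossed = r >= b_t
        if crossed.any():
            idx = active[crossed]
            hit_time[idx] = t
            hit_x[idx] = x[idx]
            active = active[~crossed]

    if active.size:
        logger.info(
            "simulate_trials: %d of %d trials censored at max_time=%.3gs "
            "and excluded", active.size, m, cfg.max_time,
        )
    done = ~np.isnan(hit_time)
    if not done.any():
        raise RuntimeError(
            "all simulated trials were censored; increase max_time"
        )
    xs = hit_x[done]
    # degenerate states at the collapse point (prob. ~0 exactly at origin)
    zero_rows = np.linalg.norm(xs, axis=1) == 0.0
    if zero_rows.any():
        xs[zero_rows, 0] = 1.0
    _, phi = cartesian_to_spherical(xs)
    phi = np.atleast_2d(phi)
    return TrialTable(
        rt=hit_time[done] + params.t0,
        phi=phi,
        n_censored=int(m - done.sum()),
    )
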