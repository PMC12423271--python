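"""Joint response-time / response-angle likelihood via the Girsanov factor.

The zero-drift first-passage density ``g`` (from the integral-equation
solver or, for constant thresholds, the analytic series) is mapped to the
joint density of decision time and hitting direction of the *driven*
process by an exponential change-of-measure factor:

    p(T, phi) = exp( mu . X(T) / sigma^2 - ||mu||^2 T / (2 sigma^2) )
                * g(T) / A_{n-1},

where ``T = rt - t0``, ``X(T)`` is the Cartesian stopping point on the
boundary sphere of radius ``b(T)`` (the threshold value *at the stopping
time* — this is the only change needed for collapsing thresholds), and
``A_{n-1} = 2 pi^{n/2} / Gamma(n/2)`` is the unit-sphere surface area.

The density is taken with respect to (time x uniform surface measure);
expressed per angle coordinates it would pick up the usual Jacobian
``prod_k sin^{n-1-k}(phi_k)``.  The constant normalisation does not affect
maximum-likelihood estimation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gamma as _gamma
from scipy.special import ive

from .model import (
    HSDMParameters,
    sphere_surface_area,
    spherical_to_cartesian,
    validate_angles,
)
from .volterra import FPTGrid, density_at, solve_for_params

__all__ = [
    "TrialTable",
    "joint_density",
    "neg_log_likelihood",
    "marginal_rt_density",
    "LIKELIHOOD_FLOOR",
]

# Guards the log against discretization-induced tiny/negative densities and
# out-of-support trials, keeping the optimizer's objective finite everywhere.
LIKELIHOOD_FLOOR = 1e-10


@dataclass(frozen=True)
class TrialTable:
    """Observed or simulated trials: response times and response angles.

    ``rt`` has shape (N,) in seconds; ``phi`` has shape (N, n-1) in
    radians under the package angle convention.  The model dimension is
    implied by the angle count.
    """

    rt: np.ndarray
    phi: np.ndarray
    n_censored: int = field(default=0, compare=False)

    def __post_init__(self):
        rt = np.asarray(self.rt, dtype=float)
        phi = np.atleast_2d(np.asarray(self.phi, dtype=float))
        if rt.size == 0:
            raise ValueError("trial table is empty")
        if rt.ndim != 1 or phi.shape[0] != rt.shape[0]:
            raise ValueError("rt and phi must have one row per trial")
        if np.any(rt <= 0):
            raise ValueError("response times must be positive")
        validate_angles(phi)
        object.__setattr__(self, "rt", rt)
        object.__setattr__(self, "phi", phi)

    def __len__(self) -> int:
        return len(self.rt)

    @property
    def n(self) -> int:
        """Model dimension implied by the angle count."""
        return self.phi.shape[1] + 1

    # -- CSV dialect: header rt,phi_1[,phi_2,...]; seconds, radians ----

    def to_frame(self) -> pd.DataFrame:
        cols = {"rt": self.rt}
        for i in range(self.phi.shape[1]):
            cols[f"phi_{i + 1}"] = self.phi[:, i]
        return pd.DataFrame(cols)

    def to_csv(self, path) -> None:
        # %.17g round-trips float64 exactly through the CSV dialect
        self.to_frame().to_csv(path, index=False, float_format="%.17g")

    @staticmethod
    def from_frame(df: pd.DataFrame) -> "TrialTable":
        angle_cols = [c for c in df.columns if c.startswith("phi_")]
        expected = [f"phi_{i + 1}" for i in range(len(angle_cols))]
        if "rt" not in df.columns or angle_cols != expected:
            raise ValueError(
                "trial table must have columns rt, phi_1[, phi_2, ...]; "
                f"got {list(df.columns)}"
            )
        rt = df["rt"].to_numpy(dtype=float)
        phi = df[angle_cols].to_numpy(dtype=float)
        bad = np.flatnonzero(~np.isfinite(rt) | (rt <= 0))
        if bad.size:
            raise ValueError(f"invalid response time in data row {bad[0] + 1}")
        try:
            validate_angles(phi)
        except ValueError as exc:
            ok = (
                np.all((phi[:, :-1] >= 0) & (phi[:, :-1] <= np.pi), axis=1)
                if phi.shape[1] > 1 else np.ones(len(phi), bool)
            )
            ok &= (phi[:, -1] >= 0) & (phi[:, -1] < 2 * np.pi)
            row = int(np.flatnonzero(~ok)[0]) + 1 if not ok.all() else "?"
            raise ValueError(f"angle out of range in data row {row}") from exc
        return TrialTable(rt=rt, phi=phi)

    @staticmethod
    def read_csv(path) -> "TrialTable":
        return TrialTable.from_frame(
            pd.read_csv(path, float_precision="round_trip"))


def _stopping_points(params: HSDMParameters, T: np.ndarray,
                     phi: np.ndarray) -> np.ndarray:
    """Cartesian hitting points X(T) on the sphere of radius b(T)."""
    b_at_T = np.asarray(params.threshold.b(np.maximum(T, 0.0)), dtype=float)
    b_at_T = np.broadcast_to(b_at_T, T.shape)
    X = spherical_to_cartesian(np.where(b_at_T > 0, b_at_T, 1.0), phi)
    X = np.atleast_2d(X).copy()
    X[b_at_T <= 0] = np.nan  # past collapse: no valid stopping point
    return X


def joint_density(rt, phi, params: HSDMParameters, grid: FPTGrid,
                  floor: float = LIKELIHOOD_FLOOR):
    """Joint density of (response time, response angles) per trial.

    ``grid`` must be a zero-drift first-passage grid solved for the same
    (rescaled) threshold and dimension.  Trials with ``T = rt - t0 <= 0``
    or beyond the grid horizon receive the likelihood floor.
    """
    p = params.rescaled()
    rt = np.atleast_1d(np.asarray(rt, dtype=float))
    scalar = np.asarray(phi).ndim == 1
    phi = validate_angles(phi, n=p.n)
    if phi.shape[0] == 1 and rt.shape[0] > 1:
        phi = np.broadcast_to(phi, (rt.shape[0], phi.shape[1]))
    if grid.n != p.n:
        raise ValueError(f"grid dimension {grid.n} != model dimension {p.n}")
    T = rt - p.t0
    g = density_at(grid, T)
    valid = T > 0
    X = _stopping_points(p, T, phi)
    mu_norm2 = float(p.mu @ p.mu)
    expo = (X @ p.mu) - 0.5 * mu_norm2 * T
    with np.errstate(invalid="ignore", over="ignore"):
        dens = np.exp(expo) * g / sphere_surface_area(p.n)
    dens = np.where(valid & np.isfinite(dens), dens, 0.0)
    dens = np.maximum(dens, floor)
    return float(dens[0]) if scalar else dens


def neg_log_likelihood(trials: TrialTable, params: HSDMParameters,
                       delta_t: float, grid: FPTGrid | None = None,
                       floor: float = LIKELIHOOD_FLOOR) -> float:
    """Negative log-likelihood of a trial set.

    One grid solve per parameter vector, reused across all trials (the
    zero-drift grid depends only on the threshold and dimension).  The
    floor keeps the objective finite for any parameter vector in bounds.
    """
    if len(trials) == 0:
        raise ValueError("trial table is empty")
    if trials.n != params.n:
        raise ValueError(
            f"trial angle count implies n={trials.n}, model has n={params.n}"
        )
    if grid is None:
        grid = solve_for_params(params, delta_t, max_rt=float(np.max(trials.rt)))
    dens = joint_density(trials.rt, trials.phi, params, grid, floor=floor)
    return float(-np.sum(np.log(dens)))


def marginal_rt_density(params: HSDMParameters, grid: FPTGrid) -> np.ndarray:
    """Marginal decision-time density on the grid, angles integrated out.

    Averaging the Girsanov factor over the uniform hitting direction gives
    ``m(T) = g(T) exp(-||mu||^2 T / 2) Gamma(n/2) (2/(b(T)||mu||))^{n/2-1}
    I_{n/2-1}(b(T)||mu||)`` (the spherical average of ``e^{mu.x}``), which
    reduces to ``g(T)`` for zero drift.
    """
    p = params.rescaled()
    if grid.n != p.n:
        raise ValueError("grid dimension does not match the model")
    mu_norm = p.drift_norm
    T = grid.times
    if mu_norm == 0.0:
        return grid.g.copy()
    nu = p.n / 2.0 - 1.0
    z = np.asarray(p.threshold.b(T), dtype=float) * mu_norm
    # Gamma(n/2) (2/z)^nu I_nu(z); evaluate the z->0 limit as 1.
    with np.errstate(divide="ignore", invalid="ignore"):
        avg = _gamma(p.n / 2.0) * (2.0 / z) ** nu * ive(nu, z) * np.exp(z)
    avg = np.where(z > 0, avg, 1.0)
    return grid.g * np.exp(-0.5 * mu_norm**2 * T) * avg
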