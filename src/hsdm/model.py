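"""Core domain types for hyper-spherical diffusion models (HSDM).

An HSDM describes a continuous-response decision as an ``n``-dimensional
Wiener accumulation process ``dX = mu dt + sigma dW`` started at the
origin and absorbed the first time its Euclidean norm reaches a decision
threshold ``b(t)`` (a circle for n=2, a sphere for n=3, ...).  The hitting
*angle* is the reported response and the hitting time plus a non-decision
latency ``t0`` is the response time.  The threshold may be constant or may
collapse over time, encoding rising urgency; the linear collapse
``b(t) = b0 - lambda * t`` is the parametric family supported out of the
box, and arbitrary ``b(t)`` can be supplied as a custom spec.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

__all__ = [
    "ThresholdSpec",
    "HSDMParameters",
    "kappa",
    "spherical_to_cartesian",
    "cartesian_to_spherical",
    "validate_angles",
    "sphere_surface_area",
    "params_from_config",
    "params_to_config",
]


# ---------------------------------------------------------------------------
# thresholds
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ThresholdSpec:
    """A (possibly time-dependent) decision threshold radius ``b(t)``.

    The integral-equation solver works on the squared process
    ``Y = R**2``, so the spec also exposes the squared boundary
    ``S(t) = b(t)**2`` and its time derivative.  For custom thresholds the
    user supplies ``b`` and ``db/dt`` only; ``S`` and ``dS/dt`` are derived
    internally (``dS/dt = 2 b db/dt``) so the two can never disagree.

    ``t_singular`` is the first time at which the boundary reaches zero
    (``b0/lambda`` for a linear collapse, ``inf`` for a constant
    threshold).  Solver grids must stay strictly below it: the Volterra
    kernel is undefined at ``b = 0`` and decisions near the singular point
    degenerate into fast guesses.
    """

    kind: str
    params: dict = field(default_factory=dict)
    _b: Callable[[np.ndarray], np.ndarray] | None = None
    _dbdt: Callable[[np.ndarray], np.ndarray] | None = None
    t_singular: float = math.inf

    # -- constructors -------------------------------------------------

    @staticmethod
    def constant(b: float) -> "ThresholdSpec":
        if b <= 0:
            raise ValueError(f"constant threshold must be positive, got b={b}")
        return ThresholdSpec(kind="constant", params={"b": float(b)})

    @staticmethod
    def linear(b0: float, lam: float) -> "ThresholdSpec":
        """Linearly collapsing threshold ``b(t) = b0 - lam * t``."""
        if b0 <= 0:
            raise ValueError(f"initial threshold must be positive, got b0={b0}")
        if lam <= 0:
            raise ValueError(
                f"collapse slope must be positive (use constant() for lam=0), got {lam}"
            )
        return ThresholdSpec(
            kind="linear",
            params={"b0": float(b0), "lambda": float(lam)},
            t_singular=float(b0) / float(lam),
        )

    @staticmethod
    def custom(
        b: Callable[[np.ndarray], np.ndarray],
        dbdt: Callable[[np.ndarray], np.ndarray],
        t_singular: float = math.inf,
    ) -> "ThresholdSpec":
        """Arbitrary boundary from user-supplied ``b(t)`` and ``db/dt``."""
        return ThresholdSpec(kind="custom", _b=b, _dbdt=dbdt,
                             t_singular=float(t_singular))

    # -- evaluation ---------------------------------------------------

    def b(self, t):
        """Boundary radius at time ``t`` (clamped at zero past collapse)."""
        t = np.asarray(t, dtype=float)
        if self.kind == "constant":
            out = np.broadcast_to(self.params["b"], t.shape).copy()
        elif self.kind == "linear":
            out = np.maximum(self.params["b0"] - self.params["lambda"] * t, 0.0)
        else:
            out = np.asarray(self._b(t), dtype=float)
        return out if out.ndim else float(out)

    def dbdt(self, t):
        t = np.asarray(t, dtype=float)
        if self.kind == "constant":
            out = np.zeros(t.shape)
        elif self.kind == "linear":
            out = np.where(t < self.t_singular, -self.params["lambda"], 0.0)
        else:
            out = np.asarray(self._dbdt(t), dtype=float)
        return out if out.ndim else float(out)

    def S(self, t):
        b = np.asarray(self.b(t))
        out = b * b
        return out if out.ndim else float(out)

    def dSdt(self, t):
        out = 2.0 * np.asarray(self.b(t)) * np.asarray(self.dbdt(t))
        return out if out.ndim else float(out)

    def rescaled(self, sigma: float) -> "ThresholdSpec":
        """Threshold of the unit-diffusion model, ``b(t)/sigma``."""
        if sigma == 1.0:
            return self
        if self.kind == "constant":
            return ThresholdSpec.constant(self.params["b"] / sigma)
        if self.kind == "linear":
            return ThresholdSpec.linear(self.params["b0"] / sigma,
                                        self.params["lambda"] / sigma)
        b, db = self._b, self._dbdt
        return ThresholdSpec.custom(lambda t: np.asarray(b(t)) / sigma,
                                    lambda t: np.asarray(db(t)) / sigma,
                                    self.t_singular)


# ---------------------------------------------------------------------------
# parameters
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HSDMParameters:
    """Full parameter vector of one HSDM instance.

    Parameters
    ----------
    n
        Dimension of the accumulation space (>= 2).
    mu
        Drift vector of length ``n`` (evidence units per second).
    t0
        Non-decision time in seconds (encoding + motor latency).
    threshold
        Decision boundary spec; must be positive at t=0.
    sigma
        Diffusion coefficient.  All internal solvers assume ``sigma = 1``
        (the conventional identification constraint); other values are
        handled exactly by the rescaling ``X -> X/sigma``, ``mu -> mu/sigma``,
        ``b -> b/sigma`` applied once on entry via :meth:`rescaled`.
    """

    n: int
    mu: np.ndarray
    t0: float
    threshold: ThresholdSpec
    sigma: float = 1.0

    def __post_init__(self):
        object.__setattr__(self, "mu", np.asarray(self.mu, dtype=float))
        if self.n < 2:
            raise ValueError(f"dimension must be >= 2, got n={self.n}")
        if self.mu.shape != (self.n,):
            raise ValueError(
                f"drift vector must have length n={self.n}, got shape {self.mu.shape}"
            )
        if self.t0 < 0:
            raise ValueError(f"non-decision time must be >= 0, got {self.t0}")
        if self.sigma <= 0:
            raise ValueError(f"diffusion coefficient must be > 0, got {self.sigma}")
        if np.asarray(self.threshold.b(0.0)) <= 0:
            raise ValueError("threshold must be positive at t=0")

    @property
    def drift_norm(self) -> float:
        return float(np.linalg.norm(self.mu))

    def rescaled(self) -> "HSDMParameters":
        """Equivalent model with unit diffusion coefficient."""
        if self.sigma == 1.0:
            return self
        return HSDMParameters(
            n=self.n,
            mu=self.mu / self.sigma,
            t0=self.t0,
            threshold=self.threshold.rescaled(self.sigma),
            sigma=1.0,
        )


def kappa(params: HSDMParameters) -> float:
    """Precision index ``kappa = b * ||mu|| / sigma**2``.

    The product of stimulus quality (drift length) and response caution
    (threshold radius).  Only defined for a constant threshold.
    """
    if params.threshold.kind != "constant":
        raise ValueError(
            "kappa is undefined for time-dependent thresholds "
            f"(threshold kind: {params.threshold.kind!r})"
        )
    return params.threshold.params["b"] * params.drift_norm / params.sigma**2


# ---------------------------------------------------------------------------
# coordinates
# ---------------------------------------------------------------------------
#
# Angle convention: phi_1 .. phi_{n-2} in [0, pi], phi_{n-1} in [0, 2*pi);
# for n=2 the single angle lies in [0, 2*pi).  Data files store radians.

def validate_angles(phi: np.ndarray, n: int | None = None) -> np.ndarray:
    """Check angle ranges; returns phi as a float array (rows = trials)."""
    phi = np.atleast_2d(np.asarray(phi, dtype=float))
    if n is not None and phi.shape[-1] != n - 1:
        raise ValueError(
            f"expected {n - 1} angles for dimension n={n}, got {phi.shape[-1]}"
        )
    if phi.shape[-1] > 1:
        inner = phi[..., :-1]
        if np.any(inner < 0) or np.any(inner > np.pi):
            raise ValueError("polar angles phi_1..phi_{n-2} must lie in [0, pi]")
    last = phi[..., -1]
    if np.any(last < 0) or np.any(last >= 2 * np.pi):
        raise ValueError("azimuthal angle phi_{n-1} must lie in [0, 2*pi)")
    return phi


def spherical_to_cartesian(radius, phi) -> np.ndarray:
    """Hitting point on the boundary sphere from its n-1 hyper-spherical angles.

    ``X_1 = r cos(phi_1)``, ``X_k = r sin(phi_1)...sin(phi_{k-1}) cos(phi_k)``,
    ..., ``X_n = r sin(phi_1)...sin(phi_{n-1})``.  Accepts a single angle
    vector or a batch (rows); ``radius`` broadcasts accordingly.
    """
    phi = np.asarray(phi, dtype=float)
    single = phi.ndim == 1
    phi = np.atleast_2d(phi)
    radius = np.broadcast_to(np.asarray(radius, dtype=float), (phi.shape[0],))
    if np.any(radius <= 0):
        raise ValueError("boundary radius must be positive")
    m, k = phi.shape
    n = k + 1
    x = np.empty((m, n))
    sin_prod = np.ones(m)
    for i in range(k):
        x[:, i] = sin_prod * np.cos(phi[:, i])
        sin_prod = sin_prod * np.sin(phi[:, i])
    x[:, n - 1] = sin_prod
    x *= radius[:, None]
    return x[0] if single else x


def cartesian_to_spherical(x) -> tuple[np.ndarray, np.ndarray]:
    """Inverse of :func:`spherical_to_cartesian`: (radius, angles).

    Polar angles are recovered with atan2 against the norm of the
    remaining tail coordinates (range [0, pi]); the final azimuth uses
    atan2 of the last two coordinates mapped to [0, 2*pi).
    """
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    x = np.atleast_2d(x)
    m, n = x.shape
    r = np.linalg.norm(x, axis=1)
    if np.any(r == 0):
        raise ValueError("cannot assign angles to the zero vector")
    phi = np.empty((m, n - 1))
    # tail norms: ||x_{i+1:}|| for the polar angles
    tail = np.sqrt(np.cumsum(x[:, ::-1] ** 2, axis=1))[:, ::-1]
    for i in range(n - 2):
        phi[:, i] = np.arctan2(tail[:, i + 1], x[:, i])
    phi[:, n - 2] = np.mod(np.arctan2(x[:, n - 1], x[:, n - 2]), 2 * np.pi)
    if single:
        return float(r[0]), phi[0]
    return r, phi


def sphere_surface_area(n: int) -> float:
    """Surface area of the unit (n-1)-sphere, ``2 pi^{n/2} / Gamma(n/2)``."""
    return 2.0 * math.pi ** (n / 2.0) / math.gamma(n / 2.0)


# ---------------------------------------------------------------------------
# JSON config plumbing
# ---------------------------------------------------------------------------

_THRESHOLD_KEYS = {"constant": {"kind", "b"}, "linear": {"kind", "b0", "lambda"}}


def _threshold_from_config(cfg: dict) -> ThresholdSpec:
    kind = cfg.get("kind")
    if kind not in _THRESHOLD_KEYS:
        raise ValueError(f"unknown threshold kind: {kind!r}")
    unknown = set(cfg) - _THRESHOLD_KEYS[kind]
    if unknown:
        raise ValueError(f"unknown threshold config keys: {sorted(unknown)}")
    if kind == "constant":
        return ThresholdSpec.constant(cfg["b"])
    return ThresholdSpec.linear(cfg["b0"], cfg["lambda"])


def params_from_config(cfg: dict) -> HSDMParameters:
    """Build parameters from the JSON model-config schema.

    Schema: ``{"n": int, "mu": [...], "sigma": float, "t0": float,
    "threshold": {"kind": "constant", "b": ...} |
    {"kind": "linear", "b0": ..., "lambda": ...}}``.
    Unknown keys are rejected.
    """
    allowed = {"n", "mu", "sigma", "t0", "threshold"}
    unknown = set(cfg) - allowed
    if unknown:
        raise ValueError(f"unknown model config keys: {sorted(unknown)}")
    missing = {"n", "mu", "t0", "threshold"} - set(cfg)
    if missing:
        raise ValueError(f"missing model config keys: {sorted(missing)}")
    return HSDMParameters(
        n=int(cfg["n"]),
        mu=np.asarray(cfg["mu"], dtype=float),
        sigma=float(cfg.get("sigma", 1.0)),
        t0=float(cfg["t0"]),
        threshold=_threshold_from_config(cfg["threshold"]),
    )


def params_to_config(params: HSDMParameters) -> dict:
    thr = params.threshold
    if thr.kind not in _THRESHOLD_KEYS:
        raise ValueError("only constant/linear thresholds have a config form")
    tcfg = {"kind": thr.kind, **thr.params}
    return {
        "n": params.n,
        "mu": [float(m) for m in params.mu],
        "sigma": params.sigma,
        "t0": params.t0,
        "threshold": tcfg,
    }
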