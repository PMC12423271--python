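"""Bessel-series first-passage distributions for constant thresholds.

The radial part of a zero-drift n-dimensional Wiener process is a Bessel
process; its first-passage time through a constant radius ``b`` has a
classical eigenfunction expansion in the positive zeros of the Bessel
function ``J_nu`` with ``nu = (n-2)/2``.  The truncated series is exact in
the large-T limit but is numerically fragile at short T (slowly decaying,
sign-alternating terms), where it can return oscillating and even negative
"densities".  This module keeps those artifacts on purpose — it serves as
the independent analytic oracle for the integral-equation solver and as a
diagnostic of the series' own instability region.  The likelihood code
never evaluates densities through this path.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.optimize import brentq
from scipy.special import gamma as _gamma
from scipy.special import jn_zeros, jv

__all__ = [
    "BesselSeriesTable",
    "bessel_zeros",
    "series_fpt_cdf",
    "series_fpt_density",
    "series_terms",
]

DEFAULT_K_TERMS = 500
_ROOT_XTOL = 1e-12


def bessel_zeros(nu: float, k_terms: int) -> np.ndarray:
    """First ``k_terms`` positive zeros of ``J_nu``, any real order nu >= 0.

    Integer orders go through scipy's tabulated routine; fractional orders
    (odd dimensions, e.g. nu=1/2 for n=3) are bracketed from the McMahon
    asymptotic guess and polished by Brent root-finding.
    """
    if k_terms < 1:
        raise ValueError("k_terms must be >= 1")
    if nu < 0:
        raise ValueError(f"order must be nonnegative, got nu={nu}")
    if float(nu).is_integer():
        return jn_zeros(int(nu), k_terms)
    mu4 = 4.0 * nu * nu
    zeros = np.empty(k_terms)
    for k in range(1, k_terms + 1):
        beta = (k + nu / 2.0 - 0.25) * np.pi
        guess = beta - (mu4 - 1.0) / (8.0 * beta)
        lo, hi = guess - 1.2, guess + 1.2
        while jv(nu, lo) * jv(nu, hi) > 0:  # widen until the sign flips
            lo -= 0.2
            hi += 0.2
        zeros[k - 1] = brentq(lambda z: jv(nu, z), lo, hi, xtol=_ROOT_XTOL)
    return zeros


@dataclass(frozen=True)
class BesselSeriesTable:
    """Cached roots ``j_{nu,k}`` and denominators ``J_{nu+1}(j_{nu,k})``."""

    nu: float
    roots: np.ndarray
    denom: np.ndarray

    @property
    def k_terms(self) -> int:
        return len(self.roots)


@lru_cache(maxsize=32)
def _table(nu: float, k_terms: int) -> BesselSeriesTable:
    roots = bessel_zeros(nu, k_terms)
    return BesselSeriesTable(nu=nu, roots=roots, denom=jv(nu + 1.0, roots))


def _check(b: float, n: int) -> float:
    if n < 2:
        raise ValueError(f"dimension must be >= 2, got n={n}")
    if b <= 0:
        raise ValueError(f"threshold must be positive, got b={b}")
    return (n - 2) / 2.0


def series_fpt_cdf(T, b: float, sigma: float = 1.0, n: int = 2,
                   k_terms: int = DEFAULT_K_TERMS):
    """P(first passage <= T) for the zero-drift process, constant threshold.

    ``G(T) = 1 - 1/(2^{nu-1} Gamma(nu+1)) * sum_k j_{nu,k}^{nu-1} /
    J_{nu+1}(j_{nu,k}) * exp(-j_{nu,k}^2 sigma^2 T / (2 b^2))``.

    Truncation can push values slightly outside [0, 1] at very small T.
    """
    nu = _check(b, n)
    tab = _table(nu, k_terms)
    T = np.asarray(T, dtype=float)
    scalar = T.ndim == 0
    T = np.atleast_1d(T)
    if np.any(T < 0):
        raise ValueError("decision time must be >= 0")
    coeff = tab.roots ** (nu - 1.0) / tab.denom
    decay = np.exp(-0.5 * np.outer(T, tab.roots**2) * sigma**2 / b**2)
    out = 1.0 - decay @ coeff / (2.0 ** (nu - 1.0) * _gamma(nu + 1.0))
    return float(out[0]) if scalar else out


def series_fpt_density(T, b: float, sigma: float = 1.0, n: int = 2,
                       k_terms: int = DEFAULT_K_TERMS):
    """First-passage density dG/dT of the zero-drift process.

    ``g(T) = sigma^2 / (2^nu b^2 Gamma(nu+1)) * sum_k j_{nu,k}^{nu+1} /
    J_{nu+1}(j_{nu,k}) * exp(-j_{nu,k}^2 sigma^2 T / (2 b^2))``.

    Truncation artifacts at short T (oscillations, negative values) are
    returned untouched so callers can detect the instability region.
    """
    nu = _check(b, n)
    tab = _table(nu, k_terms)
    T = np.asarray(T, dtype=float)
    scalar = T.ndim == 0
    T = np.atleast_1d(T)
    if np.any(T <= 0):
        raise ValueError("decision time must be > 0")
    coeff = tab.roots ** (nu + 1.0) / tab.denom
    decay = np.exp(-0.5 * np.outer(T, tab.roots**2) * sigma**2 / b**2)
    out = decay @ coeff * sigma**2 / (2.0**nu * b**2 * _gamma(nu + 1.0))
    return float(out[0]) if scalar else out


def series_terms(T: float, b: float, sigma: float = 1.0, n: int = 2,
                 k_terms: int = DEFAULT_K_TERMS) -> np.ndarray:
    """Individual (signed) terms of the density series at one time point.

    Exposed for convergence diagnostics: term magnitudes decay much more
    slowly at short T, which is the root of the series' instability.
    """
    nu = _check(b, n)
    tab = _table(nu, k_terms)
    if T <= 0:
        raise ValueError("decision time must be > 0")
    return (
        sigma**2 / (2.0**nu * b**2 * _gamma(nu + 1.0))
        * tab.roots ** (nu + 1.0) / tab.denom
        * np.exp(-0.5 * tab.roots**2 * sigma**2 * T / b**2)
    )
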