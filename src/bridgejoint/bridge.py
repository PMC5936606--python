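"""The Bridge distribution for logit-link random intercepts.

The Bridge distribution is the random-effect law with the property that a
cluster-specific intercept ``u`` added to a logistic linear predictor
integrates out to *another* logistic model, with every coefficient attenuated
by the scale parameter ``phi``:

    integral expit(u + eta) f(u; phi) du  =  expit(phi * eta)

so the exponentiated coefficients keep the same odds-ratio interpretation
within and between clusters.  The density used here is

    f(u; phi) = (1 / 2 pi) * sin(phi pi) / (cosh(phi u) + cos(phi pi)),

with ``phi`` in the open interval (0, 1); ``phi -> 1`` degenerates to a point
mass at zero and small ``phi`` gives heavy between-cluster heterogeneity.
The variance is ``(pi^2 / 3) (phi^-2 - 1)`` and the quantile function has the
closed form ``Q(p) = (1/phi) log[ sin(phi pi p) / sin(phi pi (1-p)) ]``.

A correlated bivariate version is built by coupling two Bridge margins
through a Gaussian copula with correlation ``rho``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit, ndtr

__all__ = [
    "BridgeParams",
    "BivariateBridgeParams",
    "bridge_pdf",
    "bridge_logpdf",
    "bridge_cdf",
    "bridge_cdf_bisect",
    "bridge_icdf",
    "bridge_icdf_normal",
    "bridge_variance",
    "sample_bridge",
    "sample_bivariate_bridge",
    "marginalize_logit",
]


def _check_phi(phi: float) -> float:
    phi = float(phi)
    if not 0.0 < phi < 1.0:
        raise ValueError(f"Bridge scale phi must lie strictly in (0, 1); got {phi}")
    return phi


@dataclass(frozen=True)
class BridgeParams:
    """Scale parameter of a univariate Bridge distribution."""

    phi: float

    def __post_init__(self) -> None:
        _check_phi(self.phi)

    @property
    def variance(self) -> float:
        return bridge_variance(self.phi)


@dataclass(frozen=True)
class BivariateBridgeParams:
    """Two Bridge margins coupled by a Gaussian copula.

    ``rho`` is the correlation of the underlying bivariate normal; ``rho = 0``
    gives independent margins.
    """

    phi1: float
    phi2: float
    rho: float

    def __post_init__(self) -> None:
        _check_phi(self.phi1)
        _check_phi(self.phi2)
        if not -1.0 < self.rho < 1.0:
            raise ValueError(f"copula correlation rho must lie in (-1, 1); got {self.rho}")


def bridge_logpdf(u, phi: float):
    """Log-density of the Bridge distribution.

    ``cosh(phi u) + cos(phi pi)`` is rewritten as
    ``2 sinh^2(phi u / 2) + 2 sin^2((1 - phi) pi / 2)`` which stays accurate
    as ``phi -> 1`` where both terms vanish.
    """
    phi = _check_phi(phi)
    u = np.asarray(u, dtype=float)
    eps = 1.0 - phi
    x = 0.5 * phi * np.abs(u)
    xs = np.minimum(x, 300.0)  # 2 sinh(x)^2 ~ e^{2x}/2 beyond this anyway
    denom_log = np.where(
        x > 300.0,
        2.0 * x - np.log(2.0),
        np.log(2.0 * np.sinh(xs) ** 2 + 2.0 * np.sin(0.5 * eps * np.pi) ** 2))
    return np.log(np.sin(eps * np.pi)) - np.log(2.0 * np.pi) - denom_log


def bridge_pdf(u, phi: float):
    """Density ``f(u; phi)``; symmetric about zero, integrates to one."""
    return np.exp(bridge_logpdf(u, phi))


def bridge_icdf(p, phi: float):
    """Quantile function ``Q(p; phi)`` for ``p`` strictly inside (0, 1)."""
    phi = _check_phi(phi)
    p = np.asarray(p, dtype=float)
    if np.any(p <= 0.0) or np.any(p >= 1.0):
        raise ValueError("probabilities must lie strictly in (0, 1)")
    return (np.log(np.sin(phi * np.pi * p)) - np.log(np.sin(phi * np.pi * (1.0 - p)))) / phi


def bridge_icdf_normal(z, phi: float):
    """Bridge quantile evaluated at ``p = Phi(z)`` for standard-normal ``z``.

    Uses ``ndtr(-z)`` for the upper tail so that the transform stays finite
    for |z| far beyond where ``1 - ndtr(z)`` underflows — this is the map the
    Gaussian copula and the quadrature rules go through.
    """
    phi = _check_phi(phi)
    z = np.asarray(z, dtype=float)
    p = np.maximum(ndtr(z), 1e-300)
    q = np.maximum(ndtr(-z), 1e-300)
    return (np.log(np.sin(phi * np.pi * p)) - np.log(np.sin(phi * np.pi * q))) / phi


def bridge_cdf(u, phi: float):
    """CDF of the Bridge distribution.

    Closed form obtained by integrating the density:

        F(u) = 1 - 1/(2 phi) + (1/(pi phi)) arctan[(e^{phi u} + cos(phi pi)) / sin(phi pi)]

    (differentiating recovers ``bridge_pdf`` exactly; the quantile round trip
    ``F(Q(p)) = p`` is exercised in the test suite).
    """
    phi = _check_phi(phi)
    u = np.asarray(u, dtype=float)
    expu = np.exp(np.minimum(phi * u, 700.0))
    val = (1.0 - 0.5 / phi
           + np.arctan((expu + np.cos(phi * np.pi)) / np.sin(phi * np.pi))
           / (np.pi * phi))
    return np.clip(val, 0.0, 1.0)


def bridge_cdf_bisect(u, phi: float, tol: float = 1e-10):
    """CDF by vectorised bisection on the closed-form quantile.

    Independent of :func:`bridge_cdf`; used as its cross-check.  Solves
    ``Q(p) = u`` for ``p`` to absolute tolerance ``tol``.
    """
    phi = _check_phi(phi)
    u = np.asarray(u, dtype=float)
    lo = np.full(u.shape, 1e-300)
    hi = np.full(u.shape, 1.0 - 1e-16)
    # 60 bisection steps shrink the bracket below 1e-18 < tol
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        too_low = bridge_icdf(mid, phi) < u
        lo = np.where(too_low, mid, lo)
        hi = np.where(too_low, hi, mid)
    return 0.5 * (lo + hi)


def bridge_variance(phi: float) -> float:
    """Variance ``(pi^2 / 3)(phi^-2 - 1)``; decreasing in phi, 0 at phi=1."""
    phi = _check_phi(phi)
    return (np.pi**2 / 3.0) * (phi**-2 - 1.0)


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def sample_bridge(n: int, phi: float, seed=None) -> np.ndarray:
    """Draw ``n`` Bridge variates by inverse-CDF transform of uniforms."""
    if n < 1:
        raise ValueError(f"sample size must be >= 1; got {n}")
    rng = _as_rng(seed)
    # inverse-transform through the normal keeps one shared path with the
    # copula sampler, so the univariate margins match exactly at rho = 0
    z = rng.standard_normal(int(n))
    return bridge_icdf_normal(z, phi)


def sample_bivariate_bridge(n: int, params: BivariateBridgeParams, seed=None) -> np.ndarray:
    """Draw ``n`` pairs from the Gaussian-copula bivariate Bridge.

    Returns an array of shape ``(n, 2)``.  Each margin is exactly
    Bridge(phi_k); the dependence comes from a correlated bivariate normal
    pushed through the normal CDF and the Bridge quantile.
    """
    if n < 1:
        raise ValueError(f"sample size must be >= 1; got {n}")
    rng = _as_rng(seed)
    z = rng.standard_normal((int(n), 2))
    z2 = params.rho * z[:, 0] + np.sqrt(1.0 - params.rho**2) * z[:, 1]
    u1 = bridge_icdf_normal(z[:, 0], params.phi1)
    u2 = bridge_icdf_normal(z2, params.phi2)
    return np.column_stack([u1, u2])


def marginalize_logit(eta, phi: float):
    """Population-averaged success probability ``expit(phi * eta)``.

    This is the defining identity of the Bridge family: the integral of
    ``expit(u + eta)`` against ``f(u; phi)`` collapses to a logistic function
    of the attenuated predictor.
    """
    phi = _check_phi(phi)
    return expit(phi * np.asarray(eta, dtype=float))
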