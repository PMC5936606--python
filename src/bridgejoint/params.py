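"""Parameter container for the joint two-outcome multilevel logit model.

The model has, for each outcome, two non-reference categories ``c`` with a
threshold (intercept) and a slope vector, plus the random-intercept law:
Bridge scales ``phi1, phi2`` and the Gaussian-copula correlation ``rho``.

The optimizer works on an unconstrained flat vector: slopes and thresholds
are untransformed, ``phi = expit(a)`` and ``rho = tanh(r)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import expit, logit

from .bridge import BivariateBridgeParams

__all__ = ["ParameterVector"]


@dataclass
class ParameterVector:
    omega: np.ndarray  # (2,) thresholds, outcome 1 non-reference categories
    alpha: np.ndarray  # (2, p1) slopes, outcome 1
    theta: np.ndarray  # (2,) thresholds, outcome 2
    beta: np.ndarray   # (2, p2) slopes, outcome 2
    phi1: float = 0.9
    phi2: float = 0.9
    rho: float = 0.0
    names1: list = field(default_factory=list)
    names2: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.omega = np.atleast_1d(np.asarray(self.omega, dtype=float))
        self.theta = np.atleast_1d(np.asarray(self.theta, dtype=float))
        self.alpha = np.asarray(self.alpha, dtype=float).reshape(2, -1)
        self.beta = np.asarray(self.beta, dtype=float).reshape(2, -1)
        if self.omega.shape != (2,) or self.theta.shape != (2,):
            raise ValueError("each outcome must have exactly two non-reference thresholds")
        BivariateBridgeParams(self.phi1, self.phi2, self.rho)  # validates

    @property
    def p1(self) -> int:
        return self.alpha.shape[1]

    @property
    def p2(self) -> int:
        return self.beta.shape[1]

    @property
    def bridge(self) -> BivariateBridgeParams:
        return BivariateBridgeParams(self.phi1, self.phi2, self.rho)

    # -- flat (unconstrained) packing used by the optimizer -----------------
    def to_unconstrained(self) -> np.ndarray:
        return np.concatenate([
            self.omega,
            self.alpha.ravel(),
            self.theta,
            self.beta.ravel(),
            [logit(self.phi1), logit(self.phi2), np.arctanh(self.rho)],
        ])

    @classmethod
    def from_unconstrained(cls, x: np.ndarray, p1: int, p2: int,
                           names1=None, names2=None) -> "ParameterVector":
        x = np.asarray(x, dtype=float)
        k = 2 + 2 * p1 + 2 + 2 * p2 + 3
        if x.size != k:
            raise ValueError(f"flat parameter vector has length {x.size}, expected {k}")
        i = 0
        omega = x[i:i + 2]; i += 2
        alpha = x[i:i + 2 * p1].reshape(2, p1); i += 2 * p1
        theta = x[i:i + 2]; i += 2
        beta = x[i:i + 2 * p2].reshape(2, p2); i += 2 * p2
        # clamp away from the boundary: expit/tanh saturate in floating point
        # while the optimizer explores the unconstrained scale
        phi1 = float(np.clip(expit(x[i]), 1e-9, 1.0 - 1e-9))
        phi2 = float(np.clip(expit(x[i + 1]), 1e-9, 1.0 - 1e-9))
        rho = float(np.clip(np.tanh(x[i + 2]), -1.0 + 1e-9, 1.0 - 1e-9))
        return cls(omega, alpha, theta, beta, phi1, phi2, rho,
                   names1=list(names1 or []), names2=list(names2 or []))

    def copy(self, **changes) -> "ParameterVector":
        out = replace(self)
        out.omega = self.omega.copy(); out.alpha = self.alpha.copy()
        out.theta = self.theta.copy(); out.beta = self.beta.copy()
        for key, val in changes.items():
            setattr(out, key, val)
        return out

    def swapped(self) -> "ParameterVector":
        """The same model with the two outcomes exchanged."""
        return ParameterVector(self.theta, self.beta, self.omega, self.alpha,
                               self.phi2, self.phi1, self.rho,
                               names1=self.names2, names2=self.names1)
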