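"""Thermal enhancement ratio and its modulation of the LQ parameters.

The thermal enhancement ratio (TER) quantifies hyperthermic
radiosensitisation as the ratio of radiation doses producing the same
survival endpoint with radiation alone versus combined with heat.  Modelling
the heat-driven advance through sublethal-damage states as a single
rate-limited process with denaturation kinetics k(T) = c*exp(b*(T-Tg)) gives

    TER(t, T) = o + a' * t * exp(b*(T - Tg)),

with onset o (=1 in the absence of hyperthermia), scale a' = a*c (per
minute), temperature coefficient b (1/K) and melting temperature Tg.  The
TER rescales the linear-quadratic coefficients as alpha* = alpha*TER and
beta* = beta*TER^2, so the alpha/beta ratio is divided by TER.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import InvalidInputError
from .thermo_core import RateParams

__all__ = [
    "TERParams",
    "LQParams",
    "ter",
    "modulate_lq",
    "ter_from_alpha",
    "ter_from_beta",
    "alpha_beta_ratio",
]


@dataclass(frozen=True)
class TERParams:
    """Parameters of the TER law TER = o + a'*t*exp(b*(T-Tg)).

    ``a_prime`` and ``Tg`` are jointly unidentifiable (only a'*exp(-b*Tg)
    enters); the fitting convention fixes a' = 1 and lets Tg float.  ``Tg``
    is stored in degrees Celsius by package convention; only T - Tg matters.
    """

    a_prime: float
    b: float
    Tg: float
    o: float = 1.0

    def __post_init__(self) -> None:
        if not (self.o >= 0):
            raise InvalidInputError(f"onset o must be non-negative, got {self.o}")
        if not (self.a_prime > 0):
            raise InvalidInputError(f"a_prime must be positive, got {self.a_prime}")
        if not (self.b > 0):
            raise InvalidInputError(f"b must be positive, got {self.b}")
        if not math.isfinite(self.Tg):
            raise InvalidInputError("Tg must be finite")

    @property
    def rate_params(self) -> RateParams:
        """The (c, b, Tg) rate triple with c = a' (per-minute convention)."""
        return RateParams(c=self.a_prime, b=self.b, Tg=self.Tg)


@dataclass(frozen=True)
class LQParams:
    """Linear-quadratic radiosensitivity: -ln S = alpha*D + beta*D^2.

    alpha in 1/Gy (single-hit kill), beta in 1/Gy^2 (sublethal-damage
    accumulation).
    """

    alpha: float
    beta: float

    def __post_init__(self) -> None:
        if self.alpha < 0 or self.beta < 0:
            raise InvalidInputError(
                f"alpha and beta must be non-negative, got ({self.alpha}, {self.beta})"
            )
        if self.alpha == 0 and self.beta == 0:
            raise InvalidInputError("alpha and beta cannot both be zero")

    @property
    def ratio(self) -> float:
        """The alpha/beta ratio (Gy)."""
        if self.beta == 0:
            raise InvalidInputError("alpha/beta undefined for beta = 0")
        return self.alpha / self.beta


def ter(t, T, p: TERParams):
    """Thermal enhancement ratio after heating for ``t`` minutes at ``T``.

    Strictly increasing in both t and T; equals the onset ``p.o`` at t = 0.
    ``T`` must be on the same scale as ``p.Tg`` (Celsius by convention).
    """
    t = np.asarray(t, dtype=float)
    T = np.asarray(T, dtype=float)
    if np.any(t < 0):
        raise InvalidInputError("heating time must be non-negative")
    if not (np.all(np.isfinite(t)) and np.all(np.isfinite(T))):
        raise InvalidInputError("inputs must be finite")
    out = p.o + p.a_prime * t * np.exp(p.b * (T - p.Tg))
    return float(out) if out.ndim == 0 else out


def modulate_lq(p: LQParams, ter_value: float) -> LQParams:
    """Rescale LQ coefficients by a TER: (alpha, beta) -> (alpha*TER, beta*TER^2)."""
    if not (ter_value >= 0):
        raise InvalidInputError(f"TER must be non-negative, got {ter_value}")
    return LQParams(alpha=p.alpha * ter_value, beta=p.beta * ter_value**2)


def ter_from_alpha(alpha_T, alpha0: float):
    """TER_alpha = alpha(T)/alpha0 from the heated and baseline linear coefficients."""
    if not (alpha0 > 0):
        raise InvalidInputError(f"baseline alpha must be positive, got {alpha0}")
    alpha_T = np.asarray(alpha_T, dtype=float)
    if np.any(alpha_T < 0):
        raise InvalidInputError("alpha(T) must be non-negative")
    out = alpha_T / alpha0
    return float(out) if out.ndim == 0 else out


def ter_from_beta(beta_T, beta0: float):
    """TER_beta = sqrt(beta(T)/beta0) from the heated and baseline quadratic coefficients."""
    if not (beta0 > 0):
        raise InvalidInputError(f"baseline beta must be positive, got {beta0}")
    beta_T = np.asarray(beta_T, dtype=float)
    if np.any(beta_T < 0):
        raise InvalidInputError("beta(T) must be non-negative")
    out = np.sqrt(beta_T / beta0)
    return float(out) if out.ndim == 0 else out


def alpha_beta_ratio(p: LQParams, ter_value: float) -> float:
    """Modulated alpha*/beta* ratio = (alpha/beta)/TER; decreasing in TER."""
    if not (ter_value > 0):
        raise InvalidInputError(f"TER must be positive, got {ter_value}")
    if p.beta == 0:
        raise InvalidInputError("alpha/beta undefined for beta = 0")
    return (p.alpha / p.beta) / ter_value
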