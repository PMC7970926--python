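"""Thermodynamic kernel for the sensitisation reaction.

Protein denaturation is treated as an activated process whose rate follows
Eyring transition-state theory,

    k(T) = (kB/hp) * T * exp(-dG(T) / (kB*T)),

with a Gibbs free-energy change dG(T) built from a heat capacity that varies
linearly around the melting temperature Tg:

    Cp(T) = A - B*|T - Tg|.

Integrating Cp with the melting-point reference dG(Tg) = dG0 gives a closed
form for dG(T); a numerical-quadrature route is kept alongside as an
independent check.  Near Tg the full rate is dominated by the exponential in
(T - Tg), which motivates the operational approximation

    k(T) ~= c * exp(b*(T - Tg))

used throughout the thermal-enhancement layer.  There, the prefactor ``c``
is an empirical per-minute constant (hyperthermia sessions last minutes to
hours); the 1/s Eyring prefactor is never propagated upward.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.integrate import quad

from .constants import CELSIUS_OFFSET, H_P, K_B
from .errors import InvalidInputError, NumericsError
from .units import to_kelvin

logger = logging.getLogger(__name__)

# exp() argument beyond which we refuse to evaluate rather than overflow
_EXP_OVERFLOW = 700.0


@dataclass(frozen=True)
class GibbsParams:
    """Thermodynamic parameters of the denaturation free energy.

    Attributes
    ----------
    A : float
        Heat-capacity value at the melting temperature, J/K.
    B : float
        Heat-capacity slope, J/K^2.
    Tg : float
        Melting temperature, K (temperature at which half the effective
        protein population is denatured; dG(Tg) = deltaG0).
    deltaG0 : float
        Reference Gibbs energy at Tg, J.  Default 0 per the melting-point
        convention dG(Tg) = 0.
    """

    A: float
    B: float
    Tg: float
    deltaG0: float = 0.0

    def __post_init__(self) -> None:
        if not (self.Tg > 0 and math.isfinite(self.Tg)):
            raise InvalidInputError(f"Tg must be positive and finite, got {self.Tg}")
        if self.A < 0:
            raise InvalidInputError(f"A must be non-negative, got {self.A}")
        if self.B < 0:
            raise InvalidInputError(f"B must be non-negative, got {self.B}")


@dataclass(frozen=True)
class RateParams:
    """Parameters of the approximate sensitisation rate k(T) = c*exp(b*(T-Tg)).

    Attributes
    ----------
    c : float
        Rate prefactor, 1/min (empirical, per-minute convention).
    b : float
        Exponential temperature coefficient, 1/K.
    Tg : float
        Reference (melting) temperature.  Stored in degrees Celsius by
        package convention; the rate depends only on T - Tg, so any scale
        works as long as callers pass T on the same scale.
    """

    c: float
    b: float
    Tg: float

    def __post_init__(self) -> None:
        if not (self.c > 0):
            raise InvalidInputError(f"c must be positive, got {self.c}")
        if not (self.b > 0):
            raise InvalidInputError(f"b must be positive, got {self.b}")
        # accept Tg on either scale: 0-100 C or the equivalent Kelvin window
        if not (0.0 < self.Tg < 100.0 or 273.15 < self.Tg < 373.15):
            raise InvalidInputError(
                f"Tg={self.Tg} outside the liquid-water range on both C and K scales"
            )


def _check_temperature(T, unit: str = "K") -> float:
    TK = to_kelvin(T, unit)
    if np.any(np.asarray(TK) <= 0):
        raise InvalidInputError(f"absolute temperature must be positive, got {TK} K")
    return TK


def heat_capacity(T, p: GibbsParams, unit: str = "K"):
    """Linear heat-capacity model Cp(T) = A - B*|T - Tg| (J/K).

    Equals A + B*(T - Tg) for T <= Tg.  May go negative far from Tg; that is
    the caller's concern and a warning is logged when it happens.
    """
    TK = _check_temperature(T, unit)
    cp = p.A - p.B * np.abs(np.asarray(TK, dtype=float) - p.Tg)
    if np.any(cp < 0):
        logger.warning("heat capacity negative at T=%s K (A=%g, B=%g, Tg=%g)", TK, p.A, p.B, p.Tg)
    return float(cp) if cp.ndim == 0 else cp


def delta_g_constant_cp(T, p: GibbsParams, unit: str = "K"):
    """Constant-heat-capacity Gibbs form dGc(T) = dG0 + A*[(T-Tg) - T*ln(T/Tg)] (J)."""
    TK = np.asarray(_check_temperature(T, unit), dtype=float)
    out = p.deltaG0 + p.A * ((TK - p.Tg) - TK * np.log(TK / p.Tg))
    return float(out) if out.ndim == 0 else out


def delta_g_closed(T, p: GibbsParams, unit: str = "K"):
    """Closed-form Gibbs energy change for the linear-Cp model (J).

        dG(T) = dGc(T) - (B/2)*(T^2 - Tg^2) + B*T*Tg*ln(T/Tg)

    with dGc the constant-Cp form.  Exact antiderivative of the thermal
    content/work integrals for T <= Tg (the hyperthermia regime); continuous
    in T and equal to deltaG0 at T = Tg.
    """
    TK = np.asarray(_check_temperature(T, unit), dtype=float)
    dgc = p.deltaG0 + p.A * ((TK - p.Tg) - TK * np.log(TK / p.Tg))
    out = dgc - 0.5 * p.B * (TK**2 - p.Tg**2) + p.B * TK * p.Tg * np.log(TK / p.Tg)
    return float(out) if out.ndim == 0 else out


def delta_g_numeric(T: float, p: GibbsParams, unit: str = "K", atol: float | None = None) -> float:
    """Gibbs energy change by numerical quadrature (J); oracle for the closed form.

        dG(T) = dG0 + integral_{Tg}^{T} Cp(T') * [1 - T/T'] dT'

    with the linear Cp(T') = A - B*|T' - Tg| and the melting point as the
    reference temperature.
    """
    TK = float(_check_temperature(T, unit))
    if atol is None:
        atol = 1e-9 * (abs(p.deltaG0) + 1.0)
    if TK == p.Tg:
        return p.deltaG0

    def integrand(Tp: float) -> float:
        return (p.A - p.B * abs(Tp - p.Tg)) * (1.0 - TK / Tp)

    val, err = quad(integrand, p.Tg, TK, epsabs=atol, epsrel=1e-12, limit=200)
    if not math.isfinite(val) or err > max(atol, 1e-6 * abs(val) + atol):
        raise NumericsError(
            f"quadrature did not converge: value={val}, error estimate={err}, atol={atol}"
        )
    return p.deltaG0 + val


def eyring_rate(T, deltaG, unit: str = "K"):
    """Eyring transition-state rate k = (kB/hp)*T*exp(-dG/(kB*T)), in 1/s."""
    TK = np.asarray(_check_temperature(T, unit), dtype=float)
    exponent = -np.asarray(deltaG, dtype=float) / (K_B * TK)
    if np.any(exponent > _EXP_OVERFLOW):
        raise NumericsError(f"exp overflow in Eyring rate: exponent={np.max(exponent)}")
    out = (K_B / H_P) * TK * np.exp(exponent)
    return float(out) if out.ndim == 0 else out


def rate_full(T, p: GibbsParams, unit: str = "K"):
    """Denaturation rate with the linear-Cp correction, as printed (1/s):

        k(T) = (kB*T/hp) * exp(-dGc/(kB*T)) * exp((B/(2*kB))*(T-Tg)*(1+Tg/T))

    where dGc is the constant-Cp Gibbs form evaluated at T.  This drops a
    -(B*Tg/kB)*ln(T/Tg) term relative to the full closed-form free energy;
    see :func:`rate_full_exact` for the un-dropped variant.
    """
    TK = np.asarray(_check_temperature(T, unit), dtype=float)
    dgc = delta_g_constant_cp(TK, p)
    exponent = -np.asarray(dgc) / (K_B * TK) + (p.B / (2.0 * K_B)) * (TK - p.Tg) * (1.0 + p.Tg / TK)
    if np.any(np.asarray(exponent) > _EXP_OVERFLOW):
        raise NumericsError(f"exp overflow in rate_full: exponent={np.max(exponent)}")
    out = (K_B * TK / H_P) * np.exp(exponent)
    return float(out) if out.ndim == 0 else out


def rate_full_exact(T, p: GibbsParams, unit: str = "K"):
    """Eyring rate with the full closed-form free energy (no dropped term), 1/s."""
    TK = _check_temperature(T, unit)
    return eyring_rate(TK, delta_g_closed(TK, p))


def rate_approx(T, p: RateParams):
    """Operational sensitisation rate k(T) = c*exp(b*(T-Tg)), in 1/min.

    Depends on temperature only through T - Tg: pass T on the same scale as
    ``p.Tg`` (Celsius by package convention).
    """
    T = np.asarray(T, dtype=float)
    if not np.all(np.isfinite(T)):
        raise InvalidInputError("temperature must be finite")
    out = p.c * np.exp(p.b * (T - p.Tg))
    return float(out) if out.ndim == 0 else out


def rate_params_from_gibbs(p: GibbsParams, c: float | None = None) -> RateParams:
    """Map thermodynamic parameters onto the operational (c, b, Tg) triple.

    The exponential coefficient is taken as b = B/kB (the slope of ln k
    obtained by linearising the full rate around Tg).  Note the heat-capacity
    slope can equally be read off a calorimetry peak as B = 2*kB*b when the
    peak is modelled as symmetric about Tg; ``b`` is treated as a free
    empirical parameter everywhere else in the package, so this mapping is
    documentation, not an enforced constraint.
    """
    b = p.B / K_B
    if c is None:
        c = float(rate_full(p.Tg, p)) * 60.0  # per-minute at the melting point
    return RateParams(c=c, b=b, Tg=p.Tg - CELSIUS_OFFSET)
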