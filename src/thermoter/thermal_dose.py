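"""Thermal dosimetry: CEM43 and the denaturation-based isoeffective dose.

CEM43 ("cumulative equivalent minutes at 43 C") converts a heating interval
(t, T) into the time at 43 C producing the same biological effect,

    CEM43 = t * R^(T - 43),   R = 4 below 43 C, R = 2 above,

summed over the constant-temperature segments of a schedule.

The denaturation-rate alternative references the melting temperature Tg
instead: equating reaction products t_Tg*k(Tg) = t*k(T) with
k(T) = c*exp(b*(T-Tg)) gives the isoeffective time at Tg

    D_T = t * (T/Tg) * exp(dGc*(T-Tg)/(kB*T*Tg)) * exp(b*(T-Tg))
        ~= t * exp(b*(T-Tg)),

where the approximate form drops near-unity absolute-temperature factors.
With Tg = 43 C and b = ln R the two doses coincide, so CEM43 is the special
case of a denaturation reaction melting at 43 C.  An optional biphasic
variant uses separate b values below/above a cut temperature, mirroring the
empirical R = 4/2 split.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .constants import K_B
from .errors import InvalidInputError, NumericsError
from .thermo_core import GibbsParams, RateParams, delta_g_constant_cp

logger = logging.getLogger(__name__)

__all__ = [
    "Schedule",
    "cem43",
    "cem43_schedule",
    "dt_dose",
    "dt_dose_full",
    "dt_schedule",
]

_GUARD_LOW_C, _GUARD_HIGH_C = 30.0, 60.0
_VALID_LOW_C, _VALID_HIGH_C = 40.0, 50.0


@dataclass(frozen=True)
class Schedule:
    """A piecewise-constant temperature schedule.

    ``segments`` is an ordered list of (duration_min, temperature_C) pairs.
    Temperatures must lie in the 30-60 C guardrail; values outside 40-50 C
    (the model's stated validity range) trigger a logged warning.
    """

    segments: tuple[tuple[float, float], ...]

    def __init__(self, segments) -> None:
        segs = tuple((float(d), float(T)) for d, T in segments)
        if not segs:
            raise InvalidInputError("schedule must have at least one segment")
        for i, (d, T) in enumerate(segs):
            if not (d > 0 and math.isfinite(d)):
                raise InvalidInputError(f"segment {i}: duration must be positive, got {d}")
            if not (_GUARD_LOW_C <= T <= _GUARD_HIGH_C):
                raise InvalidInputError(
                    f"segment {i}: temperature {T} C outside the {_GUARD_LOW_C}-"
                    f"{_GUARD_HIGH_C} C guardrail"
                )
            if not (_VALID_LOW_C <= T <= _VALID_HIGH_C):
                logger.warning(
                    "segment %d: temperature %g C outside the 40-50 C model validity range", i, T
                )
        object.__setattr__(self, "segments", segs)

    @property
    def total_minutes(self) -> float:
        return sum(d for d, _ in self.segments)


def _check_time(t) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    if not np.all(np.isfinite(t)):
        raise InvalidInputError("time must be finite")
    if np.any(t < 0):
        raise InvalidInputError("time must be non-negative")
    return t


def cem43(t, T):
    """Equivalent minutes at 43 C for ``t`` minutes at ``T`` degrees Celsius.

    R = 4 for T < 43 C, R = 2 for T > 43 C; at exactly 43 C the exponent is
    zero and the choice is immaterial.
    """
    t = _check_time(t)
    T = np.asarray(T, dtype=float)
    if not np.all(np.isfinite(T)):
        raise InvalidInputError("temperature must be finite")
    R = np.where(T < 43.0, 4.0, 2.0)
    out = t * R ** (T - 43.0)
    return float(out) if out.ndim == 0 else out


def cem43_schedule(s: Schedule) -> float:
    """CEM43 of a piecewise-constant schedule: sum of per-segment doses."""
    return float(sum(cem43(d, T) for d, T in s.segments))


def dt_dose(t, T, p: RateParams, b_below: float | None = None, cut: float = 43.0):
    """Isoeffective minutes at the melting temperature, D_T ~= t*exp(b*(T-Tg)).

    ``T`` on the same scale as ``p.Tg`` (Celsius by convention).  Passing
    ``b_below`` enables the biphasic variant: segments below ``cut`` use that
    coefficient instead of ``p.b`` (default is single-b).
    """
    t = _check_time(t)
    T = np.asarray(T, dtype=float)
    if not np.all(np.isfinite(T)):
        raise InvalidInputError("temperature must be finite")
    if b_below is None:
        b = p.b
    else:
        b = np.where(T < cut, float(b_below), p.b)
    out = t * np.exp(b * (T - p.Tg))
    return float(out) if out.ndim == 0 else out


def dt_dose_full(t, T, gp: GibbsParams, p: RateParams):
    """Full isoeffective dose at Tg, with the absolute-temperature factors:

        t * (T/Tg) * exp(dGc*(T-Tg)/(kB*T*Tg)) * exp(b*(T-Tg))

    ``T`` in Kelvin (the extra factors need the absolute scale); Tg is taken
    from ``gp``.  Returns the dose; the ratio to the approximate form is what
    diagnostics report.
    """
    t = _check_time(t)
    TK = np.asarray(T, dtype=float)
    if np.any(TK <= 100.0):
        raise InvalidInputError("dt_dose_full expects absolute temperature in Kelvin")
    Tg = gp.Tg
    dgc = np.asarray(delta_g_constant_cp(TK, gp), dtype=float)
    exponent = dgc * (TK - Tg) / (K_B * TK * Tg) + p.b * (TK - Tg)
    if np.any(exponent > 700.0):
        raise NumericsError(f"exp overflow in dt_dose_full: exponent={np.max(exponent)}")
    out = t * (TK / Tg) * np.exp(exponent)
    return float(out) if out.ndim == 0 else out


def dt_schedule(s: Schedule, p: RateParams, b_below: float | None = None, cut: float = 43.0) -> float:
    """D_T of a piecewise-constant schedule: sum of per-segment doses."""
    return float(sum(dt_dose(d, T, p, b_below=b_below, cut=cut) for d, T in s.segments))
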