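"""Temperature-unit handling.

Absolute-temperature formulas (Eyring prefactor, Gibbs integrals) require
Kelvin; the TER law and the thermal doses depend on temperature only through
differences T - Tg and are unit-invariant as long as T and Tg share a scale.
Public entry points that need absolute temperature accept a ``unit`` tag and
convert once at the boundary.
"""

from __future__ import annotations

import numpy as np

from .constants import CELSIUS_OFFSET
from .errors import InvalidInputError

VALID_UNITS = ("K", "C")


def to_kelvin(T, unit: str = "K"):
    """Convert a temperature (scalar or array) to Kelvin.

    Parameters
    ----------
    T : float or array_like
        Temperature value(s).
    unit : {"K", "C"}
        Scale ``T`` is expressed in.
    """
    if unit not in VALID_UNITS:
        raise InvalidInputError(f"unknown temperature unit {unit!r}; use 'K' or 'C'")
    T = np.asarray(T, dtype=float)
    if not np.all(np.isfinite(T)):
        raise InvalidInputError("temperature must be finite")
    out = T + CELSIUS_OFFSET if unit == "C" else T
    return float(out) if out.ndim == 0 else out


def to_celsius(T, unit: str = "K"):
    """Convert a temperature (scalar or array) to degrees Celsius."""
    if unit not in VALID_UNITS:
        raise InvalidInputError(f"unknown temperature unit {unit!r}; use 'K' or 'C'")
    T = np.asarray(T, dtype=float)
    if not np.all(np.isfinite(T)):
        raise InvalidInputError("temperature must be finite")
    out = T - CELSIUS_OFFSET if unit == "K" else T
    return float(out) if out.ndim == 0 else out
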