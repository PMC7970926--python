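"""LQ survival for radiotherapy alone and for simultaneous thermoradiotherapy.

Radiation alone: -ln S = alpha*D + beta*D^2.  With simultaneous heating the
coefficients are TER-modulated, -ln S = alpha*TER*D + beta*TER^2*D^2, which
is exactly a dose rescaling D -> TER*D of the unheated curve.  The quadratic
inversion (isoeffect dose) realises the operational TER definition
TER = D_R / D_{R+H} at any survival endpoint; for model-consistent curves
the ratio is endpoint-independent.

Heat-only cell kill (the downward shift of measured survival curves at
D = 0) is not part of the synergy model; an optional additive offset on
-ln S is provided for callers who want to superpose it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .errors import InvalidInputError
from .ter_model import LQParams, TERParams, modulate_lq, ter

__all__ = [
    "SurvivalCurve",
    "lq_survival",
    "neg_log_survival",
    "combined_survival",
    "isoeffect_dose",
    "ter_from_doses",
]


@dataclass(frozen=True)
class SurvivalCurve:
    """A survival curve on a dose grid: -ln S values plus provenance metadata."""

    doses: np.ndarray
    neg_log_s: np.ndarray
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        doses = np.asarray(self.doses, dtype=float)
        nls = np.asarray(self.neg_log_s, dtype=float)
        if doses.shape != nls.shape:
            raise InvalidInputError("doses and neg_log_s must have matching shapes")
        if np.any(doses < 0):
            raise InvalidInputError("doses must be non-negative")
        if np.any(nls < 0):
            raise InvalidInputError("-ln S must be non-negative")
        order = np.argsort(doses)
        if np.any(np.diff(nls[order]) < -1e-12):
            raise InvalidInputError("-ln S must be non-decreasing in dose")
        object.__setattr__(self, "doses", doses)
        object.__setattr__(self, "neg_log_s", nls)

    @property
    def survival(self) -> np.ndarray:
        return np.exp(-self.neg_log_s)


def neg_log_survival(D, p: LQParams, offset: float = 0.0):
    """-ln S = alpha*D + beta*D^2 (+ optional heat-only offset)."""
    D = np.asarray(D, dtype=float)
    if np.any(D < 0):
        raise InvalidInputError("dose must be non-negative")
    out = p.alpha * D + p.beta * D**2 + offset
    return float(out) if out.ndim == 0 else out


def lq_survival(D, p: LQParams):
    """Surviving fraction exp(-(alpha*D + beta*D^2)); equals 1 at D = 0."""
    out = np.exp(-np.asarray(neg_log_survival(D, p)))
    return float(out) if out.ndim == 0 else out


def combined_survival(D, t, T, lq: LQParams, tp: TERParams, ht_offset: float = 0.0):
    """Surviving fraction for simultaneous heating and irradiation.

    Equals ``lq_survival`` with (alpha, beta) replaced by
    (alpha*TER(t,T), beta*TER(t,T)^2).  ``ht_offset`` adds a heat-only kill
    term to -ln S; it defaults to zero (the synergy model carries no offset).
    """
    ter_value = ter(t, T, tp)
    if np.ndim(ter_value) == 0:
        mod = modulate_lq(lq, float(ter_value))
        out = np.exp(-(np.asarray(neg_log_survival(D, mod), dtype=float) + ht_offset))
        return float(out) if out.ndim == 0 else out
    D = np.asarray(D, dtype=float)
    if np.any(D < 0):
        raise InvalidInputError("dose must be non-negative")
    tv = np.asarray(ter_value, dtype=float)
    nls = lq.alpha * tv * D + lq.beta * tv**2 * D**2 + ht_offset
    return np.exp(-nls)


def isoeffect_dose(neg_log_s_target: float, p: LQParams) -> float:
    """Dose producing a given -ln S endpoint: the non-negative root of
    beta*D^2 + alpha*D - target = 0.

    Uses the numerically stable quadratic root (no cancellation for small
    beta); back-substitution reproduces the target to ~1e-10.
    """
    if not (neg_log_s_target >= 0):
        raise InvalidInputError(f"-ln S target must be non-negative, got {neg_log_s_target}")
    if neg_log_s_target == 0:
        return 0.0
    if p.beta == 0:
        # alpha > 0 guaranteed by LQParams invariant
        return neg_log_s_target / p.alpha
    disc = p.alpha**2 + 4.0 * p.beta * neg_log_s_target
    # root via 2c/(-b - sqrt(disc)) form, stable as beta -> 0
    return 2.0 * neg_log_s_target / (p.alpha + math.sqrt(disc))


def ter_from_doses(D_R: float, D_RH: float) -> float:
    """Operational TER = D_R / D_{R+H} from isoeffective doses (both > 0).

    For curves related by (alpha, beta) -> (alpha*k, beta*k^2) this ratio is
    exactly k at every endpoint.
    """
    if not (D_R > 0 and D_RH > 0):
        raise InvalidInputError(f"doses must be positive, got ({D_R}, {D_RH})")
    return D_R / D_RH
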