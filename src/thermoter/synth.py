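"""Seeded synthetic data with the statistical structure the model assumes.

The reference experiments behind the model — clonogenic TER measurements in
CHO cells in vitro, tumour-growth TER in C3H mammary carcinoma in vivo, and
LQ coefficients of thermotolerant/non-thermotolerant M8013 cells heated for
30 min — exist only as figures in the historical literature and are not
shipped.  This module generates datasets with the same design: TER linear
in heating time at fixed temperature, slope exponential in temperature
(40-46 C, sessions up to two hours), with additive Gaussian noise on TER or
log-normal noise on survival.  Presets carry the published parameter rows
verbatim as generating truths, so fitted estimates can be compared against
known values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidInputError
from .fitting import AlphaBetaDataset, TERDataset
from .survival import combined_survival
from .ter_model import LQParams, TERParams, ter

__all__ = [
    "SynthConfig",
    "PRESETS",
    "make_config",
    "gen_ter_dataset",
    "gen_alpha_beta_dataset",
    "gen_survival_curves",
    "gen_ht_neg_log_s",
]

# Published TER-model parameter rows used as generating truths.
# o for the M8013 presets defaults to 1 (their source table reports none).
PRESETS: dict[str, TERParams] = {
    "cho_like": TERParams(o=0.97, a_prime=1.00, b=0.95, Tg=48.07),
    "c3h_like": TERParams(o=1.02, a_prime=1.00, b=0.91, Tg=46.60),
    "m8013tt_like": TERParams(o=1.00, a_prime=1.00, b=0.50, Tg=46.34),
    "m8013ntt_like": TERParams(o=1.00, a_prime=1.00, b=1.09, Tg=46.47),
}

#: Default experimental design: hyperthermia regime, ~1-2 h sessions.
DEFAULT_TEMPS_C = (40.0, 41.0, 42.0, 43.0, 44.0, 45.0, 46.0)
DEFAULT_TIMES_MIN = (15.0, 30.0, 45.0, 60.0, 90.0, 120.0)

#: TER values are floored here after adding noise (TER must stay positive).
TER_FLOOR = 0.01


@dataclass(frozen=True)
class SynthConfig:
    """Configuration of a synthetic experiment.

    ``sigma`` is the additive Gaussian noise SD on TER (or the log-normal
    sigma on survival-type outputs).  ``heteroscedastic`` scales the TER
    noise SD proportionally to the TER value instead.
    """

    ter_params: TERParams
    lq_baseline: LQParams = LQParams(alpha=0.3, beta=0.03)
    temperatures: tuple[float, ...] = DEFAULT_TEMPS_C
    times: tuple[float, ...] = DEFAULT_TIMES_MIN
    sigma: float = 0.0
    heteroscedastic: bool = False
    seed: int = 0
    preset: str = "custom"

    def __post_init__(self) -> None:
        if not self.temperatures or not self.times:
            raise InvalidInputError("temperature and time grids must be non-empty")
        if self.sigma < 0:
            raise InvalidInputError("sigma must be non-negative")


def make_config(preset: str = "cho_like", **overrides) -> SynthConfig:
    """Build a :class:`SynthConfig` from a named preset, with overrides."""
    if preset == "custom":
        if "ter_params" not in overrides:
            raise InvalidInputError("custom preset requires ter_params")
        return SynthConfig(preset="custom", **overrides)
    if preset not in PRESETS:
        raise InvalidInputError(f"unknown preset {preset!r}; choose from {sorted(PRESETS)}")
    params = overrides.pop("ter_params", PRESETS[preset])
    return SynthConfig(ter_params=params, preset=preset, **overrides)


def gen_ter_dataset(cfg: SynthConfig) -> TERDataset:
    """TER over the (temperature, time) grid, plus N(0, sigma^2) noise.

    Deterministic given the seed; noisy values are floored at a small
    positive constant so the dataset invariant TER > 0 holds.
    """
    rng = np.random.default_rng(cfg.seed)
    TT, tt = np.meshgrid(cfg.temperatures, cfg.times, indexing="ij")
    T = TT.ravel()
    t = tt.ravel()
    clean = np.asarray(ter(t, T, cfg.ter_params), dtype=float)
    if cfg.sigma > 0:
        sd = cfg.sigma * clean if cfg.heteroscedastic else cfg.sigma
        noisy = clean + rng.normal(0.0, 1.0, clean.shape) * sd
    else:
        noisy = clean
    noisy = np.maximum(noisy, TER_FLOOR)
    return TERDataset(
        temperature=T,
        time=t,
        ter=noisy,
        label=f"synthetic:{cfg.preset} seed={cfg.seed} sigma={cfg.sigma} {cfg.ter_params}",
    )


def gen_alpha_beta_dataset(cfg: SynthConfig, t: float = 30.0, sigma_alpha: float | None = None) -> AlphaBetaDataset:
    """LQ coefficients at each temperature after ``t`` minutes of heating.

    alpha(T) = alpha0*TER and beta(T) = beta0*TER^2 with optional
    multiplicative log-normal noise: ``cfg.sigma`` applies to both
    coefficients unless ``sigma_alpha`` overrides the alpha channel (the
    reference data had markedly noisier alpha than beta measurements).
    """
    rng = np.random.default_rng(cfg.seed)
    T = np.asarray(cfg.temperatures, dtype=float)
    tv = np.asarray(ter(t, T, cfg.ter_params), dtype=float)
    alpha = cfg.lq_baseline.alpha * tv
    beta = cfg.lq_baseline.beta * tv**2
    s_a = cfg.sigma if sigma_alpha is None else sigma_alpha
    if s_a > 0:
        alpha = alpha * np.exp(rng.normal(0.0, s_a, T.shape))
    if cfg.sigma > 0:
        beta = beta * np.exp(rng.normal(0.0, cfg.sigma, T.shape))
    return AlphaBetaDataset(
        temperature=T,
        alpha=alpha,
        beta=beta,
        alpha0=cfg.lq_baseline.alpha,
        beta0=cfg.lq_baseline.beta,
        time=t,
        label=f"synthetic:{cfg.preset} seed={cfg.seed}",
    )


def gen_survival_curves(cfg: SynthConfig, doses) -> "pd.DataFrame":
    """Survival table over dose x time x temperature, from the combined model.

    Returns a DataFrame with columns dose_Gy, time_min, temperature_C,
    surviving_fraction.  ``cfg.sigma`` applies as log-normal noise on the
    surviving fraction.  Includes the time=0 (radiation-alone) rows.
    """
    import pandas as pd

    rng = np.random.default_rng(cfg.seed)
    doses = np.asarray(doses, dtype=float)
    rows = []
    for T in cfg.temperatures:
        for t in (0.0, *cfg.times):
            s = np.asarray(
                combined_survival(doses, t, T, cfg.lq_baseline, cfg.ter_params), dtype=float
            )
            if cfg.sigma > 0:
                s = s * np.exp(rng.normal(0.0, cfg.sigma, s.shape))
            rows.append(
                pd.DataFrame(
                    {
                        "dose_Gy": doses,
                        "time_min": t,
                        "temperature_C": T,
                        "surviving_fraction": np.clip(s, 1e-300, None),
                    }
                )
            )
    return pd.concat(rows, ignore_index=True)


def gen_ht_neg_log_s(
    cfg: SynthConfig, p1: float = 0.01, p2: float = 0.0002, reference_T: float | None = None
) -> "pd.DataFrame":
    """Heat-only kill curves: -ln S quadratic in an effective exposure time.

    Emulates heat-alone survival experiments where -ln S grows quadratically
    with treatment time, faster at higher temperature.  The effective time
    is t*exp(b*(T - T_ref)) with the config's (b, Tg) law and ``reference_T``
    defaulting to the hottest grid temperature, so that rescaling the time
    axis by the matching thermal dose collapses all temperatures onto the
    single quadratic -ln S = p1*x + p2*x^2.
    """
    import pandas as pd

    rng = np.random.default_rng(cfg.seed)
    tp = cfg.ter_params
    T_ref = max(cfg.temperatures) if reference_T is None else reference_T
    rows = []
    for T in cfg.temperatures:
        t = np.asarray(cfg.times, dtype=float)
        x = t * np.exp(tp.b * (np.asarray(T) - T_ref))
        nls = p1 * x + p2 * x**2
        if cfg.sigma > 0:
            nls = np.maximum(nls + rng.normal(0.0, cfg.sigma, nls.shape), 0.0)
        rows.append(
            pd.DataFrame({"time_min": t, "temperature_C": T, "neg_log_s": nls})
        )
    return pd.concat(rows, ignore_index=True)
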