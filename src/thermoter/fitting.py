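"""Parameter estimation for the TER model.

Three estimators are provided for TER = o + a'*t*exp(b*(T-Tg)):

* ``fit_ter_two_stage`` — the graphical procedure: per-temperature ordinary
  least squares of TER on time (the model is linear in t at fixed T), then
  OLS of ln(slope) on temperature (the slope is exponential in T).  With the
  a' = 1 convention, b is the stage-2 slope and Tg = -intercept/b; the onset
  o is the (inverse-variance weighted) mean of the stage-1 intercepts.
* ``fit_ter_nls`` — direct nonlinear least squares on the same model,
  initialised from the two-stage estimates.
* ``fit_ter_from_alpha_beta`` — for designs measuring the LQ coefficients at
  one heating time per temperature: TER_alpha = alpha(T)/alpha0 and
  TER_beta = sqrt(beta(T)/beta0) are pooled and ln(TER-1) regressed on T
  (the onset is fixed at exactly 1 here).

a' and Tg are jointly unidentifiable (only a'*exp(-b*Tg) enters the model),
so the default convention fixes a' = 1 and lets Tg float; alternatively Tg
may be fixed (e.g. from calorimetry) and a' fitted.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
import numpy as np
from scipy import optimize

from .errors import FitError, InvalidInputError
from .ter_model import TERParams, ter, ter_from_alpha, ter_from_beta

logger = logging.getLogger(__name__)

__all__ = [
    "TERDataset",
    "AlphaBetaDataset",
    "FitResult",
    "fit_ter_two_stage",
    "fit_ter_nls",
    "fit_ter_from_alpha_beta",
    "fit_ht_quadratic",
    "r_squared",
]


@dataclass(frozen=True)
class TERDataset:
    """TER measurements over a (temperature, time) design.

    Temperatures in degrees Celsius, times in minutes.  ``se`` holds optional
    per-record uncertainties (NaN where unknown).
    """

    temperature: np.ndarray
    time: np.ndarray
    ter: np.ndarray
    se: np.ndarray | None = None
    label: str = ""

    def __post_init__(self) -> None:
        T = np.asarray(self.temperature, dtype=float)
        t = np.asarray(self.time, dtype=float)
        y = np.asarray(self.ter, dtype=float)
        if not (T.shape == t.shape == y.shape):
            raise InvalidInputError("temperature, time and ter must have matching shapes")
        if T.size == 0:
            raise InvalidInputError("dataset is empty")
        if np.any(t < 0):
            raise InvalidInputError("times must be non-negative")
        if np.any(y <= 0):
            raise InvalidInputError("TER values must be positive")
        se = None if self.se is None else np.asarray(self.se, dtype=float)
        object.__setattr__(self, "temperature", T)
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "ter", y)
        object.__setattr__(self, "se", se)

    @property
    def n(self) -> int:
        return int(self.ter.size)

    def temperatures(self) -> np.ndarray:
        """Distinct temperatures, sorted."""
        return np.unique(self.temperature)


@dataclass(frozen=True)
class AlphaBetaDataset:
    """LQ coefficients measured at several temperatures, one shared heating time.

    ``alpha0``/``beta0`` are the no-heat baseline; ``time`` is the heating
    duration in minutes (the full session length, even when irradiation
    happened midway through it).
    """

    temperature: np.ndarray
    alpha: np.ndarray
    beta: np.ndarray
    alpha0: float
    beta0: float
    time: float
    label: str = ""

    def __post_init__(self) -> None:
        T = np.asarray(self.temperature, dtype=float)
        a = np.asarray(self.alpha, dtype=float)
        b = np.asarray(self.beta, dtype=float)
        if not (T.shape == a.shape == b.shape):
            raise InvalidInputError("temperature, alpha and beta must have matching shapes")
        if not (self.alpha0 > 0 and self.beta0 > 0):
            raise InvalidInputError("baseline alpha0 and beta0 must be positive")
        if not (self.time > 0):
            raise InvalidInputError("heating time must be positive")
        object.__setattr__(self, "temperature", T)
        object.__setattr__(self, "alpha", a)
        object.__setattr__(self, "beta", b)


@dataclass
class FitResult:
    """Estimates of (o, a', b, Tg) with provenance.

    ``fixed`` flags which parameters were held at their value rather than
    estimated; ``stderr`` holds standard errors where defined (NaN
    otherwise).  ``r_squared`` is computed on the TER scale against the
    pooled observations unless noted; ``extra`` carries method-specific
    diagnostics (excluded points, subset R^2, convergence trace).
    """

    o: float
    a_prime: float
    b: float
    Tg: float
    fixed: dict[str, bool]
    stderr: dict[str, float]
    r_squared: float
    residuals: np.ndarray
    method: str
    n_obs: int
    extra: dict = field(default_factory=dict)

    @property
    def params(self) -> TERParams:
        return TERParams(o=self.o, a_prime=self.a_prime, b=self.b, Tg=self.Tg)

    def summary(self) -> str:
        lines = [f"TER fit [{self.method}], n={self.n_obs}"]
        for name in ("o", "a_prime", "b", "Tg"):
            val = getattr(self, name)
            tag = "fixed" if self.fixed.get(name, False) else "free"
            se = self.stderr.get(name, float("nan"))
            se_txt = f" +/- {se:.4g}" if math.isfinite(se) else ""
            lines.append(f"  {name:8s} = {val:.6g}{se_txt} ({tag})")
        lines.append(f"  R^2      = {self.r_squared:.6g}")
        return "\n".join(lines)


def r_squared(observed, predicted) -> float:
    """Coefficient of determination 1 - SS_res/SS_tot (SS_tot about the mean)."""
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape or obs.size < 2:
        raise InvalidInputError("observed and predicted must match with length >= 2")
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    if ss_tot == 0.0:
        raise InvalidInputError("R^2 undefined: observed values are all equal")
    ss_res = float(np.sum((obs - pred) ** 2))
    return 1.0 - ss_res / ss_tot


def _ols_line(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float, float]:
    """OLS of y on x.  Returns (intercept, slope, se_intercept, se_slope)."""
    n = x.size
    X = np.column_stack([np.ones(n), x])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    if n > 2:
        sigma2 = float(resid @ resid) / (n - 2)
        cov = sigma2 * np.linalg.inv(X.T @ X)
        se = np.sqrt(np.diag(cov))
    else:
        se = np.array([np.nan, np.nan])
    return float(coef[0]), float(coef[1]), float(se[0]), float(se[1])


def fit_ter_two_stage(
    d: TERDataset,
    Tg_fixed: float | None = None,
    weighted_stage2: bool = False,
) -> FitResult:
    """Two-stage (graphical) fit of the TER law.

    Stage 1 regresses TER on time within each temperature; stage 2 regresses
    the log of the stage-1 slopes on temperature.  Temperatures whose slope
    is non-positive cannot enter the log and are excluded with a warning.
    The onset is the inverse-variance weighted mean of the stage-1
    intercepts (plain mean when intercept variances are unavailable or
    degenerate, e.g. noiseless data).

    a' and Tg are jointly unidentifiable, so by default a' is fixed at 1 and
    Tg floats; passing ``Tg_fixed`` (e.g. a calorimetric melting point)
    instead fits a' = exp(intercept + b*Tg_fixed).

    ``weighted_stage2`` propagates stage-1 slope variances into stage 2
    (off by default: the reference procedure uses unweighted trend lines).
    """
    temps = d.temperatures()
    if temps.size < 2:
        raise FitError("two-stage fit needs at least 2 distinct temperatures")

    slopes, slope_ses, intercepts, intercept_ses, used_T, excluded = [], [], [], [], [], []
    for T in temps:
        mask = d.temperature == T
        tt, yy = d.time[mask], d.ter[mask]
        if np.unique(tt).size < 2:
            raise FitError(f"temperature {T} C has fewer than 2 distinct times")
        ic, sl, se_ic, se_sl = _ols_line(tt, yy)
        if sl <= 0:
            logger.warning("stage 1 slope non-positive (%g) at %g C; excluded from stage 2", sl, T)
            excluded.append(float(T))
            continue
        slopes.append(sl)
        slope_ses.append(se_sl)
        intercepts.append(ic)
        intercept_ses.append(se_ic)
        used_T.append(float(T))
    if len(used_T) < 2:
        raise FitError("fewer than 2 temperatures with positive stage-1 slopes")

    used_T_arr = np.asarray(used_T)
    slopes_arr = np.asarray(slopes)
    ln_slopes = np.log(slopes_arr)

    if weighted_stage2 and np.all(np.isfinite(slope_ses)) and np.all(np.asarray(slope_ses) > 0):
        w = (slopes_arr / np.asarray(slope_ses)) ** 2  # var of ln(slope) ~ (se/slope)^2
        W = np.sqrt(w)
        X = np.column_stack([np.ones(used_T_arr.size), used_T_arr])
        coef, *_ = np.linalg.lstsq(X * W[:, None], ln_slopes * W, rcond=None)
        q, m = float(coef[0]), float(coef[1])
        se_q = se_m = float("nan")
    else:
        q, m, se_q, se_m = _ols_line(used_T_arr, ln_slopes)

    if m <= 0:
        raise FitError(f"stage-2 slope must be positive (got {m}): no exponential trend in T")

    b = m
    if Tg_fixed is None:
        a_prime, Tg = 1.0, -q / m
        # delta method for Tg = -q/m from the stage-2 covariance
        se_Tg = float("nan")
        if math.isfinite(se_q) and math.isfinite(se_m) and q != 0:
            se_Tg = abs(Tg) * math.hypot(se_q / abs(q), se_m / abs(m))
        stderr_extra = {"a_prime": float("nan"), "Tg": se_Tg}
        fixed = {"o": False, "a_prime": True, "b": False, "Tg": False}
    else:
        Tg = float(Tg_fixed)
        a_prime = math.exp(q + m * Tg)
        stderr_extra = {"a_prime": float("nan"), "Tg": float("nan")}
        fixed = {"o": False, "a_prime": False, "b": False, "Tg": True}

    ic_arr = np.asarray(intercepts)
    ic_se = np.asarray(intercept_ses)
    if np.all(np.isfinite(ic_se)) and np.all(ic_se > 0):
        w = 1.0 / ic_se**2
        o = float(np.sum(w * ic_arr) / np.sum(w))
        se_o = float(1.0 / math.sqrt(np.sum(w)))
    else:
        o = float(ic_arr.mean())
        se_o = float(ic_arr.std(ddof=1) / math.sqrt(ic_arr.size)) if ic_arr.size > 1 else float("nan")
    o = max(o, 0.0)

    params = TERParams(o=o, a_prime=a_prime, b=b, Tg=Tg)
    pred = ter(d.time, d.temperature, params)
    resid = d.ter - np.asarray(pred)
    r2 = r_squared(d.ter, pred)
    return FitResult(
        o=o,
        a_prime=a_prime,
        b=b,
        Tg=Tg,
        fixed=fixed,
        stderr={"o": se_o, "b": se_m, **stderr_extra},
        r_squared=r2,
        residuals=resid,
        method="two_stage",
        n_obs=d.n,
        extra={
            "stage1_slopes": dict(zip(used_T, slopes)),
            "stage1_intercepts": dict(zip(used_T, intercepts)),
            "excluded_temperatures": excluded,
        },
    )


def fit_ter_nls(
    d: TERDataset,
    fixed: dict[str, float] | None = None,
    init: TERParams | None = None,
) -> FitResult:
    """Direct nonlinear least-squares fit of TER = o + a'*t*exp(b*(T-Tg)).

    ``fixed`` maps parameter names to held values; by default a' is fixed at
    1 (freeing both a' and Tg is refused — they are not separately
    identifiable).  Initialised from the two-stage estimates unless ``init``
    is given.  Standard errors come from the Gauss-Newton covariance
    (J'J)^-1 * s^2 at the solution.
    """
    fixed = {"a_prime": 1.0} if fixed is None else dict(fixed)
    if "a_prime" not in fixed and "Tg" not in fixed:
        raise FitError(
            "a' and Tg are jointly unidentifiable: fix one of them "
            "(the default convention is a_prime=1)"
        )
    free_names = [n for n in ("o", "a_prime", "b", "Tg") if n not in fixed]
    if d.n <= len(free_names):
        raise FitError(f"{d.n} observations cannot constrain {len(free_names)} free parameters")
    if np.unique(d.temperature).size < 2 and "Tg" not in fixed:
        raise FitError("a single temperature cannot identify b and Tg")
    spread = float(np.ptp(d.ter))
    if spread < 1e-12:
        raise FitError("TER values are constant: temperature/time effect not identifiable")

    if init is None:
        try:
            ts = fit_ter_two_stage(d)
            init = ts.params
        except FitError:
            init = TERParams(o=1.0, a_prime=fixed.get("a_prime", 1.0), b=0.5,
                             Tg=float(d.temperature.max()) + 2.0)

    start = {"o": init.o, "a_prime": init.a_prime, "b": init.b, "Tg": init.Tg}
    start.update(fixed)

    def unpack(x: np.ndarray) -> TERParams:
        vals = dict(fixed)
        for name, v in zip(free_names, x):
            vals[name] = float(v)
        full = {**start, **vals}
        return TERParams(o=max(full["o"], 0.0), a_prime=max(full["a_prime"], 1e-12),
                         b=max(full["b"], 1e-12), Tg=full["Tg"])

    def residual(x: np.ndarray) -> np.ndarray:
        p = unpack(x)
        return np.asarray(ter(d.time, d.temperature, p)) - d.ter

    x0 = np.array([start[n] for n in free_names], dtype=float)
    sol = optimize.least_squares(residual, x0, method="lm", xtol=1e-14, ftol=1e-14, gtol=1e-14)
    if not sol.success:
        raise FitError(f"nonlinear least squares did not converge: {sol.message}")

    p_hat = unpack(sol.x)
    resid = residual(sol.x)
    dof = d.n - len(free_names)
    stderr = {n: float("nan") for n in ("o", "a_prime", "b", "Tg")}
    if dof > 0:
        s2 = float(resid @ resid) / dof
        JTJ = sol.jac.T @ sol.jac
        try:
            cov = s2 * np.linalg.inv(JTJ)
            for i, name in enumerate(free_names):
                stderr[name] = float(math.sqrt(max(cov[i, i], 0.0)))
        except np.linalg.LinAlgError:
            logger.warning("singular Jacobian at the NLS solution; standard errors unavailable")

    pred = np.asarray(ter(d.time, d.temperature, p_hat))
    return FitResult(
        o=p_hat.o,
        a_prime=p_hat.a_prime,
        b=p_hat.b,
        Tg=p_hat.Tg,
        fixed={n: (n in fixed) for n in ("o", "a_prime", "b", "Tg")},
        stderr=stderr,
        r_squared=r_squared(d.ter, pred),
        residuals=d.ter - pred,
        method="nls",
        n_obs=d.n,
        extra={"cost": float(sol.cost), "converged": bool(sol.success), "nfev": int(sol.nfev)},
    )


def fit_ter_from_alpha_beta(d: AlphaBetaDataset, fix_o_at_1: bool = True) -> FitResult:
    """Fit (b, Tg) from TER_alpha and TER_beta pooled, via ln(TER-1) on T.

    TER_alpha = alpha(T)/alpha0 and TER_beta = sqrt(beta(T)/beta0) are
    computed per record and pooled; OLS of ln(TER-1) on temperature with
    a' = 1 gives b = slope and Tg = (ln t - intercept)/b.  The onset is
    fixed at exactly 1 (TER - 1, not TER - o_hat).  Records with TER <= 1
    cannot enter the log and are dropped with a warning.  R^2 is reported
    on the pooled TER values and, separately, on the TER_beta subset.
    """
    if not fix_o_at_1:
        raise FitError("only the o=1 convention is supported for alpha/beta designs")
    ter_a = np.asarray(ter_from_alpha(d.alpha, d.alpha0))
    ter_b = np.asarray(ter_from_beta(d.beta, d.beta0))
    T_pool = np.concatenate([d.temperature, d.temperature])
    ter_pool = np.concatenate([ter_a, ter_b])
    kind = np.concatenate([np.zeros_like(ter_a), np.ones_like(ter_b)])  # 1 = beta-derived

    usable = ter_pool > 1.0
    n_dropped = int(np.sum(~usable))
    if n_dropped:
        logger.warning("%d record(s) with TER <= 1 excluded from the log-linear fit", n_dropped)
    if np.sum(usable) < 2:
        raise FitError("fewer than 2 usable (TER > 1) points")

    x, y = T_pool[usable], np.log(ter_pool[usable] - 1.0)
    q, m, se_q, se_m = _ols_line(x, y)
    if m <= 0:
        raise FitError(f"log-linear slope must be positive (got {m})")
    b = m
    Tg = (math.log(d.time) - q) / b

    params = TERParams(o=1.0, a_prime=1.0, b=b, Tg=Tg)
    pred_pool = np.asarray(ter(d.time, T_pool, params))
    r2_pool = r_squared(ter_pool, pred_pool)
    beta_mask = kind == 1
    r2_beta = (
        r_squared(ter_pool[beta_mask], pred_pool[beta_mask]) if np.sum(beta_mask) >= 2 else float("nan")
    )
    return FitResult(
        o=1.0,
        a_prime=1.0,
        b=b,
        Tg=Tg,
        fixed={"o": True, "a_prime": True, "b": False, "Tg": False},
        stderr={"o": float("nan"), "a_prime": float("nan"), "b": se_m, "Tg": float("nan")},
        r_squared=r2_pool,
        residuals=ter_pool - pred_pool,
        method="eq19_loglinear",
        n_obs=int(ter_pool.size),
        extra={"r_squared_beta": r2_beta, "n_excluded": n_dropped,
               "ter_alpha": ter_a, "ter_beta": ter_b},
    )


def fit_ht_quadratic(x, neg_log_s, through_origin: bool = True):
    """Least-squares quadratic -ln S = p1*x + p2*x^2 (+ intercept if requested).

    ``x`` is heating time or a thermal-dose rescaling of it.  Returns
    (coefficients, R^2); coefficients are (p1, p2) through the origin or
    (p0, p1, p2) with an intercept.  Used to compare how well different
    thermal-dose axes collapse heat-only kill curves onto one quadratic.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(neg_log_s, dtype=float)
    if x.shape != y.shape:
        raise InvalidInputError("x and -ln S must have matching shapes")
    min_n = 2 if through_origin else 3
    if x.size < min_n:
        raise FitError(f"need at least {min_n} points")
    cols = [x, x**2] if through_origin else [np.ones_like(x), x, x**2]
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise FitError("design matrix is rank-deficient (degenerate x grid)")
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    pred = X @ coef
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum((y - pred) ** 2)) / ss_tot if ss_tot > 0 else float("nan")
    return tuple(float(c) for c in coef), r2
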