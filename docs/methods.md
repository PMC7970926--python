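# Methods

## Model

### Survival and the thermal enhancement ratio

The linear-quadratic (LQ) model describes clonogenic survival after a
radiation dose D as −ln S = αD + βD², with α (Gy⁻¹) the single-hit kill
rate and β (Gy⁻²) the rate of lethality from accumulated sublethal damage.
The thermal enhancement ratio is defined operationally as TER = D_R/D_{R+H},
the ratio of doses reaching the same survival endpoint with radiation alone
versus with simultaneous hyperthermia. Treating heating as a dose rescaling
D → TER·D gives the modulation

    α* = α·TER,   β* = β·TER²,

so the dose-ratio TER of the modulated curve is endpoint-independent — the
consistency property the test suite verifies over random endpoints — and
α*/β* = (α/β)/TER.

Heat-only cell kill (the downward offset of measured survival curves at
D = 0) is deliberately not part of `combined_survival`: the model describes
the radiothermal synergy, not heat monotherapy. An additive `ht_offset` on
−ln S is available for callers who want to superpose an independently
measured heat-kill term.

### Denaturation kinetics

Radiosensitisation is attributed to the heat-driven advance of cells into a
more vulnerable state, rate-limited by protein denaturation. The rate
follows Eyring transition-state theory, k(T) = (k_B T/h_p)·exp(−ΔG/k_B T)
(CODATA 2018 constants, one table in `constants.py`). The free energy uses
the melting-point reference ΔG(Tg) = 0 and a heat capacity that varies
linearly around the melting temperature, C_p(T) = A − B·|T − Tg|.
Integrating the enthalpy and entropy contributions gives the closed form

    ΔG(T) = ΔG_c(T) − (B/2)(T² − Tg²) + B·T·Tg·ln(T/Tg),
    ΔG_c(T) = ΔG₀ + A[(T − Tg) − T·ln(T/Tg)],

implemented in `delta_g_closed` and validated against adaptive quadrature of
the defining integral (`delta_g_numeric`, `scipy.integrate.quad`) to 1e−6
relative over randomised parameters — the two routes are kept independent on
purpose.

Two rate forms are exposed. `rate_full` evaluates the literature form

    k(T) = (k_B T/h_p)·exp(−ΔG_c/k_B T)·exp[(B/2k_B)(T − Tg)(1 + Tg/T)],

which drops a −(B·Tg/k_B)·ln(T/Tg) term relative to the closed-form free
energy. That dropped term cancels the retained exponent at leading order in
(T − Tg), so for physically sized B the printed form and the exact one
(`rate_full_exact`, the Eyring rate with the full ΔG) diverge; both are
provided rather than silently resolving the discrepancy, and a test pins
down the cancellation. Operationally the package always works with the
empirical approximation

    k(T) ≈ c·exp(b·(T − Tg)),

where c (per minute) and b (K⁻¹) are free cell-line parameters. The mapping
to calorimetry can be written b = B/k_B from the rate linearisation or
b = B/2k_B when B is read off a symmetric calorimetry peak; because of this
factor-of-two ambiguity in the literature, `rate_params_from_gibbs`
documents but never enforces a mapping, and b is fitted empirically
everywhere.

### TER law and thermal dose

Assuming the absorbed sensitising energy grows linearly with exposure time
at rate k(T),

    TER(t, T) = o + a′·t·exp(b·(T − Tg)),   a′ = a·c.

Only the product a′·e^(−b·Tg) is identifiable, so the default convention
fixes a′ = 1 and lets Tg float; `Tg_fixed` inverts the convention for use
with calorimetric melting points. The TER excess is exactly linear in the
thermal dose: TER − o = a′·D_T.

Equating reaction products at T and at the reference temperature gives the
isoeffective dose at the melting point,

    D_T = t·(T/Tg)·exp[ΔG_c(T − Tg)/(k_B·T·Tg)]·exp[b(T − Tg)] ≈ t·e^{b(T−Tg)},

with the absolute-temperature factors near unity in the 40–50 °C range
(`dt_dose_full` reports the full expression for diagnostics; `dt_dose` is
the approximate form). With Tg = 43 °C and b = ln 2 the approximate D_T is
identical to CEM43 for T ≥ 43 °C (b = ln 4 below); a biphasic option
(`b_below`, cut at 43 °C by default) mirrors the empirical R = 4/2 split,
but single-b is the default. Schedules are piecewise-constant only;
continuous temperature logs must be pre-discretised by the caller. Exactly
43 °C uses exponent 0, so the R choice there is immaterial.

## Fitting

* **Two-stage** (`fit_ter_two_stage`): per-temperature OLS of TER on time
  (the model is linear in t at fixed T), then OLS of ln(slope) on
  temperature; b is the stage-2 slope and Tg = −intercept/b under a′ = 1.
  Stage 2 is unweighted by default, matching the straight trend lines of the
  graphical procedure; a weighted option propagates stage-1 slope variances.
  Temperatures with non-positive stage-1 slopes cannot enter the log and are
  dropped with a logged warning — a transparent rule preferred over any
  offset fudge. The onset o is the inverse-variance weighted mean of the
  stage-1 intercepts (plain mean when the intercept variances are degenerate,
  e.g. noiseless data or two-point strata); this aggregation convention is a
  documented choice, since the published tables report o with a ± that
  suggests averaging rather than joint estimation.
* **Nonlinear least squares** (`fit_ter_nls`): Levenberg–Marquardt on the
  TER residuals (`scipy.optimize.least_squares`), initialised from the
  two-stage estimates; a′ fixed at 1 by default and a fit with both a′ and
  Tg free is refused as unidentifiable. Standard errors come from the
  Gauss–Newton covariance s²(JᵀJ)⁻¹; a simulation test checks that the ±2 SE
  interval for b covers the truth at roughly the nominal 95% rate.
* **LQ-coefficient route** (`fit_ter_from_alpha_beta`): for designs that
  measure α(T), β(T) at one heating time, TER_α = α(T)/α₀ and
  TER_β = √(β(T)/β₀) are pooled and ln(TER − 1) regressed on T. Here o is
  fixed at exactly 1 (TER − 1, not TER − ô). Records with TER ≤ 1 are
  excluded with a warning. R² is reported on the pooled set and on the
  β-subset separately, since α measurements are often the noisier channel.
  For sessions where irradiation happens midway through heating, the full
  session length is the time variable.
* **Heat-only quadratics** (`fit_ht_quadratic`): −ln S = p₁x + p₂x²
  (through the origin by default) on time or on a thermal-dose rescaling of
  it; used to compare how well CEM43 and D_T axes collapse multi-temperature
  kill curves onto a single quadratic.

R² is 1 − SS_res/SS_tot about the observed mean, computed on the TER scale
(not the log scale) unless the log-linear method is selected explicitly;
which scale the published tables used is not stated, so both are exposed.

## Synthetic data

No experimental datasets ship with the package: the historical TER tables
it targets exist only as published figures. `synth` generates datasets with
the structure the model assumes — TER linear in time at fixed temperature,
slope exponential in temperature, additive homoscedastic Gaussian noise on
TER (a heteroscedastic option scales σ with TER; the residual structure of
the source data is unreported, so homoscedastic is the default). Default
grids mimic the experimental designs: 40–46 °C in 1 °C steps, times
{15, 30, 45, 60, 90, 120} min, ~1–2 h sessions. Presets carry the published
parameter rows verbatim as generating truths (CHO-like: o = 0.97, b = 0.95,
Tg = 48.07 °C; C3H-like: o = 1.02, b = 0.91, Tg = 46.60 °C; M8013
thermotolerant/non-thermotolerant: b = 0.50/1.09, Tg = 46.34/46.47 °C,
o = 1). Noisy TER values are floored at 0.01 to keep the dataset invariant
TER > 0. All generators take an explicit integer seed (default 0) through
`numpy.random.default_rng`.

What passing tests show — and what they do not: round-trip recovery on
synthetic surfaces demonstrates the estimators are consistent and correctly
implemented under the model's own assumptions; it cannot validate the model
against real biology (thermotolerance induction, cell-cycle effects, oxygen
dynamics and digitisation noise are all absent from the generator).

## Numerical choices

* Internal absolute-temperature unit is Kelvin; entry points needing
  absolute temperature take a `{K, C}` unit tag and convert once. The TER
  law and thermal doses depend only on T − Tg and accept any consistent
  scale; files store Celsius.
* Rates at the TER layer are per minute; the 1/s Eyring prefactor is never
  propagated into a′.
* `isoeffect_dose` uses the cancellation-free quadratic root
  2·target/(α + √(α² + 4β·target)), stable as β → 0; back-substitution
  reproduces the target to ~1e−10.
* Quadrature tolerance for `delta_g_numeric` defaults to 1e−9·(|ΔG₀| + 1)
  absolute; non-convergence raises with diagnostics.
* Exponentials are guarded at an argument of 700 and raise a numeric error
  with the offending exponent rather than overflowing.
* Simulation-based tests use 60–100 seeded replicates on the
  5-temperature × 5-time reference design, which keeps the whole suite
  under ~10 s while leaving the binomial noise of coverage checks small.

## Limitations

* Sequential (non-simultaneous) heating–irradiation intervals, heat-only
  outcome prediction, tumour-control probability, fractionation arithmetic
  and oxygen effects are out of scope.
* The biphasic behaviour around 43 °C is supported only through the two-b
  thermal-dose option; no cut-temperature estimation is attempted.
* Above Tg the linear heat-capacity model changes branch (A − B|T − Tg|);
  the closed-form free energy is intended for the hyperthermia regime
  T ≤ Tg.
* Fits assume independent homoscedastic errors; errors-in-variables
  treatment of digitised data is not attempted.
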