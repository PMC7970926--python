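"""Parameter estimation: two-stage, nonlinear, and log-linear fits."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from thermoter import (
    FitError,
    InvalidInputError,
    TERDataset,
    TERParams,
    fit_ht_quadratic,
    fit_ter_from_alpha_beta,
    fit_ter_nls,
    fit_ter_two_stage,
    gen_alpha_beta_dataset,
    gen_ter_dataset,
    make_config,
    r_squared,
    ter,
)
from thermoter.synth import PRESETS


def noiseless_dataset(params: TERParams, temps=(41, 42, 43, 44, 45), times=(15, 30, 60, 90, 120)):
    cfg = make_config("custom", ter_params=params, temperatures=tuple(map(float, temps)),
                      times=tuple(map(float, times)), sigma=0.0)
    return gen_ter_dataset(cfg)


class TestTwoStage:
    @pytest.mark.parametrize("preset", sorted(PRESETS))
    def test_noiseless_recovery_of_published_rows(self, preset):
        """Self-consistency: refitting noiseless model surfaces generated from
        each published parameter row returns the generating values."""
        truth = PRESETS[preset]
        res = fit_ter_two_stage(noiseless_dataset(truth))
        assert res.o == pytest.approx(truth.o, rel=1e-6)
        assert res.b == pytest.approx(truth.b, rel=1e-6)
        assert res.Tg == pytest.approx(truth.Tg, rel=1e-6)
        assert res.a_prime == 1.0
        assert res.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_single_temperature_is_degenerate(self):
        truth = PRESETS["cho_like"]
        with pytest.raises(FitError):
            fit_ter_two_stage(noiseless_dataset(truth, temps=(43,)))

    def test_fixed_tg_mode_fits_a_prime(self):
        """Fixing Tg at a shifted value re-expresses the same fit through a'."""
        truth = TERParams(o=1.0, a_prime=1.0, b=0.8, Tg=47.0)
        res = fit_ter_two_stage(noiseless_dataset(truth), Tg_fixed=45.0)
        assert res.Tg == 45.0
        # a' * exp(-b*Tg_fixed) must match exp(-b*Tg_true)
        assert res.a_prime * np.exp(-res.b * 45.0) == pytest.approx(
            np.exp(-truth.b * truth.Tg), rel=1e-9
        )

    def test_temperature_shift_equivariance(self):
        """Shifting all temperatures by dT shifts Tg by dT and leaves b alone."""
        truth = TERParams(o=1.0, a_prime=1.0, b=0.9, Tg=46.5)
        base = fit_ter_two_stage(noiseless_dataset(truth))
        shifted_truth = TERParams(o=1.0, a_prime=1.0, b=0.9, Tg=46.5 + 2.0)
        shifted = fit_ter_two_stage(noiseless_dataset(shifted_truth, temps=(43, 44, 45, 46, 47)))
        assert shifted.b == pytest.approx(base.b, rel=1e-9)
        assert shifted.Tg == pytest.approx(base.Tg + 2.0, rel=1e-9)

    def test_nonpositive_slope_excluded_with_warning(self, caplog):
        """A temperature whose TER does not grow with time is dropped from stage 2."""
        truth = PRESETS["cho_like"]
        d = noiseless_dataset(truth, temps=(42, 43, 44, 45))
        # corrupt the 42 C stratum to a decreasing trend
        ter_vals = d.ter.copy()
        mask = d.temperature == 42.0
        ter_vals[mask] = 1.5 - 0.001 * d.time[mask]
        d2 = TERDataset(temperature=d.temperature, time=d.time, ter=ter_vals)
        with caplog.at_level("WARNING"):
            res = fit_ter_two_stage(d2)
        assert 42.0 in res.extra["excluded_temperatures"]
        assert res.b == pytest.approx(truth.b, rel=1e-6)


class TestNLS:
    def test_matches_two_stage_on_noiseless_data(self):
        truth = PRESETS["cho_like"]
        d = noiseless_dataset(truth)
        ts = fit_ter_two_stage(d)
        nls = fit_ter_nls(d)
        assert nls.b == pytest.approx(ts.b, rel=1e-6)
        assert nls.Tg == pytest.approx(ts.Tg, rel=1e-6)
        assert nls.o == pytest.approx(ts.o, rel=1e-6)

    @settings(deadline=None, max_examples=25)
    @given(
        b=st.floats(0.3, 1.5),
        Tg=st.floats(44.0, 50.0),
        o=st.floats(0.9, 1.1),
    )
    def test_estimator_consistency_randomized(self, b, Tg, o):
        """Two independent estimators agree on noiseless model data."""
        truth = TERParams(o=o, a_prime=1.0, b=b, Tg=Tg)
        d = noiseless_dataset(truth)
        ts = fit_ter_two_stage(d)
        nls = fit_ter_nls(d)
        assert nls.b == pytest.approx(ts.b, rel=1e-6)
        assert nls.Tg == pytest.approx(ts.Tg, rel=1e-6)
        assert ts.b == pytest.approx(b, rel=1e-6)
        assert ts.Tg == pytest.approx(Tg, rel=1e-6)

    def test_joint_a_prime_tg_refused(self):
        d = noiseless_dataset(PRESETS["cho_like"])
        with pytest.raises(FitError, match="unidentifiable"):
            fit_ter_nls(d, fixed={})

    def test_constant_ter_flagged(self):
        n = 10
        d = TERDataset(
            temperature=np.repeat([41.0, 43.0], n // 2),
            time=np.tile([10.0, 20.0, 30.0, 40.0, 50.0], 2),
            ter=np.full(n, 1.3),
        )
        with pytest.raises(FitError):
            fit_ter_nls(d)

    def test_noisy_recovery_median_error(self):
        """Monte-Carlo recovery: median relative error of b stays below 10%
        at the reference design with sigma=0.1 additive noise."""
        truth = PRESETS["cho_like"]
        errs = []
        for seed in range(60):
            cfg = make_config(
                "custom", ter_params=truth, sigma=0.1, seed=seed,
                temperatures=(41.0, 42.0, 43.0, 44.0, 45.0),
                times=(15.0, 30.0, 60.0, 90.0, 120.0),
            )
            res = fit_ter_nls(gen_ter_dataset(cfg))
            errs.append(abs(res.b - truth.b) / truth.b)
        assert float(np.median(errs)) <= 0.10


class TestAlphaBetaFit:
    def test_noiseless_recovery_published_row(self):
        """Round-trip through the LQ-coefficient chain recovers (b, Tg)."""
        truth = PRESETS["m8013ntt_like"]  # b=1.09, Tg=46.47
        cfg = make_config("m8013ntt_like", temperatures=(42.0, 43.0, 44.0, 45.0, 46.0))
        ds = gen_alpha_beta_dataset(cfg, t=30.0)
        res = fit_ter_from_alpha_beta(ds)
        assert res.b == pytest.approx(truth.b, rel=1e-9)
        assert res.Tg == pytest.approx(truth.Tg, rel=1e-9)
        assert res.o == 1.0
        assert res.r_squared == pytest.approx(1.0, abs=1e-10)
        assert res.extra["r_squared_beta"] == pytest.approx(1.0, abs=1e-10)

    def test_record_below_baseline_excluded(self, caplog):
        cfg = make_config("m8013ntt_like", temperatures=(42.0, 43.0, 44.0, 45.0, 46.0))
        ds = gen_alpha_beta_dataset(cfg, t=30.0)
        alpha = ds.alpha.copy()
        alpha[0] = 0.5 * ds.alpha0  # TER_alpha < 1: log undefined
        from thermoter import AlphaBetaDataset

        ds2 = AlphaBetaDataset(
            temperature=ds.temperature, alpha=alpha, beta=ds.beta,
            alpha0=ds.alpha0, beta0=ds.beta0, time=ds.time,
        )
        with caplog.at_level("WARNING"):
            res = fit_ter_from_alpha_beta(ds2)
        assert res.extra["n_excluded"] == 1
        assert any("excluded" in r.message for r in caplog.records)

    def test_noisy_alpha_clean_beta(self):
        """Noise confined to the alpha channel degrades the pooled fit while
        the beta-derived TER values stay exactly on the generating law."""
        cfg = make_config("m8013ntt_like", temperatures=(42.0, 43.0, 44.0, 45.0, 46.0),
                          sigma=0.0, seed=7)
        ds = gen_alpha_beta_dataset(cfg, t=30.0, sigma_alpha=0.25)
        res = fit_ter_from_alpha_beta(ds)
        assert res.r_squared < 1.0 - 1e-6
        clean = np.asarray(ter(30.0, ds.temperature, cfg.ter_params))
        np.testing.assert_allclose(res.extra["ter_beta"], clean, rtol=1e-9)

    def test_too_few_usable_points(self):
        from thermoter import AlphaBetaDataset

        ds = AlphaBetaDataset(
            temperature=np.array([42.0, 44.0]),
            alpha=np.array([0.2, 0.25]),  # both below alpha0=0.3 -> TER_a < 1
            beta=np.array([0.02, 0.025]),  # both below beta0 -> TER_b < 1
            alpha0=0.3, beta0=0.03, time=30.0,
        )
        with pytest.raises(FitError):
            fit_ter_from_alpha_beta(ds)


class TestQuadraticAndR2:
    def test_exact_quadratic_recovery(self):
        x = np.array([5.0, 10.0, 20.0, 40.0, 80.0])
        y = 0.01 * x + 0.002 * x**2
        (p1, p2), r2 = fit_ht_quadratic(x, y)
        assert p1 == pytest.approx(0.01, rel=1e-9)
        assert p2 == pytest.approx(0.002, rel=1e-9)
        assert r2 == pytest.approx(1.0)

    def test_all_zero_response(self):
        x = np.array([1.0, 2.0, 3.0])
        coef, _ = fit_ht_quadratic(x, np.zeros(3))
        assert coef == pytest.approx((0.0, 0.0), abs=1e-12)

    def test_intercept_mode_needs_three_points(self):
        with pytest.raises(FitError):
            fit_ht_quadratic(np.array([1.0, 2.0]), np.array([0.1, 0.2]), through_origin=False)

    def test_thermal_dose_rescaling_collapses_curves(self):
        """Rescaling time by exp(b*(T-Tref)) collapses heat-kill curves from
        different temperatures onto one quadratic (higher R^2 than raw time)."""
        from thermoter.synth import gen_ht_neg_log_s

        cfg = make_config("cho_like", temperatures=(42.0, 43.0, 44.0, 45.0), sigma=0.0)
        df = gen_ht_neg_log_s(cfg, p1=0.01, p2=0.0002)
        b = cfg.ter_params.b
        T_ref = max(cfg.temperatures)
        x_raw = df["time_min"].to_numpy()
        x_scaled = x_raw * np.exp(b * (df["temperature_C"].to_numpy() - T_ref))
        y = df["neg_log_s"].to_numpy()
        _, r2_raw = fit_ht_quadratic(x_raw, y)
        coef, r2_scaled = fit_ht_quadratic(x_scaled, y)
        assert r2_scaled == pytest.approx(1.0, abs=1e-10)
        assert r2_scaled > r2_raw
        assert coef == pytest.approx((0.01, 0.0002), rel=1e-8)

    def test_r_squared_worked_cases(self):
        obs = np.array([1.0, 2.0, 3.0])
        assert r_squared(obs, obs) == pytest.approx(1.0)
        assert r_squared(obs, np.full(3, obs.mean())) == pytest.approx(0.0)
        assert r_squared(obs, np.array([1.0, 2.0, 4.0])) == pytest.approx(0.5)
        with pytest.raises(InvalidInputError):
            r_squared(np.ones(3), np.ones(3))
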