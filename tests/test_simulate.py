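"""Synthetic generator: environment processes, truth surfaces, yields."""

import numpy as np
import pandas as pd
import pytest

from cropfda import (
    Bump,
    EnvProcessConfig,
    NoiseModel,
    TrueSurface,
    apply_holidays,
    evaluate_true_surface,
    make_synthetic_study,
    simulate_environment,
    simulate_yield,
    weekday_holiday,
)
from cropfda.simulate import CoverageError


def test_degenerate_process_is_constant():
    cfg = EnvProcessConfig(mean_level=21.5, cadence_minutes=10)
    s = simulate_environment(cfg, "2021-01-01", 3, seed=0)
    assert np.allclose(s.to_numpy(), 21.5)


def test_environment_deterministic_under_seed():
    cfg = EnvProcessConfig(18.0, 5.0, 280.0, 3.0, 0.6, cadence_minutes=10)
    a = simulate_environment(cfg, "2021-01-01", 30, seed=7)
    b = simulate_environment(cfg, "2021-01-01", 30, seed=7)
    assert a.equals(b)


def test_minute_cadence_point_count():
    """A 1172-day study at 1-minute cadence is on the order of 2M points."""
    cfg = EnvProcessConfig(mean_level=18.0, cadence_minutes=1)
    s = simulate_environment(cfg, "2019-10-01", 1172, seed=0)
    assert len(s) == 1172 * 1440


def test_nonneg_clips_at_zero():
    cfg = EnvProcessConfig(1.0, 0.0, 0.0, 5.0, 0.0, cadence_minutes=60, nonneg=True)
    s = simulate_environment(cfg, "2021-01-01", 60, seed=1)
    assert (s >= 0).all()
    assert (s == 0).any()  # the heavy noise must actually hit the clip


def test_invalid_n_days_raises():
    with pytest.raises(ValueError):
        simulate_environment(EnvProcessConfig(10.0), "2021-01-01", 0)


def test_true_surface_empty_is_zero():
    surf = TrueSurface(0, ())
    assert evaluate_true_surface(surf, 12.3, 200.0) == 0.0


def test_true_surface_peak_and_off_center():
    b = Bump(center_s=45.0, center_t=150.0, amplitude=0.04, width_s=10.0, width_t=50.0)
    surf = TrueSurface(0, (b,))
    assert np.isclose(evaluate_true_surface(surf, 45.0, 150.0), 0.04)
    expected = 0.04 * np.exp(-((30.0 - 45.0) ** 2) / (2 * 100.0) - ((100.0 - 150.0) ** 2) / (2 * 2500.0))
    assert np.isclose(evaluate_true_surface(surf, 30.0, 100.0), expected)


def _flat_env(value, start, n_days, cadence=60):
    cfg = EnvProcessConfig(mean_level=value, cadence_minutes=cadence)
    return simulate_environment(cfg, start, n_days, seed=0)


def test_yield_zero_surfaces_is_zero():
    env = [_flat_env(20.0, "2021-01-01", 100)]
    y, sig = simulate_yield(env, [TrueSurface(0, ())], NoiseModel(0.0), 30, "2021-02-01")
    assert np.allclose(y.to_numpy(), 0.0)
    assert np.allclose(sig.to_numpy(), 0.0)


def test_yield_constant_env_constant_surface():
    """x ≡ c and β ≡ b integrate to J·c·b·lag_days at every date."""
    c_val, b_val, lag = 20.0, 0.03, 30
    env = [_flat_env(c_val, "2021-01-01", 100)] * 2
    const = TrueSurface(0, (Bump(0.0, 0.0, b_val, 1e9, 1e9),))
    y, _ = simulate_yield(env, [const, const], NoiseModel(0.0), lag, "2021-02-01")
    assert np.allclose(y.to_numpy(), 2 * c_val * b_val * lag, rtol=1e-9)


def test_yield_matches_trapezoid_oracle():
    """One bump surface, sinusoidal environment: independent trapezoid check."""
    cfg = EnvProcessConfig(mean_level=15.0, annual_amplitude=6.0, annual_phase=40.0,
                           cadence_minutes=60)
    env = simulate_environment(cfg, "2021-01-01", 120, seed=0)
    surf = TrueSurface(0, (Bump(20.0, 60.0, 0.05, 8.0, 40.0),))
    lag, origin = 40, "2021-01-01"
    dates = pd.date_range("2021-02-15", periods=10, freq="D")
    y, _ = simulate_yield([env], [surf], NoiseModel(0.0), lag, origin,
                          harvest_dates=dates)
    daily = env.resample("D").mean()
    for d, got in y.items():
        t = (d - pd.Timestamp(origin)).days % 365.0
        want = 0.0
        for k in range(lag):
            x_k = daily.loc[d - pd.Timedelta(days=k + 1)]
            sg = np.linspace(k, k + 1, 501)
            want += x_k * np.trapezoid(surf(sg, t), sg)
        assert abs(got - want) < 1e-6 * max(1.0, abs(want))


def test_yield_insufficient_history_raises():
    env = [_flat_env(20.0, "2021-01-01", 50)]
    surf = TrueSurface(0, ())
    with pytest.raises(CoverageError):
        simulate_yield(env, [surf], NoiseModel(0.0), 30, "2021-01-01",
                       harvest_dates=pd.date_range("2021-01-10", periods=5))


def test_holidays_identity_when_rule_matches_nothing():
    y = pd.Series(np.arange(10.0), index=pd.date_range("2021-01-01", periods=10))
    out = apply_holidays(y, lambda d: False)
    assert out.equals(y)


def test_holidays_weekly_removes_exact_count():
    y = pd.Series(1.0, index=pd.date_range("2021-01-01", periods=70))
    rule = weekday_holiday(2)
    out = apply_holidays(y, rule)
    assert len(y) - len(out) == 10
    removed = set(y.index) - set(out.index)
    assert removed == {d for d in y.index if rule(d)}


def test_holidays_removing_everything_raises():
    y = pd.Series(1.0, index=pd.date_range("2021-01-01", periods=5))
    with pytest.raises(ValueError):
        apply_holidays(y, lambda d: True)


def test_study_deterministic_and_covered():
    a = make_synthetic_study(seed=3, cadence_minutes=60)
    b = make_synthetic_study(seed=3, cadence_minutes=60)
    assert a.yield_daily.equals(b.yield_daily)
    assert a.env_raw[0].equals(b.env_raw[0])
    a.check_coverage()
    # holidays removed a strict subset of the date range
    assert len(a.yield_daily) < (a.yield_daily.index[-1] - a.yield_daily.index[0]).days + 1


def test_study_noise_calibration():
    ds = make_synthetic_study(seed=5, cadence_minutes=60, noise_frac=0.10)
    signal_sd = float(np.std(ds.signal.to_numpy() - 60.0))
    assert np.isclose(ds.noise.sd, 0.1 * signal_sd, rtol=1e-6)
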