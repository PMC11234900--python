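"""Canned simulation experiments: surface recovery, model comparison, leakage.

These functions run the full pipeline — generator → preprocessing →
functionalization → penalized fit with information-criterion selection — on
synthetic data with known truth, and measure how well the method does.  They
are used both by the test suite and by the results-reproduction script, so
the numbers those two report are computed by the same code path.

Problem sizes are scaled for a desk machine: sensor cadence of 10 minutes
(the hourly averaging step makes finer cadence statistically equivalent),
six pooled seasons sampled every sixth harvest day for the recovery study
(n ≈ 280 with ~6 cross-year replicates per season-time), and four seasons
for the forecasting experiments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .basis import BasisSystem
from .evaluation import RollingProtocol, rolling_forecast, windowed_rmse
from .model import VCFRMSpec, functionalize, surface_grid
from .preprocess import build_lag_windows, center, hourly_average, moving_average_yield
from .selection import SelectionGrid, select
from .simulate import SimulatedDataset, make_synthetic_study

#: wider-than-default ladder so the chosen smoothness is interior, not clipped
RECOVERY_GRID = np.logspace(-4, 6, 11)
#: t-ladder with the t-constant (FRM) limit as its top rung
T_GRID_WITH_LIMIT = np.append(RECOVERY_GRID, np.inf)


def pipeline_samples(
    ds: SimulatedDataset,
    window_days: int = 7,
    min_present: int = 4,
    subsample_step: int = 1,
):
    """Standard preprocessing of a simulated dataset into aligned samples."""
    env_h = [hourly_average(s) for s in ds.env_raw]
    resp = moving_average_yield(
        ds.yield_daily, window_days=window_days, min_present=min_present
    )
    if subsample_step > 1:
        resp = resp.iloc[::subsample_step]
    return build_lag_windows(env_h, resp, ds.lag_days, ds.season_origin)


def default_specs(
    lag_days: int = 60,
    t_domain: tuple[float, float] = (0.0, 335.0),
    n_basis_s: int = 10,
    n_basis_t: int = 10,
    intercept: bool = True,
) -> tuple[VCFRMSpec, VCFRMSpec]:
    """(VCFRM, FRM) spec templates with the default basis systems."""
    sb = BasisSystem((0.0, float(lag_days)), n_basis_s)
    tb = BasisSystem(t_domain, n_basis_t)
    vc = VCFRMSpec(J=2, s_basis=sb, t_basis=tb, intercept=intercept)
    fr = VCFRMSpec(J=2, s_basis=sb, t_basis=tb, model_kind="constant-in-t")
    return vc, fr


@dataclass
class RecoveryResult:
    n: int
    chosen: tuple[float, float]
    rel_l2_error: float
    peak_s: float
    peak_t: float
    true_peak_s: float
    true_peak_t: float


def surface_recovery(
    seed: int,
    n_years: int = 6,
    subsample_step: int = 6,
    cadence_minutes: int = 10,
    rho: float = 1.0,
) -> RecoveryResult:
    """Fit the model on synthetic truth and measure surface recovery.

    Six seasons pooled on the day-of-season axis, harvests sampled every
    sixth day (n ≈ 280), yield noise sd at 10 % of the signal sd.  The
    smoothness pair is chosen by GCV over ``RECOVERY_GRID``; the relative L2
    error pools both coefficient surfaces over s ∈ [0, 60] and the
    well-covered interior t ∈ [30, 300] (penalized spline surfaces are
    unreliable at the season-axis boundaries, where data are thin).  The
    peak location is the argmax of the temperature surface, compared with
    the generating positive bump.
    """
    ds = make_synthetic_study(
        seed=seed, cadence_minutes=cadence_minutes, n_years=n_years
    )
    samples = pipeline_samples(ds, subsample_step=subsample_step)
    centered, info = center(samples)
    vc, _ = default_specs(lag_days=ds.lag_days)
    fs = functionalize(centered, vc.s_basis, rho=rho)
    grid = SelectionGrid(RECOVERY_GRID, T_GRID_WITH_LIMIT)
    res = select(fs, vc, grid, centering=info)
    s_grid = np.linspace(0.0, float(ds.lag_days), 61)
    t_grid = np.linspace(30.0, 300.0, 91)
    num = den = 0.0
    for j in range(2):
        est = surface_grid(res.fit, j, s_grid, t_grid)
        tru = ds.truth[j](s_grid[:, None], t_grid[None, :])
        num += np.sum((est - tru) ** 2)
        den += np.sum(tru ** 2)
    est0 = surface_grid(res.fit, 0, s_grid, t_grid)
    i, k = np.unravel_index(np.argmax(est0), est0.shape)
    pos_bump = max(ds.truth[0].bumps, key=lambda b: b.amplitude)
    return RecoveryResult(
        n=len(samples),
        chosen=res.chosen,
        rel_l2_error=float(np.sqrt(num / den)),
        peak_s=float(s_grid[i]),
        peak_t=float(t_grid[k]),
        true_peak_s=pos_bump.center_s,
        true_peak_t=pos_bump.center_t,
    )


def forecast_experiment(
    seed: int,
    kind: str = "t-varying",
    n_years: int = 4,
    subsample_step: int = 4,
    cadence_minutes: int = 10,
    rho: float = 1.0,
    gap: int = 6,
) -> pd.DataFrame:
    """Rolling-origin forecasts of the final season, VCFRM vs FRM.

    The first ``n_years − 1`` seasons (plus the already-elapsed part of the
    last) train the models; each harvest index of the final season is a
    forecast origin.  Smoothness weights are selected once, at the first
    origin, on its training set.
    """
    ds = make_synthetic_study(
        seed=seed, cadence_minutes=cadence_minutes, n_years=n_years, kind=kind
    )
    samples = pipeline_samples(ds, subsample_step=subsample_step)
    vc, fr = default_specs(lag_days=ds.lag_days)
    season_start = ds.season_origin + pd.Timedelta(days=365 * (n_years - 1))
    test_idx = [s.index for s in samples if s.harvest_date >= season_start]
    protocol = RollingProtocol(
        test_indices=test_idx,
        gap=gap,
        selection=SelectionGrid(RECOVERY_GRID, T_GRID_WITH_LIMIT),
        reselect_every=0,
        rho=rho,
    )
    return rolling_forecast(samples, vc, fr, protocol)


def test_rmse(records: pd.DataFrame, model: str) -> float:
    e = records["y_true"].to_numpy() - records[model].to_numpy()
    return float(np.sqrt(np.mean(e ** 2)))


def model_comparison(
    seed: int, kind: str, n_replicates: int = 20, **kwargs
) -> pd.DataFrame:
    """Replicated VCFRM-vs-FRM test RMSEs on freshly simulated studies."""
    ss = np.random.SeedSequence(seed)
    rows = []
    for rep, child in enumerate(ss.spawn(n_replicates)):
        rep_seed = int(child.generate_state(1)[0] % (2 ** 31))
        records = forecast_experiment(rep_seed, kind=kind, **kwargs)
        rows.append(
            {
                "replicate": rep,
                "seed": rep_seed,
                "rmse_vcfrm": test_rmse(records, "y_vcfrm"),
                "rmse_frm": test_rmse(records, "y_frm"),
            }
        )
    return pd.DataFrame(rows)


def leakage_contrast(seed: int, **kwargs) -> tuple[float, float]:
    """Test RMSE with the leakage gap (6) vs deliberately leaking (gap 0).

    The 7-day forward moving-average response makes the last six training
    indices overlap the forecast week; admitting them (and the origin itself)
    into training exploits that overlap, so the leaking protocol must score
    better than the honest one.
    """
    honest = forecast_experiment(seed, gap=6, **kwargs)
    leaky = forecast_experiment(seed, gap=0, **kwargs)
    return test_rmse(leaky, "y_vcfrm"), test_rmse(honest, "y_vcfrm")
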