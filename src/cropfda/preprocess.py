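"""From raw sensor and yield series to aligned regression samples.

Four steps, in the order the analysis applies them:

1. hourly averaging of each raw sensor stream (half-open clock-hour bins);
2. a forward 7-day moving average of the daily yield, which both smooths the
   response and bridges facility-holiday gaps;
3. extraction, for each response date, of the hourly environmental history
   over the preceding lag window (60 days for strawberry-style data, 80 for
   tomato-style), on the s axis "days before harvest";
4. centering of both the response and the predictor windows, with the
   training means stored so held-out data can be centered without leakage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .simulate import _season_time

logger = logging.getLogger(__name__)


class EmptyDataError(ValueError):
    pass


@dataclass
class AlignedSample:
    """One harvest date ready for regression.

    ``y`` is the 7-day moving-average yield; ``windows[j]`` holds the hourly
    means of predictor j on the lag axis, index k covering
    s ∈ [k/24, (k+1)/24) days before harvest (k=0 is the hour just before
    harvest midnight); NaN marks missing hours.  ``t`` is the day-of-season.
    """

    index: int
    harvest_date: pd.Timestamp
    t: float
    y: float
    windows: list[np.ndarray]
    lag_days: int

    @property
    def s_grid(self) -> np.ndarray:
        """Hourly cell midpoints on [0, lag_days), in days before harvest."""
        return (np.arange(self.lag_days * 24) + 0.5) / 24.0


@dataclass
class CenteringInfo:
    """Training means: scalar y mean and one mean hourly profile per predictor."""

    y_mean: float
    x_mean_curves: list[np.ndarray]


def hourly_average(series: pd.Series) -> pd.Series:
    """Hourly means of a raw sensor stream.

    Each clock hour [h, h+1) maps to the arithmetic mean of the raw samples
    falling in it; hours with no samples are NaN (absence, not zero).
    """
    if series.empty:
        raise EmptyDataError("empty sensor series")
    return series.resample("h").mean()


def moving_average_yield(
    yields: pd.Series, window_days: int = 7, min_present: int = 4
) -> pd.Series:
    """Forward moving average of the daily yield.

    The response at harvest date d is the mean of the available yields on
    calendar days [d, d + window_days − 1]; it is emitted only for observed
    harvest dates whose window contains at least ``min_present`` values, so a
    near-empty week cannot masquerade as a weekly average.
    """
    if window_days < 1:
        raise ValueError("window_days must be >= 1")
    if yields.empty:
        raise EmptyDataError("empty yield series")
    full = yields.asfreq("D")
    arr = full.to_numpy(dtype=float)
    n = arr.size
    out_idx, out_val = [], []
    for i, d in enumerate(full.index):
        if np.isnan(arr[i]):
            continue  # not a harvest date
        window = arr[i : min(i + window_days, n)]
        present = np.isfinite(window)
        if present.sum() >= min_present:
            out_idx.append(d)
            out_val.append(float(window[present].mean()))
    return pd.Series(out_val, index=pd.DatetimeIndex(out_idx), name="y")


def build_lag_windows(
    hourly_env: list[pd.Series],
    response: pd.Series,
    lag_days: int,
    season_origin,
    max_gap_hours: int = 24,
) -> list[AlignedSample]:
    """Attach each response date to its hourly lag windows.

    For response date d, predictor j's window covers [d − lag_days, d) hour
    by hour; dates whose windows miss more than ``max_gap_hours`` cells in any
    predictor are dropped with a logged reason (short gaps are left to the
    basis smoother).  Output order is chronological; every emitted value
    traces to a raw hourly cell — nothing is imputed here.
    """
    if lag_days < 1:
        raise ValueError("lag_days must be >= 1")
    n_cells = lag_days * 24
    t_vals = _season_time(response.index, season_origin)
    samples: list[AlignedSample] = []
    hours_back = pd.to_timedelta(np.arange(1, n_cells + 1), unit="h")
    for i, (d, y) in enumerate(response.items()):
        stamps = pd.Timestamp(d) - hours_back
        windows = []
        ok = True
        for j, env in enumerate(hourly_env):
            w = env.reindex(stamps).to_numpy(dtype=float)
            n_missing = int(np.isnan(w).sum())
            if n_missing > max_gap_hours:
                logger.info(
                    "dropping %s: predictor %d missing %d hourly cells "
                    "(max_gap_hours=%d)", d, j, n_missing, max_gap_hours
                )
                ok = False
                break
            windows.append(w)
        if ok:
            samples.append(
                AlignedSample(
                    index=len(samples) + 1,
                    harvest_date=pd.Timestamp(d),
                    t=float(t_vals[i]),
                    y=float(y),
                    windows=windows,
                    lag_days=lag_days,
                )
            )
    return samples


def center(
    samples: list[AlignedSample], info: CenteringInfo | None = None
) -> tuple[list[AlignedSample], CenteringInfo]:
    """Subtract sample means from y and each predictor window.

    Training mode (``info=None``) computes means from the given samples;
    test mode subtracts the stored training means, so held-out samples never
    influence the centering.  Missing hourly cells are ignored when forming
    the mean profiles and remain missing afterwards.
    """
    if info is None:
        if not samples:
            raise EmptyDataError("cannot compute centering from an empty set")
        y_mean = float(np.mean([s.y for s in samples]))
        J = len(samples[0].windows)
        curves = []
        for j in range(J):
            stack = np.stack([s.windows[j] for s in samples])
            with np.errstate(invalid="ignore"):
                curves.append(np.nanmean(stack, axis=0))
        info = CenteringInfo(y_mean=y_mean, x_mean_curves=curves)
    out = []
    for s in samples:
        out.append(
            replace(
                s,
                y=s.y - info.y_mean,
                windows=[w - m for w, m in zip(s.windows, info.x_mean_curves)],
            )
        )
    return out, info


def uncenter_y(y: np.ndarray, info: CenteringInfo) -> np.ndarray:
    """Map centered responses/predictions back to original units."""
    return np.asarray(y) + info.y_mean


def uncenter(
    samples: list[AlignedSample], info: CenteringInfo
) -> list[AlignedSample]:
    """Exact inverse of :func:`center` with the same ``info``."""
    out = []
    for s in samples:
        out.append(
            replace(
                s,
                y=s.y + info.y_mean,
                windows=[w + m for w, m in zip(s.windows, info.x_mean_curves)],
            )
        )
    return out
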