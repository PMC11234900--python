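"""Rolling-origin forecast evaluation and the VCFRM-vs-FRM comparison.

The forecasting experiment mimics how a grower would use the model: at each
origin n0 (one per test-period harvest index) the model is trained on past
data only and predicts the single observation i = n0 — the average yield of
the coming week.  Because the response at index i is a forward 7-day moving
average, the responses at indices n0−5,…,n0−1 overlap the week being
predicted; the training set is therefore truncated at i = n0 − 6 (a 6-index
gap), which is exactly what prevents the leak.  Centering and smoothness
selection are likewise computed from the training window only.

Forecast accuracy is summarized by the 30-day windowed RMSE

    RMSE_i = sqrt( (1/30) Σ_{j=i}^{i+30} (y_j − ŷ_j)² ),

implemented exactly as printed — the sum has 31 terms over a divisor of 30,
so a constant error e yields |e|·sqrt(31/30).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import (
    FunctionalSample,
    VCFRMSpec,
    fit as model_fit,
    functionalize,
    predict,
    resolve_spec,
)
from .preprocess import AlignedSample, center
from .selection import SelectionGrid, select

logger = logging.getLogger(__name__)


class ProtocolError(ValueError):
    pass


def training_indices(n0: int, gap: int = 6) -> range:
    """Training observation indices for forecast origin n0: 1, …, n0 − gap.

    With the default gap of 6 this is the leakage-safe protocol for a 7-day
    forward moving-average response; gap=0 deliberately admits the test index
    into training and is used only to demonstrate the leak.
    """
    return range(1, n0 - gap + 1)


@dataclass
class RollingProtocol:
    """Configuration of the rolling-origin experiment.

    ``test_indices`` are 1-based observation indices (the held-out final
    season); ``gap`` is the number of trailing indices excluded from training
    (default 6 — one less than the response window length); smoothness
    selection runs on the first origin's training set and is refreshed every
    ``reselect_every`` origins.
    """

    test_indices: list[int]
    gap: int = 6
    min_train: int = 50
    refit_per_origin: bool = True
    selection: SelectionGrid = field(default_factory=SelectionGrid)
    reselect_every: int = 30
    rho: float | str = "gcv"

    def __post_init__(self) -> None:
        self.test_indices = sorted(int(i) for i in self.test_indices)
        if not self.test_indices:
            raise ProtocolError("empty test index set")
        if self.gap < 0:
            raise ProtocolError("gap must be >= 0")


@dataclass
class AuditLog:
    """Records which sample indices each rolling step touched, and why."""

    touched: list[tuple[int, str, frozenset[int]]] = field(default_factory=list)

    def record(self, n0: int, purpose: str, indices) -> None:
        self.touched.append((n0, purpose, frozenset(int(i) for i in indices)))

    def violations(self, gap: int) -> list[tuple[int, str, set[int]]]:
        """Indices used for training/centering/selection beyond 1..n0−gap."""
        out = []
        for n0, purpose, idx in self.touched:
            if purpose == "predict":
                allowed = set(training_indices(n0, gap)) | {n0}
            else:
                allowed = set(training_indices(n0, gap))
            extra = set(idx) - allowed
            if extra:
                out.append((n0, purpose, extra))
        return out


def rolling_forecast(
    samples: list[AlignedSample],
    vcfrm_template: VCFRMSpec,
    frm_template: VCFRMSpec,
    protocol: RollingProtocol,
    audit: AuditLog | None = None,
) -> pd.DataFrame:
    """One-step-ahead rolling predictions of both models over the test indices.

    For each origin n0: train on observation indices 1…n0−gap, center the
    training set, smooth to functional data, select smoothness weights
    (first origin, refreshed every ``reselect_every`` origins), fit VCFRM and
    FRM, then center the single test observation n0 with the *training*
    centering and predict it.  Returns one row per origin with columns
    ``n0, date, t, y_true, y_vcfrm, y_frm``.
    """
    ordered = sorted(samples, key=lambda s: s.harvest_date)
    by_index = {s.index: s for s in ordered}
    if len(by_index) != len(ordered):
        raise ProtocolError("duplicate sample indices")
    n_total = len(ordered)
    sel_v = sel_f = None
    origins_since_selection = None
    records = []
    for n0 in protocol.test_indices:
        if n0 not in by_index:
            raise ProtocolError(f"test index {n0} not present in the sample set")
        train_idx = [i for i in training_indices(n0, protocol.gap) if i in by_index]
        if len(train_idx) < protocol.min_train:
            raise ProtocolError(
                f"origin n0={n0}: only {len(train_idx)} training samples "
                f"(min_train={protocol.min_train})"
            )
        train = [by_index[i] for i in train_idx]
        if audit is not None:
            audit.record(n0, "center", train_idx)
            audit.record(n0, "train", train_idx)
        train_c, info = center(train)
        ftrain = functionalize(train_c, vcfrm_template.s_basis, rho=protocol.rho)
        need_selection = (
            origins_since_selection is None
            or (
                protocol.reselect_every
                and origins_since_selection >= protocol.reselect_every
            )
        )
        if need_selection:
            if audit is not None:
                audit.record(n0, "select", train_idx)
            sel_v = select(ftrain, vcfrm_template, protocol.selection).chosen
            frm_grid = SelectionGrid(
                lambda_s_values=protocol.selection.lambda_s_values,
                lambda_t_values=np.array([0.0]),
                criterion=protocol.selection.criterion,
                kappa=protocol.selection.kappa,
            )
            sel_f = select(ftrain, frm_template, frm_grid).chosen
            origins_since_selection = 0
        origins_since_selection += 1
        fit_v = model_fit(ftrain, resolve_spec(vcfrm_template, *sel_v), centering=info)
        fit_f = model_fit(ftrain, resolve_spec(frm_template, *sel_f), centering=info)
        test = by_index[n0]
        if audit is not None:
            audit.record(n0, "predict", [n0])
        test_c, _ = center([test], info)
        ftest = functionalize(test_c, vcfrm_template.s_basis, rho=protocol.rho)
        records.append(
            {
                "n0": n0,
                "date": test.harvest_date,
                "t": test.t,
                "y_true": test.y,
                "y_vcfrm": float(predict(fit_v, ftest)[0]),
                "y_frm": float(predict(fit_f, ftest)[0]),
            }
        )
    return pd.DataFrame.from_records(records).sort_values("n0", ignore_index=True)


def windowed_rmse(
    records: pd.DataFrame, model: str = "y_vcfrm", window: int = 30
) -> pd.Series:
    """30-day windowed RMSE trajectory, computed exactly as printed.

    RMSE_i sums the squared errors of records i…i+window (window+1 terms),
    divides by ``window``, and takes the square root; values are emitted only
    where the full window exists.  Indexed by the record position i.
    """
    if records.empty:
        return pd.Series(dtype=float, name=f"rmse_{model}")
    err2 = (records["y_true"].to_numpy() - records[model].to_numpy()) ** 2
    n = err2.size
    out_idx, out_val = [], []
    for i in range(n - window):
        out_idx.append(int(records["n0"].iloc[i]))
        out_val.append(float(np.sqrt(err2[i : i + window + 1].sum() / window)))
    return pd.Series(out_val, index=out_idx, name=f"rmse_{model}")


def compare_models(
    records: pd.DataFrame,
    season_bins: np.ndarray | None = None,
    window: int = 30,
) -> pd.DataFrame:
    """Per-season-bin RMSE of both models plus 30-day-window win counts.

    Rows are day-of-season bins (default: 90-day quarters of the season
    axis); columns give each model's plain RMSE within the bin and the
    number of 30-day windows starting in the bin that each model wins
    (smaller windowed RMSE).
    """
    if season_bins is None:
        season_bins = np.array([0.0, 90.0, 180.0, 270.0, 365.0])
    r_v = windowed_rmse(records, "y_vcfrm", window)
    r_f = windowed_rmse(records, "y_frm", window)
    win_v = (r_v.to_numpy() < r_f.to_numpy()) if len(r_v) else np.array([], bool)
    win_t = records.set_index("n0").loc[r_v.index, "t"].to_numpy() if len(r_v) else np.array([])
    rows = []
    t = records["t"].to_numpy()
    for lo, hi in zip(season_bins[:-1], season_bins[1:]):
        m = (t >= lo) & (t < hi)
        wm = (win_t >= lo) & (win_t < hi) if win_t.size else np.array([], bool)
        def _rmse(col):
            if not m.any():
                return np.nan
            e = records["y_true"].to_numpy()[m] - records[col].to_numpy()[m]
            return float(np.sqrt(np.mean(e**2)))
        rows.append(
            {
                "t_lo": float(lo),
                "t_hi": float(hi),
                "n_obs": int(m.sum()),
                "rmse_vcfrm": _rmse("y_vcfrm"),
                "rmse_frm": _rmse("y_frm"),
                "windows": int(wm.size),
                "vcfrm_wins": int(win_v[wm].sum()) if wm.size else 0,
                "frm_wins": int((~win_v[wm]).sum()) if wm.size else 0,
            }
        )
    return pd.DataFrame(rows)
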