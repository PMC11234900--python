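"""Rendering helpers: coefficient-surface contour maps and forecast plots."""

from __future__ import annotations

import numpy as np

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .model import VCFRMFit, surface_grid


def plot_surface(
    fit: VCFRMFit, j: int, n_s: int = 80, n_t: int = 80, ax=None, title=None
):
    """Contour map of β̂_j: lag days before harvest (x) vs day-of-season (y)."""
    s_lo, s_hi = fit.spec.s_basis.domain
    t_lo, t_hi = fit.spec.t_basis.domain
    s = np.linspace(s_lo, s_hi, n_s)
    t = np.linspace(t_lo, t_hi, n_t)
    M = surface_grid(fit, j, s, t)
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    lim = np.abs(M).max() or 1.0
    cs = ax.contourf(s, t, M.T, levels=15, cmap="RdBu_r", vmin=-lim, vmax=lim)
    ax.contour(s, t, M.T, levels=15, colors="k", linewidths=0.3)
    ax.set_xlabel("days before harvest (s)")
    ax.set_ylabel("day of season (t)")
    ax.set_title(title or f"coefficient surface, predictor {j}")
    plt.colorbar(cs, ax=ax)
    return ax


def plot_forecast(records, ax=None):
    """Actual vs predicted yields over the rolling test period."""
    if ax is None:
        _, ax = plt.subplots(figsize=(8, 3.5))
    ax.plot(records["date"], records["y_true"], "-", color="k", label="actual")
    ax.plot(records["date"], records["y_vcfrm"], "--", label="VCFRM")
    ax.plot(records["date"], records["y_frm"], ":", label="FRM")
    ax.set_xlabel("date")
    ax.set_ylabel("7-day mean yield")
    ax.legend()
    return ax


def plot_rmse_trajectory(rmse_vcfrm, rmse_frm, ax=None):
    """30-day windowed RMSE trajectories of both models."""
    if ax is None:
        _, ax = plt.subplots(figsize=(8, 3))
    ax.plot(rmse_vcfrm.index, rmse_vcfrm.to_numpy(), "--", label="VCFRM")
    ax.plot(rmse_frm.index, rmse_frm.to_numpy(), ":", label="FRM")
    ax.set_xlabel("forecast origin index")
    ax.set_ylabel("30-day RMSE")
    ax.legend()
    return ax
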