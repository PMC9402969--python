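"""Thickness-trend reporting: normalized I_opt and k_a versus light path,
plus predicted biomass-vs-irradiance curves.

The optimal irradiance I_opt rises with reactor thickness (deeper cultures
need more incident light to bring the depth-averaged level to the optimum),
while the fitted extinction coefficient k_a falls until it stabilizes at the
optical value near 0.1 m² g⁻¹ for thick reactors. I_opt is reported both raw
and normalized on a 413 µmol m⁻² s⁻¹ reference value, a conventional
reporting scale for this organism.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Mapping

import matplotlib
import numpy as np
import pandas as pd

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .estimation import FitResult
from .growth_model import KineticParams, steady_state_batch

__all__ = ["REFERENCE_I_OPT", "report_thickness_trends", "plot_trends",
           "plot_prediction_curves", "prediction_curve"]

#: Reference irradiance for the normalized I_opt' = I_opt / 413, µmol m⁻² s⁻¹.
REFERENCE_I_OPT = 413.0


def _as_param_mapping(fit) -> Mapping[float, KineticParams]:
    if isinstance(fit, FitResult):
        return {w: f.params for w, f in fit.fits.items()}
    return fit


def report_thickness_trends(fit, reference_I_opt: float = REFERENCE_I_OPT
                            ) -> pd.DataFrame:
    """Trend table of I_opt, I_opt' = I_opt/reference and k_a per thickness.

    Accepts a :class:`~thinpbr.estimation.FitResult` or a plain mapping of
    thickness (mm) → :class:`~thinpbr.growth_model.KineticParams`. Rows are
    sorted by thickness. With a single thickness a degenerate-trend warning
    is issued and the one-row table still returned.
    """
    params = _as_param_mapping(fit)
    if len(params) < 2:
        warnings.warn("trend report over fewer than 2 thicknesses is degenerate",
                      stacklevel=2)
    rows = []
    for w in sorted(params):
        p = params[w]
        rows.append({
            "thickness_mm": w,
            "mu_max_d": p.mu_max,
            "I_opt_umol_m2_s": p.I_opt,
            "I_opt_norm": p.I_opt / reference_I_opt,
            "k_a_m2_g": p.k_a,
        })
    return pd.DataFrame(rows)


def prediction_curve(p: KineticParams, thickness_mm: float, tau: float,
                     I0_max: float, n: int = 60) -> pd.DataFrame:
    """Predicted stable steady-state biomass on an irradiance grid."""
    I0 = np.linspace(0.0, I0_max, n)
    X = steady_state_batch(thickness_mm / 1000.0, I0, np.full_like(I0, tau), p)
    return pd.DataFrame({"I0_umol_m2_s": I0, "X_pred_g_m3": X})


def plot_trends(trend: pd.DataFrame, path) -> Path:
    """Two-panel plot: I_opt' and k_a versus thickness."""
    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(8, 3.2))
    ax1.plot(trend["thickness_mm"], trend["I_opt_norm"], "o-")
    ax1.set_xlabel("thickness [mm]")
    ax1.set_ylabel("I_opt' [-]")
    ax2.plot(trend["thickness_mm"], trend["k_a_m2_g"], "s-")
    ax2.set_xlabel("thickness [mm]")
    ax2.set_ylabel("k_a [m$^2$ g$^{-1}$]")
    fig.tight_layout()
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path)
    plt.close(fig)
    return path


def plot_prediction_curves(params: Mapping[float, KineticParams],
                           tau_by_thickness: Mapping[float, float],
                           path, I0_max_thin: float = 500.0,
                           I0_max_thick: float = 1200.0) -> Path:
    """One panel per thickness of predicted biomass versus irradiance."""
    params = _as_param_mapping(params)
    ws = sorted(params)
    fig, axes = plt.subplots(1, len(ws), figsize=(3 * len(ws), 3), squeeze=False)
    for ax, w in zip(axes[0], ws):
        i_max = I0_max_thin if w <= 8 else I0_max_thick
        curve = prediction_curve(params[w], w, tau_by_thickness[w], i_max)
        ax.plot(curve["I0_umol_m2_s"], curve["X_pred_g_m3"])
        ax.set_title(f"{w:g} mm, tau={tau_by_thickness[w]:g} d")
        ax.set_xlabel("I0 [µmol m$^{-2}$ s$^{-1}$]")
        ax.set_ylabel("X [g m$^{-3}$]")
    fig.tight_layout()
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path)
    plt.close(fig)
    return path
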