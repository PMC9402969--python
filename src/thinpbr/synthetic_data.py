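"""Synthetic steady-state observation tables for pipeline testing.

The published raw measurements behind this kind of analysis are typically
not deposited, so validation of the estimator has to run on data with the
same statistical structure. This module generates steady-state biomass
observations from the growth model itself: the default design reproduces the
experimental envelope of the thin-photobioreactor study conditions —
thicknesses 2/5/8/15/35 mm, irradiance grids spanning 0–500 µmol m⁻² s⁻¹
(thin reactors) and 0–1200 µmol m⁻² s⁻¹ (thick ones), and the per-thickness
residence times 1.5 / 1 / 1–2 / 1.43–2.5 / 1.05 d — with multiplicative
Gaussian observation noise of a chosen coefficient of variation.

Noise is placed directly on the steady-state mass concentration (the
cell-count stage and the count-to-mass conversion of real experiments are
not emulated). Washout cells produce observations of zero plus floor noise,
matching how the estimator treats them.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .estimation import DEFAULT_SIGMA_FLOOR
from .growth_model import KineticParams, steady_state_batch

__all__ = ["ThicknessBlock", "DesignSpec", "paper_design", "simulate_observations"]

#: Irradiance plotting ranges of the emulated designs, µmol m⁻² s⁻¹.
_THIN_I0_MAX = 500.0    # 2-8 mm reactors
_THICK_I0_MAX = 1200.0  # 15-35 mm reactors

#: Lowest non-zero lamp setting of the default grids, µmol m⁻² s⁻¹.
_I0_MIN = 20.0


@dataclass(frozen=True)
class ThicknessBlock:
    """One thickness's factorial design cell set."""

    thickness_mm: float
    I0_levels: tuple[float, ...]
    tau_levels: tuple[float, ...]
    replicates: int = 3

    def __post_init__(self) -> None:
        if self.thickness_mm <= 0:
            raise ValueError("thickness_mm must be positive")
        if any(i < 0 for i in self.I0_levels):
            raise ValueError("I0 levels must be non-negative")
        if any(t <= 0 for t in self.tau_levels):
            raise ValueError("tau levels must be positive")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")


@dataclass(frozen=True)
class DesignSpec:
    """A full multi-thickness design plus the noise and seed contract."""

    blocks: tuple[ThicknessBlock, ...]
    noise_cv: float = 0.05
    seed: int = 0
    preset: str | None = None

    def __post_init__(self) -> None:
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        if self.preset == "paper-design":
            for b in self.blocks:
                cap = _THIN_I0_MAX if b.thickness_mm <= 8 else _THICK_I0_MAX
                if max(b.I0_levels) > cap:
                    raise ValueError(
                        f"preset design at {b.thickness_mm} mm exceeds the "
                        f"plotted irradiance range ({cap})")


def _grid(i_max: float, n: int) -> tuple[float, ...]:
    """Zero plus n log-spaced irradiance levels: resolves both the
    photolimited rise and the inhibited fall with few points."""
    return (0.0,) + tuple(np.geomspace(_I0_MIN, i_max, n))


def paper_design(noise_cv: float = 0.05, seed: int = 0, replicates: int = 3,
                 n_I0: int = 8) -> DesignSpec:
    """The preset design emulating the five-thickness study conditions.

    Residence times per thickness: 2 mm → 1.5 d; 5 mm → 1 d; 8 mm → 1 and
    2 d; 15 mm → 1.43 and 2.5 d; 35 mm → 1.05 d. Irradiance grids are zero
    plus ``n_I0`` log-spaced levels up to 500 (thin) or 1200 (thick)
    µmol m⁻² s⁻¹.
    """
    blocks = (
        ThicknessBlock(2.0, _grid(_THIN_I0_MAX, n_I0), (1.5,), replicates),
        ThicknessBlock(5.0, _grid(_THIN_I0_MAX, n_I0), (1.0,), replicates),
        ThicknessBlock(8.0, _grid(_THIN_I0_MAX, n_I0), (1.0, 2.0), replicates),
        ThicknessBlock(15.0, _grid(_THICK_I0_MAX, n_I0), (1.43, 2.5), replicates),
        ThicknessBlock(35.0, _grid(_THICK_I0_MAX, n_I0), (1.05,), replicates),
    )
    return DesignSpec(blocks=blocks, noise_cv=noise_cv, seed=seed,
                      preset="paper-design")


def simulate_observations(design: DesignSpec,
                          truth: Mapping[float, KineticParams]) -> pd.DataFrame:
    """Generate an observation table from the model under ``truth``.

    For every design cell the stable steady-state concentration is computed
    and perturbed with multiplicative Gaussian noise of CV ``noise_cv``,
    truncated at zero. Washout cells yield observations of zero plus floor
    noise (sigma = noise_cv × the estimator's concentration floor). Seeded
    and fully reproducible: the same (design, truth) gives an identical
    table.
    """
    for b in design.blocks:
        if b.thickness_mm not in truth:
            raise KeyError(
                f"no true parameter set provided for thickness {b.thickness_mm} mm")
    rng = np.random.default_rng(np.random.SeedSequence([design.seed]))
    rows = []
    for b in design.blocks:
        p = truth[b.thickness_mm]
        W_m = b.thickness_mm / 1000.0
        i0g, taug = np.meshgrid(b.I0_levels, b.tau_levels)
        i0f, tauf = i0g.ravel(), taug.ravel()
        pred = steady_state_batch(W_m, i0f, tauf, p)
        for i0, tau, x in zip(i0f, tauf, pred):
            for rep in range(1, b.replicates + 1):
                eps = rng.standard_normal()
                if x > 0:
                    obs = x * (1.0 + design.noise_cv * eps)
                else:
                    obs = design.noise_cv * DEFAULT_SIGMA_FLOOR * eps
                rows.append({
                    "thickness_mm": b.thickness_mm,
                    "I0_umol_m2_s": float(i0),
                    "tau_d": float(tau),
                    "X_obs_g_m3": max(obs, 0.0),
                    "replicate": rep,
                })
    return pd.DataFrame(rows)
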