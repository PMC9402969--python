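"""Mixing-induced light–dark cycle calculus: the pulsed-light analogy.

Turbulent mixing carries cells back and forth across the self-shading light
gradient, so a cell experiences intermittent illumination even under a
continuous lamp. This module quantifies that regime for a flat reactor:

* the regular motion (travel) time ``tau_t = L / v_cell`` for a cell crossing
  the full optical path at the bubble-driven lateral velocity,
* the photic depth ``z_ph = ln(I0/I_opt) / (k_a X)``, the depth at which the
  local irradiance falls to I_opt — above it light is inhibitory,
* the light/dark phase times a regularly moving cell spends in and below the
  photic zone, and
* the duty cycle ``phi = t_l / (t_l + t_d)``, the fraction of a cycle spent
  under inhibitory light.

Travel times comparable to the photosynthetic-unit (PSU) turnover time
(~10 ms) mean the flashing-light regime matters; ``phi = 1`` means cells are
effectively under continuous (inhibitory) light — the situation in ultra-thin
reactors, where the whole depth is photic.

Note the extinction coefficient used here is the *optical* one (default
0.1 m² g⁻¹, the thickness-independent value), deliberately a separate input
from any fitted k_a of the growth model.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

from .growth_model import KineticParams, OperatingPoint, steady_state_biomass

__all__ = [
    "MixingSpec",
    "LightDarkMetrics",
    "regular_motion_time",
    "photic_depth",
    "phase_times",
    "duty_cycle",
    "classify_regime",
    "metrics_from_steady_state",
]

#: Thickness-independent optical extinction coefficient used for duty-cycle
#: computations, m² g⁻¹.
DUTY_K_A_DEFAULT = 0.1


@dataclass(frozen=True)
class MixingSpec:
    """Mixing hypothesis: cell lateral velocity (cm s⁻¹, assumed equal to the
    bubble rise velocity, plausibly 30–50) and the PSU turnover reference
    time (ms)."""

    v_cell: float = 30.0
    psu_turnover: float = 10.0

    def __post_init__(self) -> None:
        if not (self.v_cell > 0 and self.psu_turnover > 0):
            raise ValueError("v_cell and psu_turnover must be positive")
        if not 30.0 <= self.v_cell <= 50.0:
            warnings.warn(
                f"v_cell = {self.v_cell} cm/s is outside the plausible "
                "bubble-velocity range 30-50 cm/s", stacklevel=2,
            )


@dataclass(frozen=True)
class LightDarkMetrics:
    """Light–dark cycle summary for one operating condition.

    ``z_ph`` is clipped to [0, W]; the raw (unclipped, possibly negative or
    infinite) photic depth is kept in ``z_ph_raw``. ``pulse_I`` is the pulse
    intensity, taken as the incident irradiance I0. ``near_psu_turnover``
    flags travel times within one order of magnitude of the PSU turnover
    time, where flashing-light effects are expected.
    """

    tau_t: float          # regular motion time, ms
    z_ph: float           # clipped photic depth, m
    z_ph_raw: float       # unclipped photic depth, m (may be ±inf)
    t_l: float            # light phase, ms
    t_d: float            # dark phase, ms
    phi: float            # duty cycle, dimensionless
    pulse_I: float        # pulse intensity, µmol m⁻² s⁻¹
    regime: str           # "continuous-light" or "pulsed-light"
    near_psu_turnover: bool


def regular_motion_time(L: float, v_cell: float) -> float:
    """Travel time L/v_cell in ms, for L in cm and v_cell in cm s⁻¹."""
    if not (L > 0 and v_cell > 0):
        raise ValueError("L and v_cell must be strictly positive")
    return L / v_cell * 1000.0


def photic_depth(X: float, I0: float, k_a: float, I_opt: float) -> float:
    """Unclipped photic depth ``ln(I0/I_opt) / (k_a X)`` in m.

    Negative when I0 < I_opt (no inhibitory zone anywhere). Defined limits:
    I0 = 0 gives -inf (all dark); X = 0 gives ±inf with the sign of
    ln(I0/I_opt) — with no biomass there is no attenuation, so the photic
    zone is either the whole (unbounded) depth or absent.
    """
    if k_a <= 0 or I_opt <= 0:
        raise ValueError("k_a and I_opt must be strictly positive")
    if X < 0 or I0 < 0:
        raise ValueError("X and I0 must be non-negative")
    if I0 == 0.0:
        return -math.inf
    log_ratio = math.log(I0 / I_opt)
    if X == 0.0:
        return math.copysign(math.inf, log_ratio) if log_ratio != 0.0 else 0.0
    return log_ratio / (k_a * X)


def phase_times(z_ph: float, W: float, v_cell: float) -> tuple[float, float]:
    """Light and dark phase times (ms) for a cell crossing thickness W (m).

    The photic depth is clipped to [0, W] so that ``t_l + t_d = W / v_cell``
    holds for every input; v_cell is in cm s⁻¹.
    """
    if not (W > 0 and v_cell > 0):
        raise ValueError("W and v_cell must be strictly positive")
    z = min(max(z_ph, 0.0), W)
    v_m_s = v_cell / 100.0
    t_l = z / v_m_s * 1000.0
    t_d = (W - z) / v_m_s * 1000.0
    return t_l, t_d


def duty_cycle(t_l: float, t_d: float) -> float:
    """Duty cycle ``t_l / (t_l + t_d)`` in [0, 1]."""
    if t_l < 0 or t_d < 0:
        raise ValueError("phase times must be non-negative")
    if t_l + t_d == 0:
        raise ValueError("t_l and t_d cannot both be zero")
    return t_l / (t_l + t_d)


def classify_regime(op: OperatingPoint, X: float, I_opt: float,
                    duty_k_a: float = DUTY_K_A_DEFAULT,
                    mix: MixingSpec | None = None) -> LightDarkMetrics:
    """Compose travel time, photic depth, phase times and duty cycle.

    ``X`` is the biomass concentration (g m⁻³), typically the model's stable
    steady state; ``duty_k_a`` is the optical extinction coefficient used
    for the light profile here (default 0.1 m² g⁻¹), intentionally distinct
    from the growth model's fitted k_a. Labels the condition
    "continuous-light" when phi = 1 and "pulsed-light" otherwise.
    """
    mix = mix if mix is not None else MixingSpec()
    tau_t = regular_motion_time(op.W * 100.0, mix.v_cell)
    z_raw = photic_depth(X, op.I0, duty_k_a, I_opt)
    t_l, t_d = phase_times(z_raw, op.W, mix.v_cell)
    phi = duty_cycle(t_l, t_d)
    ratio = tau_t / mix.psu_turnover
    return LightDarkMetrics(
        tau_t=tau_t,
        z_ph=min(max(z_raw, 0.0), op.W),
        z_ph_raw=z_raw,
        t_l=t_l,
        t_d=t_d,
        phi=phi,
        pulse_I=op.I0,
        regime="continuous-light" if phi == 1.0 else "pulsed-light",
        near_psu_turnover=0.1 <= ratio <= 10.0,
    )


def metrics_from_steady_state(op: OperatingPoint, p: KineticParams,
                              duty_k_a: float = DUTY_K_A_DEFAULT,
                              mix: MixingSpec | None = None) -> LightDarkMetrics:
    """Convenience composition: solve the growth model's stable steady state
    at ``op`` and classify the light–dark regime at that biomass, using the
    model's I_opt as the photic threshold."""
    ss = steady_state_biomass(op, p)
    return classify_regime(op, ss.stable_root, p.I_opt, duty_k_a=duty_k_a, mix=mix)
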