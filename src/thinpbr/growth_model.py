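"""Light field, Haldane growth kinetics and the CSTR biomass balance.

The model couples three pieces:

* Lambert–Beer self-shading: the local irradiance at depth ``z`` in a flat
  culture of homogeneous biomass ``X`` is ``I(z) = I0 * exp(-k_a * X * z)``.
* A reparameterized Haldane (substrate-inhibition) light response for the
  gross specific growth rate,
  ``mu(I) = mu_max * I / (I + K_I * (I/I_opt - 1)**2)``,
  which is zero at I=0, attains its unique maximum ``mu_max`` exactly at
  ``I = I_opt`` and decays to zero at high irradiance (photoinhibition).
* A continuous stirred-tank (chemostat) balance on biomass,
  ``dX/dt = -X/tau + r_bar(X)``, where ``r_bar`` is the growth rate averaged
  over the reactor depth, so the light gradient feeds back on the achievable
  steady state.

Because the depth-averaged specific rate is unimodal in ``X`` under Haldane
inhibition, the steady-state condition ``mu_bar(X) = 1/tau + k_d`` can have
zero, one or two positive roots; the largest one (on the branch where
``mu_bar`` decreases with ``X``) is the stable steady state reached from a
healthy inoculum, and the absence of any positive root is washout.

Units throughout: depth/thickness in m, irradiance in µmol m⁻² s⁻¹, biomass
in g m⁻³, time in days, extinction coefficient in m² g⁻¹ (so the optical
depth ``k_a * X * z`` is dimensionless).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import quad, solve_ivp
from scipy.optimize import brentq

__all__ = [
    "KineticParams",
    "OperatingPoint",
    "SteadyStateSolution",
    "Trajectory",
    "local_irradiance",
    "specific_growth_rate",
    "depth_averaged_rate",
    "mean_specific_gross_rate",
    "steady_state_biomass",
    "steady_state_batch",
    "simulate_transient",
]

#: Optical depth below which the depth average collapses to a midpoint value.
_THIN_OPTICAL_DEPTH = 1e-9

#: Default scan window for steady-state root bracketing, g m⁻³.
X_FLOOR_DEFAULT = 1e-3
X_CAP_DEFAULT = 1e5


@dataclass(frozen=True)
class KineticParams:
    """The five growth parameters of the light-limited chemostat model.

    Attributes
    ----------
    mu_max : float
        Maximum specific growth rate, d⁻¹.
    K_I : float
        Half-saturation constant of the light response, µmol m⁻² s⁻¹.
    I_opt : float
        Irradiance of maximal growth, µmol m⁻² s⁻¹.
    k_d : float
        Specific decay (respiration/maintenance) rate, d⁻¹.
    k_a : float
        Lambert–Beer mass extinction coefficient, m² g⁻¹.
    """

    mu_max: float
    K_I: float
    I_opt: float
    k_d: float
    k_a: float

    def __post_init__(self) -> None:
        for name in ("mu_max", "K_I", "I_opt", "k_d", "k_a"):
            v = getattr(self, name)
            if not (v > 0 and math.isfinite(v)):
                raise ValueError(f"{name} must be strictly positive, got {v!r}")


@dataclass(frozen=True)
class OperatingPoint:
    """One steady-state experiment: thickness W (m), incident irradiance
    I0 (µmol m⁻² s⁻¹) and residence time tau (d)."""

    W: float
    I0: float
    tau: float

    def __post_init__(self) -> None:
        if not self.W > 0:
            raise ValueError(f"W must be > 0, got {self.W!r}")
        if self.I0 < 0:
            raise ValueError(f"I0 must be >= 0, got {self.I0!r}")
        if not self.tau > 0:
            raise ValueError(f"tau must be > 0, got {self.tau!r}")

    @classmethod
    def from_volumes(cls, W: float, I0: float, V_R: float, flow: float) -> "OperatingPoint":
        """Build from reactor volume V_R (m³) and liquid flowrate (m³ d⁻¹),
        using tau = V_R / flow."""
        if not (V_R > 0 and flow > 0):
            raise ValueError("V_R and flow must be strictly positive")
        return cls(W=W, I0=I0, tau=V_R / flow)


@dataclass(frozen=True)
class SteadyStateSolution:
    """All strictly positive steady states of the biomass balance.

    ``roots`` are sorted ascending; ``stable_root`` is the largest positive
    root (0.0 under washout); ``washout`` is True when no positive root
    exists. The trivial root X=0 always satisfies the balance and is
    reported only through the washout flag. ``residuals`` are the balance
    residuals ``-X/tau + r_bar(X)`` at each root, g m⁻³ d⁻¹.
    """

    roots: tuple[float, ...]
    stable_root: float
    washout: bool
    residuals: tuple[float, ...] = field(default=())


@dataclass(frozen=True)
class Trajectory:
    """A transient biomass trajectory: times (d) and concentrations (g m⁻³)."""

    times: np.ndarray
    concentrations: np.ndarray

    def __post_init__(self) -> None:
        if len(self.times) != len(self.concentrations):
            raise ValueError("times and concentrations must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.concentrations < 0):
            raise ValueError("concentrations must be non-negative")


def local_irradiance(z, I0, k_a, X):
    """Lambert–Beer irradiance ``I0 * exp(-k_a * X * z)`` at depth z.

    Accepts scalars or arrays; monotone non-increasing in each of z, k_a, X.
    """
    z, I0, k_a, X = (np.asarray(a, dtype=float) for a in (z, I0, k_a, X))
    if np.any(z < 0) or np.any(I0 < 0) or np.any(k_a < 0) or np.any(X < 0):
        raise ValueError("local_irradiance requires non-negative z, I0, k_a, X")
    out = I0 * np.exp(-k_a * X * z)
    return out if out.ndim else float(out)


def specific_growth_rate(I, p: KineticParams, net: bool = False):
    """Haldane specific growth rate at irradiance I (µmol m⁻² s⁻¹), d⁻¹.

    Gross mode returns ``mu_max * I / (I + K_I * (I/I_opt - 1)**2)``; the
    net mode subtracts the decay rate k_d. The gross rate is unimodal with
    maximum exactly ``mu_max`` at ``I = I_opt``.
    """
    I = np.asarray(I, dtype=float)
    if np.any(I < 0):
        raise ValueError("irradiance must be non-negative")
    denom = I + p.K_I * (I / p.I_opt - 1.0) ** 2
    mu = p.mu_max * I / denom
    if net:
        mu = mu - p.k_d
    return mu if mu.ndim else float(mu)


def _antiderivative(u, K_I: float, I_opt: float):
    """Antiderivative of ``1 / (a u² + b u + c)`` with a=K_I/I_opt²,
    b=1-2K_I/I_opt, c=K_I — the quadratic obtained by substituting
    u = I(z) in the depth integral of the Haldane rate."""
    a = K_I / I_opt**2
    b = 1.0 - 2.0 * K_I / I_opt
    disc = 4.0 * K_I / I_opt - 1.0  # = 4ac - b²
    t = 2.0 * a * u + b
    if disc > 0:
        s = math.sqrt(disc)
        return (2.0 / s) * np.arctan(t / s)
    if disc < 0:
        s = math.sqrt(-disc)
        return (1.0 / s) * np.log(np.abs((t - s) / (t + s)))
    return -2.0 / t


def mean_specific_gross_rate(X, op_W, op_I0, p: KineticParams):
    """Depth-averaged gross specific rate ``(1/W) ∫ mu(I(z)) dz``, closed form.

    Vectorized over X (and broadcastable I0). Uses the substitution
    u = I(z), which turns the integrand into 1/(quadratic in u); for thin
    optical depths the midpoint value is used to avoid catastrophic
    cancellation.
    """
    X = np.asarray(X, dtype=float)
    I0 = np.asarray(op_I0, dtype=float)
    X, I0 = np.broadcast_arrays(X, I0)
    delta = p.k_a * X * op_W  # optical depth, dimensionless
    out = np.zeros(X.shape)
    lit = I0 > 0
    thin = lit & (delta < _THIN_OPTICAL_DEPTH)
    thick = lit & ~thin
    if np.any(thin):
        out[thin] = specific_growth_rate(I0[thin] * np.exp(-delta[thin] / 2.0), p)
    if np.any(thick):
        I_bot = I0[thick] * np.exp(-delta[thick])
        F = _antiderivative(I0[thick], p.K_I, p.I_opt) - _antiderivative(I_bot, p.K_I, p.I_opt)
        out[thick] = p.mu_max * F / delta[thick]
    return out if out.ndim else float(out)


def depth_averaged_rate(X: float, op: OperatingPoint, p: KineticParams,
                        method: str = "quad") -> float:
    """Volumetric depth-averaged growth rate ``r_bar(X)``, g m⁻³ d⁻¹.

    ``r_bar = [ (1/W) ∫₀^W mu(I(z)) dz - k_d ] * X``. The default evaluates
    the depth integral by adaptive quadrature (relative tolerance 1e-10);
    ``method="analytic"`` uses the closed form of
    :func:`mean_specific_gross_rate`, which must agree with quadrature and
    is the fast path used internally.
    """
    if X < 0:
        raise ValueError("X must be non-negative")
    if X == 0.0:
        return 0.0
    if method == "analytic":
        mu_bar = mean_specific_gross_rate(X, op.W, op.I0, p)
    elif method == "quad":
        if op.I0 == 0.0:
            mu_bar = 0.0
        else:
            delta = p.k_a * X * op.W
            if delta < _THIN_OPTICAL_DEPTH:
                mu_bar = specific_growth_rate(op.I0 * math.exp(-delta / 2.0), p)
            else:
                val, _ = quad(
                    lambda z: specific_growth_rate(local_irradiance(z, op.I0, p.k_a, X), p),
                    0.0, op.W, epsrel=1e-10, epsabs=0.0, limit=200,
                )
                mu_bar = val / op.W
    else:
        raise ValueError(f"unknown method {method!r}")
    return (mu_bar - p.k_d) * X


def _scan_brackets(f_grid: np.ndarray, grid: np.ndarray):
    """Sign-change brackets (lo, hi) of a function sampled on a grid."""
    s = np.sign(f_grid)
    idx = np.nonzero(s[:-1] * s[1:] < 0)[0]
    return [(grid[i], grid[i + 1]) for i in idx]


def steady_state_biomass(op: OperatingPoint, p: KineticParams,
                         x_floor: float = X_FLOOR_DEFAULT,
                         x_cap: float = X_CAP_DEFAULT,
                         n_scan: int = 512) -> SteadyStateSolution:
    """Solve the chemostat steady state ``mu_bar(X) = 1/tau + k_d``.

    Scans the depth-averaged specific gross rate on a geometric grid in
    ``[x_floor, x_cap]`` g m⁻³, brackets sign changes and refines each by
    Brent's method to 1e-10 relative. Under Haldane inhibition with
    ``I0 > I_opt`` there may be 0, 1 or 2 positive roots; the largest is
    reported as the stable steady state. Washout (no positive root) is
    guaranteed whenever ``1/tau + k_d >= mu_max`` since ``mu_bar < mu_max``.
    Roots that would fall below ``x_floor`` are reported as washout, not as
    tiny concentrations.
    """
    rhs = 1.0 / op.tau + p.k_d
    if op.I0 <= 0.0 or rhs >= p.mu_max:
        return SteadyStateSolution(roots=(), stable_root=0.0, washout=True)
    grid = np.geomspace(x_floor, x_cap, n_scan)
    f = mean_specific_gross_rate(grid, op.W, op.I0, p) - rhs
    if f[-1] > 0:
        raise RuntimeError(
            f"mu_bar still exceeds 1/tau + k_d at X = {x_cap} g m^-3; "
            "raise x_cap to bracket the stable root"
        )
    brackets = _scan_brackets(f, grid)
    roots = []
    for lo, hi in brackets:
        r = brentq(
            lambda x: mean_specific_gross_rate(x, op.W, op.I0, p) - rhs,
            lo, hi, rtol=1e-12, maxiter=200,
        )
        roots.append(r)
    roots = sorted(r for r in roots if r >= x_floor)
    if not roots:
        return SteadyStateSolution(roots=(), stable_root=0.0, washout=True)
    residuals = tuple(-r / op.tau + depth_averaged_rate(r, op, p, method="analytic")
                      for r in roots)
    return SteadyStateSolution(
        roots=tuple(roots), stable_root=roots[-1], washout=False, residuals=residuals
    )


def steady_state_batch(W, I0, tau, p: KineticParams,
                       x_floor: float = X_FLOOR_DEFAULT,
                       x_cap: float = X_CAP_DEFAULT,
                       n_scan: int = 64,
                       xrtol: float = 1e-10) -> np.ndarray:
    """Stable steady-state biomass for many operating points at once.

    Vectorized geometric-grid scan + bisection in log-space to relative
    precision ``xrtol``; returns 0.0 for washout cells. This is the hot
    path of the likelihood: one call evaluates every design cell of a
    dataset for a candidate parameter vector.
    """
    W = float(W)
    I0 = np.atleast_1d(np.asarray(I0, dtype=float))
    tau = np.atleast_1d(np.asarray(tau, dtype=float))
    I0, tau = np.broadcast_arrays(I0, tau)
    rhs = 1.0 / tau + p.k_d
    out = np.zeros(I0.shape)
    live = (I0 > 0) & (rhs < p.mu_max)
    if not np.any(live):
        return out
    grid = np.geomspace(x_floor, x_cap, n_scan)
    f = mean_specific_gross_rate(grid[None, :], W, I0[live, None], p) - rhs[live, None]
    if np.any(f[:, -1] > 0):
        raise RuntimeError("stable root above x_cap; raise x_cap")
    # last sign change + -> - is the bracket of the largest (stable) root
    sign_change = (f[:, :-1] > 0) & (f[:, 1:] <= 0)
    has_root = sign_change.any(axis=1)
    if np.any(has_root):
        last = n_scan - 2 - np.argmax(sign_change[has_root, ::-1], axis=1)
        lo, hi = grid[last], grid[last + 1]
        rhs_live = rhs[live][has_root]
        i0_live = I0[live][has_root]
        # geometric-mean bisection: the bracket is one geometric grid step
        # wide, so the iteration count for relative precision xrtol is fixed
        step = math.log(grid[1] / grid[0])
        n_iter = max(1, math.ceil(math.log2(step / math.log1p(xrtol))))
        for _ in range(n_iter):
            mid = np.sqrt(lo * hi)
            fm = mean_specific_gross_rate(mid, W, i0_live, p) - rhs_live
            pos = fm > 0
            lo = np.where(pos, mid, lo)
            hi = np.where(pos, hi, mid)
        roots = np.sqrt(lo * hi)
        tmp = np.zeros(live.sum())
        tmp[has_root] = np.where(roots >= x_floor, roots, 0.0)
        out[live] = tmp
    return out


def simulate_transient(X0: float, horizon: float, op: OperatingPoint,
                       p: KineticParams, n_points: int = 200) -> Trajectory:
    """Integrate ``dX/dt = -X/tau + r_bar(X)`` from X0 over ``horizon`` days.

    Uses a stiff-capable integrator (LSODA) with the closed-form depth
    average in the right-hand side and non-negativity clamping; from an
    inoculum above the unstable root the trajectory converges to the stable
    steady state, otherwise to washout.
    """
    if X0 < 0:
        raise ValueError("X0 must be non-negative")
    if horizon <= 0:
        raise ValueError("horizon must be positive")

    def rhs(_t, y):
        x = max(y[0], 0.0)
        if x == 0.0:
            return [0.0]
        return [-x / op.tau + depth_averaged_rate(x, op, p, method="analytic")]

    sol = solve_ivp(rhs, (0.0, horizon), [X0], method="LSODA",
                    t_eval=np.linspace(0.0, horizon, n_points),
                    rtol=1e-9, atol=1e-8)
    if not sol.success:
        raise RuntimeError(f"transient integration failed: {sol.message}")
    return Trajectory(times=sol.t, concentrations=np.clip(sol.y[0], 0.0, None))
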