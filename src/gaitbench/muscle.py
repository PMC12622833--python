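"""Hill-type muscle-tendon mechanics in prescribed-kinematics mode.

The muscle-tendon unit (MTU) is a massless fiber in series with an elastic
tendon. Fiber force depends on activation ``a``, normalized fiber length
``l_fiber / l_opt`` and normalized fiber velocity ``v_fiber / v_max`` through
dimensionless characteristic curves; the tendon is an elastic element that is
slack below its slack length. All solves here run with *prescribed* MTU
kinematics: nothing in this module integrates skeletal dynamics.

Sign conventions (used throughout the package):

* fiber velocity is **lengthening-positive** (``v_fiber > 0`` = eccentric);
* fiber power ``p_fiber = -f_fiber * v_fiber`` is **shortening-positive**,
  so concentric contractions do positive mechanical work.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "MuscleParams",
    "MuscleState",
    "MuscleTrajectory",
    "CurveSet",
    "DEFAULT_CURVES",
    "activation_dynamics",
    "integrate_activation",
    "active_force_length",
    "passive_force_length",
    "force_velocity",
    "tendon_force_length",
    "tendon_strain_energy",
    "fiber_equilibrium",
    "fiber_power",
    "solve_trajectory",
]

MUSCLE_DENSITY = 1058.7
"""Muscle tissue density (kg/m^3) used to derive muscle mass from volume."""

SPECIFIC_TENSION = 0.25e6
"""Specific tension (N/m^2): max isometric force per physiological cross-section."""


@dataclass(frozen=True)
class MuscleParams:
    """Static per-muscle constants for mechanics and energetics.

    Parameters
    ----------
    name : str
        Muscle identifier.
    f_iso_max : float
        Maximal isometric fiber force (N).
    l_opt : float
        Optimal fiber length (m).
    l_tendon_slack : float
        Tendon slack length (m).
    alpha_opt : float
        Pennation angle at optimal fiber length (rad), in [0, pi/2).
    v_max : float
        Maximal shortening velocity in optimal fiber lengths per second.
    frac_slow : float
        Slow-twitch fiber fraction in [0, 1].
    mass : float or None
        Muscle mass (kg). When None it is derived as
        ``f_iso_max / specific_tension * density * l_opt``.
    tau_act, tau_deact : float
        Activation / deactivation time constants (s).
    tendon_strain_iso : float
        Tendon strain at which normalized tendon force reaches 1 (dimensionless).
    tendon_stiffness_shape : float
        Dimensionless exponential shape parameter of the tendon curve.
    """

    name: str
    f_iso_max: float
    l_opt: float
    l_tendon_slack: float
    alpha_opt: float = 0.0
    v_max: float = 10.0
    frac_slow: float = 0.5
    mass: float | None = None
    tau_act: float = 0.015
    tau_deact: float = 0.060
    tendon_strain_iso: float = 0.049
    tendon_stiffness_shape: float = 3.0

    def __post_init__(self) -> None:
        for attr in ("f_iso_max", "l_opt", "l_tendon_slack", "v_max",
                     "tau_act", "tau_deact", "tendon_strain_iso",
                     "tendon_stiffness_shape"):
            if not getattr(self, attr) > 0:
                raise ValueError(f"{self.name}: {attr} must be > 0")
        if not 0.0 <= self.frac_slow <= 1.0:
            raise ValueError(f"{self.name}: frac_slow must be in [0, 1]")
        if not 0.0 <= self.alpha_opt < math.pi / 2:
            raise ValueError(f"{self.name}: alpha_opt must be in [0, pi/2)")
        if self.mass is not None and not self.mass > 0:
            raise ValueError(f"{self.name}: mass must be > 0")

    @property
    def muscle_mass(self) -> float:
        """Muscle mass (kg), derived from PCSA x density when not given."""
        if self.mass is not None:
            return self.mass
        return self.f_iso_max / SPECIFIC_TENSION * MUSCLE_DENSITY * self.l_opt

    @property
    def width(self) -> float:
        """Constant fiber-thickness parameter ``l_opt * sin(alpha_opt)`` (m)."""
        return self.l_opt * math.sin(self.alpha_opt)

    @property
    def v_max_mps(self) -> float:
        """Maximal shortening velocity in m/s."""
        return self.v_max * self.l_opt

    def pennation(self, l_fiber: float | np.ndarray) -> float | np.ndarray:
        """Pennation angle (rad) at fiber length ``l_fiber`` (m), constant width."""
        return np.arcsin(np.clip(self.width / np.maximum(l_fiber, 1e-12), 0.0, 1.0))


@dataclass
class MuscleState:
    """Instantaneous fiber/tendon state of one MTU.

    ``p_fiber = -f_fiber * v_fiber`` (velocity lengthening-positive, power
    shortening-positive). ``residual`` is the fiber-tendon force-balance
    residual along the tendon, normalized by ``f_iso_max``.
    """

    a: float
    l_fiber_norm: float
    v_fiber_norm: float
    f_fiber: float
    f_tendon: float
    p_fiber: float
    residual: float = 0.0


@dataclass
class MuscleTrajectory:
    """Time series of one muscle over a stride (shared, strictly increasing grid)."""

    t: np.ndarray
    e: np.ndarray
    a: np.ndarray
    l_fiber_norm: np.ndarray
    v_fiber_norm: np.ndarray
    f_fiber: np.ndarray
    f_tendon: np.ndarray
    p_fiber: np.ndarray
    stride_time: float
    periodic: bool = False
    l_mtu: np.ndarray | None = None
    v_mtu: np.ndarray | None = None
    params: MuscleParams | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        if t.ndim != 1 or t.size < 2 or np.any(np.diff(t) <= 0):
            raise ValueError("time grid must be 1-D and strictly increasing")
        n = t.size
        for name in ("e", "a", "l_fiber_norm", "v_fiber_norm",
                     "f_fiber", "f_tendon", "p_fiber"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (n,):
                raise ValueError(f"channel {name} does not share the time grid")
            setattr(self, name, arr)
        self.t = t
        if not self.stride_time > 0:
            raise ValueError("stride_time must be > 0")


# ---------------------------------------------------------------------------
# Activation dynamics (first-order excitation-activation coupling)
# ---------------------------------------------------------------------------

def activation_dynamics(e: float, a: float, params: MuscleParams) -> float:
    """Activation rate da/dt (1/s) from first-order excitation coupling.

    ``da/dt = (e - a) * (e / tau_act + (1 - e) / tau_deact)``: the effective
    rate constant blends the (faster) activation and (slower) deactivation
    time constants with the excitation level, so activation rises faster than
    it decays and any trajectory started in [0, 1] stays in [0, 1].
    """
    e_arr, a_arr = np.asarray(e, dtype=float), np.asarray(a, dtype=float)
    if np.any((e_arr < 0) | (e_arr > 1)):
        raise ValueError("excitation e must be in [0, 1]")
    if np.any((a_arr < 0) | (a_arr > 1)):
        raise ValueError("activation a must be in [0, 1]")
    rate = (e_arr - a_arr) * (e_arr / params.tau_act + (1.0 - e_arr) / params.tau_deact)
    return float(rate) if np.isscalar(e) and np.isscalar(a) else rate


def integrate_activation(
    t: np.ndarray,
    e: np.ndarray,
    a0: float,
    params: MuscleParams,
) -> np.ndarray:
    """Integrate the activation ODE along ``t`` for excitation series ``e``.

    Uses an exact exponential step per interval (the ODE is linear in ``a``
    for piecewise-constant excitation, evaluated at midpoints), which is
    unconditionally stable and keeps ``a`` in [0, 1].
    """
    t = np.asarray(t, dtype=float)
    e = np.clip(np.asarray(e, dtype=float), 0.0, 1.0)
    a = np.empty_like(t)
    a[0] = a0
    for i in range(t.size - 1):
        dt = t[i + 1] - t[i]
        em = 0.5 * (e[i] + e[i + 1])
        k = em / params.tau_act + (1.0 - em) / params.tau_deact
        # exact solution of da/dt = (em - a) * k over dt
        a[i + 1] = em + (a[i] - em) * math.exp(-k * dt)
    return np.clip(a, 0.0, 1.0)


# ---------------------------------------------------------------------------
# Characteristic curves
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CurveSet:
    """Coefficients of the dimensionless characteristic curves.

    Active force-length is a sum of Gaussians centered at the optimal length
    (peak exactly 1 at ``l_norm = 1``); passive force-length is the usual
    exponential toe curve; force-velocity is a Hill hyperbola on the
    concentric side joined C1-continuously to a saturating eccentric branch.
    """

    # active FL: sum_i w_i * exp(-(x-1)^2 / s_i), weights sum to 1
    fl_weights: tuple[float, ...] = (0.85, 0.15)
    fl_widths: tuple[float, ...] = (0.45, 0.09)
    # passive FL: (exp(k*(x-1)/e0) - 1) / (exp(k) - 1) for x > 1
    pas_shape: float = 4.0
    pas_strain_max: float = 0.6
    # force-velocity: concentric Hill shape factor and eccentric plateau
    fv_shape: float = 0.25
    fv_ecc_max: float = 1.5

    def active_fl(self, l_norm):
        x = np.asarray(l_norm, dtype=float)
        out = np.zeros_like(x)
        for w, s in zip(self.fl_weights, self.fl_widths):
            out = out + w * np.exp(-((x - 1.0) ** 2) / s)
        return out if out.ndim else float(out)

    def passive_fl(self, l_norm):
        x = np.asarray(l_norm, dtype=float)
        k, e0 = self.pas_shape, self.pas_strain_max
        out = (np.exp(k * (x - 1.0) / e0) - 1.0) / (math.exp(k) - 1.0)
        out = np.where(x > 1.0, out, 0.0)
        return out if out.ndim else float(out)

    def fv(self, v_norm):
        v = np.asarray(v_norm, dtype=float)
        af, fe = self.fv_shape, self.fv_ecc_max
        conc = (1.0 + v) / (1.0 - v / af)          # v in [-1, 0]
        c = (fe - 1.0) * af / (1.0 + af)           # C1 match of slope at v = 0
        denom = np.where(v >= 0.0, v + c, 1.0)     # guard unused branch
        ecc = fe - (fe - 1.0) * c / denom          # v >= 0
        out = np.where(v < 0.0, np.where(v <= -1.0, 0.0, conc), ecc)
        return out if out.ndim else float(out)

    # scalar fast paths (pure-python math; hot loop of the equilibrium solver)
    def active_fl_scalar(self, x: float) -> float:
        out = 0.0
        for w, s in zip(self.fl_weights, self.fl_widths):
            out += w * math.exp(-((x - 1.0) ** 2) / s)
        return out

    def passive_fl_scalar(self, x: float) -> float:
        if x <= 1.0:
            return 0.0
        k, e0 = self.pas_shape, self.pas_strain_max
        return (math.exp(k * (x - 1.0) / e0) - 1.0) / (math.exp(k) - 1.0)

    def fv_scalar(self, v: float) -> float:
        af, fe = self.fv_shape, self.fv_ecc_max
        if v < 0.0:
            return 0.0 if v <= -1.0 else (1.0 + v) / (1.0 - v / af)
        c = (fe - 1.0) * af / (1.0 + af)
        return fe - (fe - 1.0) * c / (v + c)


DEFAULT_CURVES = CurveSet()

#: Tri-Gaussian active force-length coefficients from the muscle-modeling
#: literature (peak slightly off 1; provided as an alternative, not default).
TRI_GAUSSIAN_FL = (
    (0.815, 1.055, 0.162, 0.0633),
    (0.433, 0.717, -0.0299, 0.2),
    (0.100, 1.000, 0.3540, 0.0),
)


def active_force_length(l_fiber_norm, curves: CurveSet = DEFAULT_CURVES):
    """Active force-length multiplier; peaks at exactly 1 at ``l_fiber_norm = 1``."""
    return curves.active_fl(l_fiber_norm)


def passive_force_length(l_fiber_norm, curves: CurveSet = DEFAULT_CURVES):
    """Passive force-length multiplier; 0 at/below optimal length, non-decreasing."""
    return curves.passive_fl(l_fiber_norm)


def force_velocity(v_fiber_norm, curves: CurveSet = DEFAULT_CURVES):
    """Force-velocity multiplier (lengthening-positive velocity).

    ``fv(0) = 1``, ``fv(-1) = 0`` (maximal shortening), bounded above by the
    eccentric plateau ``fv_ecc_max``.
    """
    return curves.fv(v_fiber_norm)


def tendon_force_length(l_tendon_norm, params: MuscleParams):
    """Normalized tendon force vs ``l_tendon / l_tendon_slack``.

    Zero at/below slack length; exponential rise reaching 1 at strain
    ``tendon_strain_iso``; shape set by ``tendon_stiffness_shape``.
    """
    x = np.asarray(l_tendon_norm, dtype=float)
    if np.any(x < 0):
        raise ValueError("l_tendon_norm must be >= 0")
    k, e0 = params.tendon_stiffness_shape, params.tendon_strain_iso
    out = (np.exp(k * (x - 1.0) / e0) - 1.0) / (math.exp(k) - 1.0)
    out = np.where(x > 1.0, out, 0.0)
    return out if out.ndim else float(out)


def tendon_strain_energy(l_tendon: float | np.ndarray, params: MuscleParams):
    """Elastic energy (J) stored in the tendon at length ``l_tendon`` (m).

    Closed-form integral of ``f_iso_max * tendon_force_length`` from slack
    length; a state function of tendon length, so it vanishes over any closed
    cycle.
    """
    lt = np.asarray(l_tendon, dtype=float)
    ls = params.l_tendon_slack
    x = np.maximum(lt / ls, 1.0)
    k, e0 = params.tendon_stiffness_shape, params.tendon_strain_iso
    denom = math.exp(k) - 1.0
    # integral of (exp(k(x-1)/e0) - 1)/denom dx from 1 to x, times f_iso * ls
    antider = (e0 / k) * (np.exp(k * (x - 1.0) / e0) - 1.0) - (x - 1.0)
    out = params.f_iso_max * ls * antider / denom
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# Fiber-tendon equilibrium
# ---------------------------------------------------------------------------

class EquilibriumError(RuntimeError):
    """No fiber-tendon force balance could be bracketed; carries diagnostics."""

    def __init__(self, msg: str, diagnostics: dict | None = None):
        super().__init__(msg)
        self.diagnostics = diagnostics or {}


def _fiber_force(a, l_norm, v_norm, params, curves):
    fl = curves.active_fl_scalar(l_norm)
    fp = curves.passive_fl_scalar(l_norm)
    fv = curves.fv_scalar(v_norm)
    return params.f_iso_max * (a * fl * fv + fp)


def _tendon_force_scalar(l_tendon_norm: float, params: MuscleParams) -> float:
    if l_tendon_norm <= 1.0:
        return 0.0
    k, e0 = params.tendon_stiffness_shape, params.tendon_strain_iso
    # cap the exponent: forces beyond ~e^60 x f_iso only occur while the
    # bracket scan probes infeasible lengths and must stay finite
    arg = min(k * (l_tendon_norm - 1.0) / e0, 60.0)
    return (math.exp(arg) - 1.0) / (math.exp(k) - 1.0)


def fiber_equilibrium(
    l_mtu: float,
    v_mtu: float,
    a: float,
    params: MuscleParams,
    tendon_mode: Literal["rigid", "compliant"] = "compliant",
    curves: CurveSet = DEFAULT_CURVES,
    v_fiber: float | None = None,
    xtol: float = 1e-12,
    bracket_hint: float | None = None,
) -> MuscleState:
    """Solve the fiber-tendon force balance at one instant.

    In ``rigid`` mode the tendon stays at slack length and fiber length
    follows from geometry. In ``compliant`` mode a bracketed scalar root find
    on normalized fiber length drives the residual
    ``f_tendon - f_fiber * cos(alpha)`` below 1e-10 relative to
    ``f_iso_max``; when several roots exist the smallest feasible fiber
    length is returned (deterministic tie-break).

    The fiber velocity entering the force-velocity curve is, unless supplied
    explicitly via ``v_fiber`` (m/s, lengthening-positive), the rigid-tendon
    partition ``v_mtu * cos(alpha)`` — the velocity split is indeterminate
    from a single instant; trajectory solves refine it (see
    :func:`solve_trajectory`).
    """
    if not 0.0 <= a <= 1.0:
        raise ValueError("activation a must be in [0, 1]")
    w = params.width

    def geometry(l_f):
        cos_a = math.sqrt(max(l_f * l_f - w * w, 0.0)) / l_f if l_f > 0 else 1.0
        return cos_a

    if tendon_mode == "rigid":
        proj = l_mtu - params.l_tendon_slack
        l_f = math.sqrt(proj * proj + w * w)
        cos_a = geometry(l_f)
        v_f = v_mtu * cos_a if v_fiber is None else v_fiber
        f_f = _fiber_force(a, l_f / params.l_opt, v_f / params.v_max_mps, params, curves)
        f_t = f_f * cos_a
        return MuscleState(
            a=a, l_fiber_norm=l_f / params.l_opt,
            v_fiber_norm=v_f / params.v_max_mps,
            f_fiber=f_f, f_tendon=f_t, p_fiber=-f_f * v_f, residual=0.0,
        )

    if tendon_mode != "compliant":
        raise ValueError("tendon_mode must be 'rigid' or 'compliant'")
    if l_mtu <= params.l_tendon_slack * (1.0 - 1e-9):
        raise EquilibriumError(
            "MTU shorter than tendon slack length: no compliant equilibrium",
            {"l_mtu": l_mtu, "l_tendon_slack": params.l_tendon_slack},
        )

    def residual(l_norm):
        l_f = l_norm * params.l_opt
        cos_a = geometry(l_f)
        v_f = v_mtu * cos_a if v_fiber is None else v_fiber
        l_t = l_mtu - l_f * cos_a
        f_t = params.f_iso_max * _tendon_force_scalar(
            max(l_t, 0.0) / params.l_tendon_slack, params)
        f_f = _fiber_force(a, l_norm, v_f / params.v_max_mps, params, curves)
        return f_t - f_f * cos_a

    lo = max(params.width / params.l_opt + 1e-9, 0.01)
    hi = max((l_mtu - 1e-12) / params.l_opt if w == 0 else
             math.sqrt(l_mtu * l_mtu + w * w) / params.l_opt, lo + 1e-6)

    def scan(grid):
        prev_x, prev_v = grid[0], residual(grid[0])
        if prev_v == 0.0:
            return (prev_x, prev_x)
        for x in grid[1:]:
            v = residual(x)
            if v == 0.0:
                return (x, x)
            if prev_v * v < 0.0:
                return (prev_x, x)
            prev_x, prev_v = x, v
        return None

    bracket = None
    if bracket_hint is not None:
        # warm start: narrow window around the previous solution
        wlo = max(lo, bracket_hint - 0.05)
        whi = min(hi, bracket_hint + 0.05)
        if whi > wlo:
            bracket = scan(np.linspace(wlo, whi, 9))
    if bracket is None:
        bracket = scan(np.linspace(lo, hi, 120))
    if bracket is None:
        raise EquilibriumError(
            "no equilibrium bracket found",
            {"l_mtu": l_mtu, "v_mtu": v_mtu, "a": a,
             "residual_lo": float(residual(lo)), "residual_hi": float(residual(hi))},
        )
    if bracket[0] == bracket[1]:
        root = bracket[0]
    else:
        root = brentq(residual, bracket[0], bracket[1], xtol=xtol, rtol=8.9e-16)

    l_f = root * params.l_opt
    cos_a = geometry(l_f)
    v_f = v_mtu * cos_a if v_fiber is None else v_fiber
    l_t = l_mtu - l_f * cos_a
    f_t = params.f_iso_max * tendon_force_length(max(l_t, 0.0) / params.l_tendon_slack, params)
    f_f = _fiber_force(a, root, v_f / params.v_max_mps, params, curves)
    return MuscleState(
        a=a, l_fiber_norm=root, v_fiber_norm=v_f / params.v_max_mps,
        f_fiber=f_f, f_tendon=f_t, p_fiber=-f_f * v_f,
        residual=(f_t - f_f * cos_a) / params.f_iso_max,
    )


def fiber_power(state: MuscleState) -> float:
    """Fiber mechanical power (W), positive when shortening."""
    return state.p_fiber


def _periodic_gradient(y: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Spectral derivative of a periodic, uniformly sampled series."""
    n = y.size
    T = t[-1] - t[0] + (t[1] - t[0])  # period assuming last+dt wraps to first
    freqs = np.fft.rfftfreq(n, d=T / n)
    return np.fft.irfft(2j * np.pi * freqs * np.fft.rfft(y), n=n)


def solve_trajectory(
    t: np.ndarray,
    l_mtu: np.ndarray,
    e: np.ndarray,
    params: MuscleParams,
    tendon_mode: Literal["rigid", "compliant"] = "compliant",
    curves: CurveSet = DEFAULT_CURVES,
    v_mtu: np.ndarray | None = None,
    a0: float | None = None,
    periodic: bool = False,
    warmup_cycles: int = 3,
    stride_time: float | None = None,
) -> MuscleTrajectory:
    """Solve activation dynamics + fiber equilibrium along an MTU trajectory.

    Activations are integrated from ``a0`` (for ``periodic`` trajectories the
    initial activation is relaxed over ``warmup_cycles`` repeats of the stride
    so the series is periodic). Equilibrium is solved pointwise; for periodic
    uniform grids the fiber velocity (and hence fiber power) is then
    recomputed by spectral differentiation of the solved fiber-length series,
    which makes the cyclic energy balance
    ``W_mtu = W_fiber + dE_tendon (= 0 over a cycle)`` hold to discretization
    accuracy. For non-periodic input a second-order finite difference is used.
    """
    t = np.asarray(t, dtype=float)
    l_mtu = np.asarray(l_mtu, dtype=float)
    e = np.clip(np.asarray(e, dtype=float), 0.0, 1.0)
    uniform_grid = t.size > 4 and np.allclose(np.diff(t), t[1] - t[0], rtol=1e-8)
    if v_mtu is None:
        v_mtu = _series_derivative(l_mtu, t, periodic and uniform_grid)
    else:
        v_mtu = np.asarray(v_mtu, dtype=float)
    T = stride_time if stride_time is not None else float(t[-1] - t[0])

    if a0 is None:
        a0 = float(e[0])
    a = integrate_activation(t, e, a0, params)
    if periodic:
        for _ in range(warmup_cycles):
            a = integrate_activation(t, e, float(a[-1]), params)

    n = t.size
    l_f = np.empty(n)
    states = []
    hint = None
    for i in range(n):
        st = fiber_equilibrium(l_mtu[i], v_mtu[i], a[i], params,
                               tendon_mode=tendon_mode, curves=curves,
                               bracket_hint=hint)
        states.append(st)
        l_f[i] = st.l_fiber_norm * params.l_opt
        hint = st.l_fiber_norm

    # refine fiber velocity from the solved fiber-length series
    v_f = _series_derivative(l_f, t, periodic and uniform_grid)

    f_fiber = np.array([s.f_fiber for s in states])
    f_tendon = np.array([s.f_tendon for s in states])
    return MuscleTrajectory(
        t=t, e=e, a=a,
        l_fiber_norm=l_f / params.l_opt,
        v_fiber_norm=v_f / params.v_max_mps,
        f_fiber=f_fiber, f_tendon=f_tendon,
        p_fiber=-f_fiber * v_f,
        stride_time=T, periodic=periodic,
        l_mtu=l_mtu, v_mtu=v_mtu, params=params,
    )


def _series_derivative(y: np.ndarray, t: np.ndarray, periodic: bool) -> np.ndarray:
    """Derivative of a sampled series; spectral when periodic on a uniform grid.

    Periodic series are expected to carry a duplicated endpoint
    (``y[-1] == y[0]``); the duplicate is dropped for the FFT and restored.
    """
    if periodic and abs(y[-1] - y[0]) <= 1e-9 * max(1.0, abs(y[0])):
        out = np.empty_like(y)
        out[:-1] = _periodic_gradient(y[:-1], t[:-1])
        out[-1] = out[0]
        return out
    return np.gradient(y, t)
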