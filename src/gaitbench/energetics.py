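"""Metabolic energy models for Hill-type muscle states.

Two models are provided:

* :class:`BhargavaModel` — a phenomenological heat-rate model summing
  activation heat, maintenance heat, shortening/lengthening heat, and fiber
  mechanical work rate, with slow/fast fiber-type partitioning of the heat
  constants and mass scaling.
* :func:`margaria_rate` — an efficiency-based model that charges positive
  (concentric) fiber power at an efficiency of 0.25 and negative (eccentric)
  power at an efficiency of -1.2, so dissipating mechanical energy still
  costs positive metabolic energy.

Stride-level energies come from trapezoidal integration of the rate series
(:func:`integrate_energy`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np

from .muscle import MuscleParams, MuscleState, MUSCLE_DENSITY, SPECIFIC_TENSION

__all__ = [
    "BhargavaCoefficients",
    "BhargavaModel",
    "EnergyRates",
    "bhargava_rate",
    "margaria_rate",
    "MargariaModel",
    "integrate_energy",
    "EFF_CONCENTRIC",
    "EFF_ECCENTRIC",
]

EFF_CONCENTRIC = 0.25
"""Mechanical efficiency of concentric (positive) fiber power."""

EFF_ECCENTRIC = -1.2
"""Signed mechanical efficiency of eccentric (negative) fiber power."""


@dataclass(frozen=True)
class BhargavaCoefficients:
    """Heat-rate constants of the phenomenological metabolic model.

    Defaults are the widely used published set: activation heat 40 (slow) /
    133 (fast) W/kg, maintenance heat 74 / 111 W/kg modulated by a piecewise-
    linear fiber-length curve, shortening heat coefficient
    ``0.16 * F_iso(a, l) + 0.18 * F_ce`` for concentric and ``0.157 * F_ce``
    for eccentric contractions, muscle density 1058.7 kg/m^3 and specific
    tension 0.25 MPa for mass derivation. The stimulation-duration decay of
    the activation heat and the per-muscle basal rate are optional switches
    (both off by default).
    """

    act_slow: float = 40.0          # W/kg
    act_fast: float = 133.0         # W/kg
    maint_slow: float = 74.0        # W/kg
    maint_fast: float = 111.0       # W/kg
    # piecewise-linear maintenance modulation vs normalized fiber length
    maint_fl_knots: tuple[float, ...] = (0.0, 0.5, 1.0, 1.5, 2.0)
    maint_fl_values: tuple[float, ...] = (0.5, 0.5, 1.0, 0.0, 0.0)
    short_coef_iso: float = 0.16    # scales isometric force at (a, l)
    short_coef_force: float = 0.18  # scales actual fiber force (concentric)
    lengthen_coef: float = 0.157    # scales actual fiber force (eccentric)
    include_decay: bool = False
    decay_floor: float = 0.06
    decay_tau: float = 10.0         # s, stimulation-duration decay constant
    basal_rate: float = 0.0         # W/kg muscle mass, off by default
    density: float = MUSCLE_DENSITY
    specific_tension: float = SPECIFIC_TENSION

    def __post_init__(self) -> None:
        for attr in ("act_slow", "act_fast", "maint_slow", "maint_fast",
                     "short_coef_iso", "short_coef_force", "lengthen_coef"):
            if getattr(self, attr) < 0:
                raise ValueError(f"{attr} must be >= 0")
        if self.act_slow == self.act_fast or self.maint_slow == self.maint_fast:
            raise ValueError("slow and fast heat constants must be distinct")
        if len(self.maint_fl_knots) != len(self.maint_fl_values):
            raise ValueError("maintenance curve knots/values length mismatch")

    def maint_fl_scale(self, l_fiber_norm):
        """Maintenance-heat modulation at normalized fiber length."""
        return np.interp(l_fiber_norm, self.maint_fl_knots, self.maint_fl_values)

    # -- config round trip ---------------------------------------------------
    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping) -> "BhargavaCoefficients":
        d = dict(d)
        for key in ("maint_fl_knots", "maint_fl_values"):
            if key in d:
                d[key] = tuple(float(x) for x in d[key])
        unknown = set(d) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown coefficient fields: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_file(cls, path) -> "BhargavaCoefficients":
        """Load a coefficient set from a YAML or JSON file."""
        import json
        import yaml

        text = open(path).read()
        data = yaml.safe_load(text) if str(path).endswith((".yml", ".yaml")) else json.loads(text)
        return cls.from_dict(data)


@dataclass
class EnergyRates:
    """Instantaneous metabolic rate components (W) of one muscle.

    ``e_dot_total = h_act + h_maint + h_sl + w_dot (+ basal)`` after any
    configured clamping; ``e_dot_net = e_dot_total - basal``.
    """

    h_act: float
    h_maint: float
    h_sl: float
    w_dot: float
    basal: float
    e_dot_total: float
    e_dot_net: float


def _recruitment_mix(e: float, frac_slow: float) -> tuple[float, float]:
    """Slow/fast recruitment weights at excitation ``e``.

    Slow fibers are recruited first: ``u_slow = f_slow * sin(pi/2 * e)``,
    ``u_fast = (1 - f_slow) * (1 - cos(pi/2 * e))``.
    """
    u_slow = frac_slow * math.sin(0.5 * math.pi * e)
    u_fast = (1.0 - frac_slow) * (1.0 - math.cos(0.5 * math.pi * e))
    return u_slow, u_fast


class BhargavaModel:
    """Phenomenological heat-rate metabolic model.

    Parameters
    ----------
    coeffs : BhargavaCoefficients
        Heat-rate constant set.
    mode : {"exact", "smooth"}
        Positivity treatment of the total rate. ``exact`` applies a hard
        ``max(., 0)``; ``smooth`` applies the smooth positive part
        ``0.5 * (x + sqrt(x^2 + b^2))`` with smoothing width ``b`` (W) —
        strictly positive for every input, as needed by gradient-based
        optimal control (and by efficiency ratios at fast lengthening, where
        the hard clamp would return exactly zero).
    clamp : bool
        Disable to return the raw signed sum of components.
    """

    name = "bhargava"

    def __init__(self, coeffs: BhargavaCoefficients | None = None,
                 mode: str = "exact", smooth_width: float = 10.0,
                 clamp: bool = True):
        if mode not in ("exact", "smooth"):
            raise ValueError("mode must be 'exact' or 'smooth'")
        self.coeffs = coeffs if coeffs is not None else BhargavaCoefficients()
        self.mode = mode
        self.smooth_width = smooth_width
        self.clamp = clamp

    def _positive(self, x: float) -> float:
        if not self.clamp:
            return x
        if self.mode == "exact":
            return max(x, 0.0)
        b = self.smooth_width
        return 0.5 * (x + math.sqrt(x * x + b * b))

    def rate(self, state: MuscleState, e: float, params: MuscleParams,
             t_stim: float | None = None) -> EnergyRates:
        """Metabolic rate components for one muscle state.

        ``t_stim`` (s) feeds the optional stimulation-duration decay of the
        activation heat; ignored unless ``coeffs.include_decay``.
        """
        c = self.coeffs
        if params is None:
            raise ValueError("the heat-rate model requires muscle parameters")
        if not 0.0 <= e <= 1.0:
            raise ValueError("excitation e must be in [0, 1]")
        mass = (params.mass if params.mass is not None
                else params.f_iso_max / c.specific_tension * c.density * params.l_opt)

        u_slow, u_fast = _recruitment_mix(e, params.frac_slow)
        decay = 1.0
        if c.include_decay:
            ts = 0.0 if t_stim is None else max(t_stim, 0.0)
            decay = c.decay_floor + (1.0 - c.decay_floor) * math.exp(-ts / c.decay_tau)

        h_act = mass * decay * (u_slow * c.act_slow + u_fast * c.act_fast)
        h_maint = (mass * c.maint_fl_scale(state.l_fiber_norm)
                   * (u_slow * c.maint_slow + u_fast * c.maint_fast))

        v_fiber = state.v_fiber_norm * params.v_max_mps  # m/s, lengthening +
        if v_fiber <= 0.0:  # concentric
            f_iso_al = (state.a * params.f_iso_max
                        * _active_fl_of_state(state, params))
            alpha = c.short_coef_iso * f_iso_al + c.short_coef_force * state.f_fiber
        else:  # eccentric
            alpha = c.lengthen_coef * state.f_fiber
        h_sl = -alpha * v_fiber  # positive while shortening, negative while lengthening

        w_dot = state.p_fiber
        basal = c.basal_rate * mass
        total = self._positive(h_act + h_maint + h_sl + w_dot + basal)
        return EnergyRates(h_act=h_act, h_maint=h_maint, h_sl=h_sl,
                           w_dot=w_dot, basal=basal,
                           e_dot_total=total, e_dot_net=total - basal)

    def __repr__(self) -> str:  # pragma: no cover
        return f"BhargavaModel(mode={self.mode!r})"


def _active_fl_of_state(state: MuscleState, params: MuscleParams) -> float:
    from .muscle import active_force_length

    return float(active_force_length(state.l_fiber_norm))


def bhargava_rate(state: MuscleState, e: float, params: MuscleParams,
                  coeffs: BhargavaCoefficients | None = None,
                  **model_kwargs) -> EnergyRates:
    """Functional wrapper over :class:`BhargavaModel` (exact mode defaults)."""
    return BhargavaModel(coeffs, **model_kwargs).rate(state, e, params)


def margaria_rate(p_fiber):
    """Efficiency-based metabolic rate (W) from fiber power (W).

    ``p+ / 0.25 + p- / (-1.2)`` with ``p+ = max(p, 0)``, ``p- = min(p, 0)``;
    nonnegative, piecewise linear, zero only at zero power.
    """
    p = np.asarray(p_fiber, dtype=float)
    if not np.all(np.isfinite(p)):
        raise ValueError("fiber power must be finite")
    out = np.maximum(p, 0.0) / EFF_CONCENTRIC + np.minimum(p, 0.0) / EFF_ECCENTRIC
    return out if out.ndim else float(out)


class MargariaModel:
    """Efficiency-based metabolic model (constant concentric/eccentric efficiencies)."""

    name = "margaria"

    def rate(self, state: MuscleState, e: float, params: MuscleParams,
             t_stim: float | None = None) -> EnergyRates:
        total = margaria_rate(state.p_fiber)
        return EnergyRates(h_act=0.0, h_maint=0.0,
                           h_sl=total - state.p_fiber, w_dot=state.p_fiber,
                           basal=0.0, e_dot_total=total, e_dot_net=total)

    def __repr__(self) -> str:  # pragma: no cover
        return "MargariaModel()"


def integrate_energy(rates: list[EnergyRates] | np.ndarray, t: np.ndarray,
                     as_components: bool = True):
    """Trapezoidal stride integrals (J) of metabolic rate series.

    ``rates`` is either a sequence of :class:`EnergyRates` (component-wise
    integrals are returned as a dict) or a plain array of total rates (a
    single float is returned). ``E_net = E_total - E_basal``.
    """
    t = np.asarray(t, dtype=float)
    if t.ndim != 1 or np.any(np.diff(t) <= 0):
        raise ValueError("time grid must be strictly increasing")
    if isinstance(rates, (list, tuple)) and rates and isinstance(rates[0], EnergyRates):
        out = {}
        for comp in ("h_act", "h_maint", "h_sl", "w_dot", "basal",
                     "e_dot_total", "e_dot_net"):
            series = np.array([getattr(r, comp) for r in rates], dtype=float)
            if series.shape != t.shape:
                raise ValueError("rate series does not share the time grid")
            out[comp.replace("_dot", "").replace("h_", "Q_")] = float(np.trapezoid(series, t))
        out["E_total"] = out.pop("e_total")
        out["E_net"] = out.pop("e_net")
        out["W_fiber"] = out.pop("w")
        out["E_basal"] = out.pop("basal")
        return out
    series = np.asarray(rates, dtype=float)
    if series.shape != t.shape:
        raise ValueError("rate series does not share the time grid")
    return float(np.trapezoid(series, t))
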