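"""Stride-level mechanical-work and metabolic accounting.

Container :class:`GaitTrial` holds one full stride — per-muscle fiber
trajectories, joint kinematics/kinetics, torque-motor excitations, ground
contact channels — plus the condition metadata (speed, slope, added mass).
Operations decompose fiber work, integrate metabolic energy, form the cost of
transport, activation costs (plain and volume-weighted), the multi-term
optimal-control cost function, passive joint torques and dissipation
energies. All integrals are trapezoidal on the trial's native grid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .energetics import EnergyRates, integrate_energy
from .muscle import MuscleParams, MuscleState, MuscleTrajectory

__all__ = [
    "GaitTrial",
    "CostWeights",
    "EnergyBreakdown",
    "JointPassiveCoeffs",
    "fiber_work",
    "cost_of_transport",
    "activation_cost",
    "passive_torque",
    "cost_function_terms",
    "dissipation_energy",
    "muscle_energy_rates",
    "trial_metabolic_energy",
    "energy_breakdown",
]


@dataclass
class GaitTrial:
    """One stride of a (simulated) gait trial on a shared time grid.

    ``q``, ``qdot``, ``qddot``, ``tau`` are DataFrames indexed by time with
    one column per joint coordinate; ``e_arms`` and ``u_slack`` likewise;
    ``contact_force`` / ``contact_velocity`` share column names (per contact
    channel). ``condition`` carries slope (%), added-mass spec and flags.
    """

    t: np.ndarray
    muscles: dict[str, MuscleTrajectory]
    stride_time: float
    speed: float
    q: pd.DataFrame | None = None
    qdot: pd.DataFrame | None = None
    qddot: pd.DataFrame | None = None
    tau: pd.DataFrame | None = None
    e_arms: pd.DataFrame | None = None
    u_slack: pd.DataFrame | None = None
    contact_force: pd.DataFrame | None = None
    contact_velocity: pd.DataFrame | None = None
    condition: dict = field(default_factory=dict)
    body_mass: float = 62.0

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        if self.t.ndim != 1 or np.any(np.diff(self.t) <= 0):
            raise ValueError("time grid must be strictly increasing")
        if not self.stride_time > 0:
            raise ValueError("stride_time must be > 0")
        if self.speed < 0:
            raise ValueError("speed must be >= 0")
        n = self.t.size
        for name, traj in self.muscles.items():
            if traj.t.shape != self.t.shape or not np.allclose(traj.t, self.t):
                raise ValueError(f"muscle {name} does not share the trial grid")
        for name in ("q", "qdot", "qddot", "tau", "e_arms", "u_slack",
                     "contact_force", "contact_velocity"):
            df = getattr(self, name)
            if df is not None and len(df) != n:
                raise ValueError(f"channel table {name} does not share the trial grid")


@dataclass(frozen=True)
class CostWeights:
    """Nonnegative weights of the multi-term gait cost function.

    The cost is ``J = (1/d) * sum_i w_i * int ||.||_2^2 dt`` over metabolic
    power (w1), muscle activations (w2), joint accelerations (w3), passive
    torques (w4), arm-motor excitations (w5) and slack controls (w6);
    ``d`` is the normalization distance (m), by default the distance
    traveled per gait cycle.
    """

    w_metab: float = 1.0
    w_act: float = 1.0
    w_qdd: float = 1.0
    w_passive: float = 1.0
    w_arms: float = 1.0
    w_slack: float = 1.0
    d: float | None = None  # None -> speed * stride_time of the trial

    def __post_init__(self) -> None:
        for f in ("w_metab", "w_act", "w_qdd", "w_passive", "w_arms", "w_slack"):
            if getattr(self, f) < 0:
                raise ValueError(f"{f} must be >= 0")
        if self.d is not None and not self.d > 0:
            raise ValueError("normalization distance d must be > 0")


@dataclass
class EnergyBreakdown:
    """Per-muscle and whole-body stride energy accounting (J)."""

    per_muscle: pd.DataFrame  # rows: muscles; cols W_pos, W_neg, W_net, E_total, E_net
    W_pos: float
    W_neg: float
    W_net: float
    E_total: float
    E_net: float
    mean_power: float  # stride-average total metabolic power (W)
    cot: float | None  # J/kg/m on net energy; None if speed is 0

    def to_csv(self, path) -> None:
        df = self.per_muscle.copy()
        df.loc["TOTAL"] = [self.W_pos, self.W_neg, self.W_net,
                           self.E_total, self.E_net]
        df.to_csv(path, index_label="muscle")


@dataclass(frozen=True)
class JointPassiveCoeffs:
    """Passive joint torque coefficients: double-exponential limit stiffness
    engaging near the range-of-motion bounds plus linear damping.

    ``T(q, qdot) = -k * (exp(s*(q - q_high)) - exp(-s*(q - q_low))) - c*qdot``
    """

    k: float = 2.0        # N*m, limit stiffness scale
    s: float = 5.0        # 1/rad, engagement sharpness
    q_low: float = -1.0   # rad, lower engagement limit
    q_high: float = 1.0   # rad, upper engagement limit
    damping: float = 0.1  # N*m*s/rad


# ---------------------------------------------------------------------------
# Work and energy
# ---------------------------------------------------------------------------

def fiber_work(trajectory: MuscleTrajectory) -> dict:
    """Positive, negative and net fiber work (J) over the stride.

    Trapezoidal integrals of ``max(p, 0)``, ``min(p, 0)`` and ``p``;
    ``W_net = W_pos + W_neg``.
    """
    t, p = trajectory.t, trajectory.p_fiber
    w_pos = float(np.trapezoid(np.maximum(p, 0.0), t))
    w_neg = float(np.trapezoid(np.minimum(p, 0.0), t))
    return {"W_pos": w_pos, "W_neg": w_neg, "W_net": w_pos + w_neg}


def cost_of_transport(E: float, body_mass: float, speed: float,
                      stride_time: float) -> float:
    """Metabolic cost of transport (J/kg/m): ``E / (m * speed * stride_time)``."""
    if body_mass <= 0 or speed <= 0 or stride_time <= 0:
        raise ValueError("body_mass, speed and stride_time must be > 0")
    return E / (body_mass * speed * stride_time)


def muscle_energy_rates(traj: MuscleTrajectory, model,
                        params: MuscleParams | None = None) -> list[EnergyRates]:
    """Metabolic rate components along one muscle trajectory.

    Parameters may be omitted for models that depend only on the fiber state
    (the efficiency-based model); heat-rate models require them.
    """
    p = params if params is not None else traj.params
    rates = []
    for i in range(traj.t.size):
        state = MuscleState(
            a=float(traj.a[i]), l_fiber_norm=float(traj.l_fiber_norm[i]),
            v_fiber_norm=float(traj.v_fiber_norm[i]),
            f_fiber=float(traj.f_fiber[i]), f_tendon=float(traj.f_tendon[i]),
            p_fiber=float(traj.p_fiber[i]))
        rates.append(model.rate(state, float(traj.e[i]), p,
                                t_stim=float(traj.t[i] - traj.t[0])))
    return rates


def trial_metabolic_energy(trial: GaitTrial, model) -> float:
    """Summed stride-integrated total metabolic energy (J) over all muscles."""
    total = 0.0
    for traj in trial.muscles.values():
        rates = muscle_energy_rates(traj, model)
        total += integrate_energy(rates, traj.t)["E_total"]
    return total


def energy_breakdown(trial: GaitTrial, model,
                     basal_rate: float = 0.0) -> EnergyBreakdown:
    """Full stride accounting: per-muscle work and metabolic energy plus totals.

    ``basal_rate`` is a whole-body basal metabolic rate (W) subtracted over
    the stride to form net metabolic energy; the cost of transport is
    reported on the net energy (and equals the total-energy value when the
    basal rate is zero).
    """
    rows = {}
    for name, traj in trial.muscles.items():
        w = fiber_work(traj)
        rates = muscle_energy_rates(traj, model)
        e = integrate_energy(rates, traj.t)
        rows[name] = [w["W_pos"], w["W_neg"], w["W_net"],
                      e["E_total"], e["E_net"]]
    df = pd.DataFrame.from_dict(
        rows, orient="index",
        columns=["W_pos", "W_neg", "W_net", "E_total", "E_net"])
    E_total = float(df["E_total"].sum())
    E_net = E_total - basal_rate * trial.stride_time
    cot = None
    if trial.speed > 0:
        cot = cost_of_transport(E_net, trial.body_mass, trial.speed,
                                trial.stride_time)
    return EnergyBreakdown(
        per_muscle=df,
        W_pos=float(df["W_pos"].sum()), W_neg=float(df["W_neg"].sum()),
        W_net=float(df["W_net"].sum()),
        E_total=E_total, E_net=E_net,
        mean_power=E_total / trial.stride_time, cot=cot)


# ---------------------------------------------------------------------------
# Activation cost
# ---------------------------------------------------------------------------

def activation_cost(trial: GaitTrial, subset: list[str] | None = None,
                    weighting: str = "uniform",
                    volumes: Mapping[str, float] | None = None) -> float:
    """Time-averaged mean activation over a muscle subset.

    ``weighting='volume'`` weights each muscle by its relative volume; when
    no volume table is supplied the proxy ``f_iso_max * l_opt`` is used
    (proportional to muscle volume at fixed specific tension).
    """
    names = list(trial.muscles) if subset is None else list(subset)
    unknown = [n for n in names if n not in trial.muscles]
    if unknown:
        raise KeyError(f"unknown muscle name(s): {unknown}")
    if weighting not in ("uniform", "volume"):
        raise ValueError("weighting must be 'uniform' or 'volume'")

    T = trial.t[-1] - trial.t[0]
    means = {}
    for n in names:
        traj = trial.muscles[n]
        means[n] = float(np.trapezoid(traj.a, traj.t)) / T

    if weighting == "uniform":
        w = {n: 1.0 for n in names}
    else:
        if volumes is not None:
            w = {n: float(volumes[n]) for n in names}
        else:
            w = {}
            for n in names:
                p = trial.muscles[n].params
                if p is None:
                    raise ValueError(
                        f"muscle {n} has no params; supply a volume table")
                w[n] = p.f_iso_max * p.l_opt
    wsum = sum(w.values())
    return sum(w[n] * means[n] for n in names) / wsum


# ---------------------------------------------------------------------------
# Passive torques and the cost function
# ---------------------------------------------------------------------------

def passive_torque(q, qdot, coeffs: JointPassiveCoeffs):
    """Passive joint torque (N*m): limit stiffness + linear damping.

    Near-zero inside the range of motion; the exponential terms engage near
    the ``q_low`` / ``q_high`` limits, resisting further motion; the damping
    term is ``-c * qdot``.
    """
    q = np.asarray(q, dtype=float)
    qdot = np.asarray(qdot, dtype=float)
    stiff = -coeffs.k * (np.exp(coeffs.s * (q - coeffs.q_high))
                         - np.exp(-coeffs.s * (q - coeffs.q_low)))
    out = stiff - coeffs.damping * qdot
    return out if out.ndim else float(out)


def _sq_norm_integral(df: pd.DataFrame, t: np.ndarray) -> float:
    vals = df.to_numpy(dtype=float)
    return float(np.trapezoid(np.sum(vals * vals, axis=1), t))


def cost_function_terms(trial: GaitTrial, weights: CostWeights, model,
                        passive_coeffs: Mapping[str, JointPassiveCoeffs] | None = None,
                        ) -> dict:
    """Evaluate the multi-term gait cost function on a trial.

    Each term is ``w_i / d * int ||.||^2 dt`` (instantaneous squared 2-norm
    over the relevant vector channel). Returns the per-term audit dictionary
    plus the total ``J``. Terms with zero weight are skipped, so their
    channels need not be present; a missing channel with nonzero weight
    raises a per-term error naming the channel.
    """
    d = weights.d if weights.d is not None else trial.speed * trial.stride_time
    if not d > 0:
        raise ValueError("normalization distance is not positive "
                         "(zero speed trial needs explicit d)")
    t = trial.t
    terms: dict[str, float] = {}

    def need(channel, term):
        val = getattr(trial, channel, None)
        if val is None:
            raise ValueError(f"cost term '{term}' requires trial channel '{channel}'")
        return val

    if weights.w_metab > 0:
        rates = []
        for name, traj in trial.muscles.items():
            r = muscle_energy_rates(traj, model)
            rates.append([x.e_dot_total for x in r])
        if not rates:
            raise ValueError("cost term 'metabolic' requires muscle trajectories")
        arr = np.asarray(rates).T  # time x muscles
        terms["metabolic"] = weights.w_metab / d * float(
            np.trapezoid(np.sum(arr * arr, axis=1), t))
    else:
        terms["metabolic"] = 0.0

    if weights.w_act > 0:
        acts = np.column_stack([traj.a for traj in trial.muscles.values()])
        terms["activation"] = weights.w_act / d * float(
            np.trapezoid(np.sum(acts * acts, axis=1), t))
    else:
        terms["activation"] = 0.0

    terms["joint_acc"] = (weights.w_qdd / d * _sq_norm_integral(need("qddot", "joint_acc"), t)
                          if weights.w_qdd > 0 else 0.0)

    if weights.w_passive > 0:
        q = need("q", "passive_torque")
        qdot = need("qdot", "passive_torque")
        coeffs = passive_coeffs or {}
        cols = {}
        for joint in q.columns:
            c = coeffs.get(joint)
            if c is None:
                raise ValueError(
                    f"cost term 'passive_torque' is missing coefficients for joint '{joint}'")
            cols[joint] = passive_torque(q[joint].to_numpy(), qdot[joint].to_numpy(), c)
        tp = pd.DataFrame(cols)
        terms["passive_torque"] = weights.w_passive / d * _sq_norm_integral(tp, t)
    else:
        terms["passive_torque"] = 0.0

    terms["arm_excitation"] = (weights.w_arms / d * _sq_norm_integral(need("e_arms", "arm_excitation"), t)
                               if weights.w_arms > 0 else 0.0)
    terms["slack"] = (weights.w_slack / d * _sq_norm_integral(need("u_slack", "slack"), t)
                      if weights.w_slack > 0 else 0.0)

    terms["total"] = sum(v for k, v in terms.items() if k != "total")
    return terms


def dissipation_energy(trial: GaitTrial,
                       damper_coeffs: Mapping[str, float] | None = None,
                       passive_coeffs: Mapping[str, JointPassiveCoeffs] | None = None,
                       ) -> dict:
    """Stride energy dissipated in joint dampers and in the ground contact (J).

    ``E_damper = sum_joints int c * qdot^2 dt`` with per-joint damping
    coefficients (N*m*s/rad), taken from ``damper_coeffs`` or from the
    damping fields of ``passive_coeffs``. ``E_contact`` is the net negative
    work of the contact forces, reported as positive dissipation:
    ``-int sum_channels F . v dt`` restricted to instants of dissipative
    (negative) contact power.
    """
    out = {}
    if damper_coeffs is None and passive_coeffs is not None:
        damper_coeffs = {j: c.damping for j, c in passive_coeffs.items()}
    if damper_coeffs is not None:
        if trial.qdot is None:
            raise ValueError("dissipation_energy requires trial channel 'qdot'")
        e = 0.0
        for joint, c in damper_coeffs.items():
            if joint not in trial.qdot.columns:
                raise ValueError(f"joint '{joint}' not in qdot channels")
            qd = trial.qdot[joint].to_numpy(dtype=float)
            e += float(np.trapezoid(c * qd * qd, trial.t))
        out["E_damper"] = e

    if trial.contact_force is not None or trial.contact_velocity is not None:
        if trial.contact_force is None or trial.contact_velocity is None:
            raise ValueError("contact dissipation requires both force and velocity channels")
        f = trial.contact_force.to_numpy(dtype=float)
        v = trial.contact_velocity[trial.contact_force.columns].to_numpy(dtype=float)
        power = np.sum(f * v, axis=1)
        out["E_contact"] = float(-np.trapezoid(np.minimum(power, 0.0), trial.t))
    return out
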