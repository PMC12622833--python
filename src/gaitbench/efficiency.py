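"""Isokinetic maximal-efficiency analysis and gait efficiency ratios.

Mechanical efficiency is fiber mechanical power divided by total metabolic
power. The isokinetic protocol clamps the fiber state directly — full
activation, optimal fiber length, a prescribed contraction velocity, no
tendon and no activation dynamics — and sweeps the normalized velocity grid,
mirroring how maximal muscle efficiency is characterized experimentally.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .energetics import BhargavaModel, MargariaModel
from .muscle import MuscleParams, MuscleState, force_velocity

__all__ = [
    "EfficiencyCurve",
    "EfficiencySummary",
    "isokinetic_state",
    "isokinetic_sweep",
    "aggregate_efficiency",
    "gait_efficiency_ratios",
    "default_sweep_model",
]


class UndefinedEfficiencyError(ZeroDivisionError):
    """Metabolic rate is exactly zero at nonzero mechanical power."""


@dataclass
class EfficiencyCurve:
    """Mechanical efficiency vs normalized fiber velocity for one muscle.

    ``v_grid`` is lengthening-positive (shortening < 0). ``max_concentric``
    is the maximal efficiency over shortening velocities; ``min_eccentric``
    the signed minimum (most negative) over lengthening velocities.
    Efficiency is exactly 0 at v = 0 for heat-rate models (zero mechanical
    power, positive heat); bounds away from 0 are empirical outputs, not
    invariants.
    """

    muscle: str
    v_grid: np.ndarray
    efficiency: np.ndarray
    max_concentric: float
    v_at_max: float
    min_eccentric: float
    v_at_min: float


@dataclass
class EfficiencySummary:
    """Across-muscle summary of isokinetic efficiency extrema."""

    n_muscles: int
    mean_max_concentric: float
    min_max_concentric: float
    max_max_concentric: float
    mean_min_eccentric: float
    min_min_eccentric: float
    max_min_eccentric: float


def default_sweep_model() -> BhargavaModel:
    """Heat-rate model configured for the sweep (smooth positivity).

    The smooth mode keeps the total rate strictly positive at full
    activation, so the efficiency ratio is defined on the whole velocity
    grid (with the hard clamp, fast lengthening drives the clamped total to
    exactly zero).
    """
    return BhargavaModel(mode="smooth")


def isokinetic_state(params: MuscleParams, v_norm: float) -> MuscleState:
    """Clamped fiber state: a = 1, optimal length, prescribed velocity, no tendon."""
    f = params.f_iso_max * force_velocity(v_norm)
    v_mps = v_norm * params.v_max_mps
    return MuscleState(a=1.0, l_fiber_norm=1.0, v_fiber_norm=v_norm,
                       f_fiber=f, f_tendon=f, p_fiber=-f * v_mps)


def _efficiency_at(params: MuscleParams, model, v_norm: float) -> float:
    state = isokinetic_state(params, v_norm)
    rate = model.rate(state, 1.0, params)
    if state.p_fiber == 0.0:
        return 0.0
    if rate.e_dot_total == 0.0:
        raise UndefinedEfficiencyError(
            f"zero metabolic rate at v_norm={v_norm:g} for muscle {params.name}")
    return state.p_fiber / rate.e_dot_total


def isokinetic_sweep(
    params: MuscleParams,
    model=None,
    v_grid: np.ndarray | None = None,
    refine_passes: int = 2,
    refine_factor: int = 10,
) -> EfficiencyCurve:
    """Sweep fiber velocities at maximal activation and optimal length.

    ``v_grid`` defaults to 2001 points on [-0.999, 0.999] (normalized by
    v_max, singular endpoints excluded). Extrema are sharpened by
    ``refine_passes`` local grid refinements (each ``refine_factor`` x finer
    around the current optimum) for argmax stability.
    """
    if model is None:
        model = default_sweep_model()
    if v_grid is None:
        v_grid = np.linspace(-0.999, 0.999, 2001)
    v_grid = np.asarray(v_grid, dtype=float)
    if not (np.any(v_grid < 0) and np.any(v_grid > 0)):
        raise ValueError("v_grid must span shortening and lengthening velocities")

    eff = np.array([_efficiency_at(params, model, v) for v in v_grid])

    def _refine(mask, pick):
        vv, ee = v_grid[mask], eff[mask]
        i = pick(ee)
        v_best, e_best = vv[i], ee[i]
        lo = vv[max(i - 1, 0)]
        hi = vv[min(i + 1, vv.size - 1)]
        for _ in range(refine_passes):
            sub = np.linspace(lo, hi, 2 * refine_factor + 1)
            sub_eff = np.array([_efficiency_at(params, model, v) for v in sub])
            j = pick(sub_eff)
            if (pick is np.argmax and sub_eff[j] > e_best) or \
               (pick is np.argmin and sub_eff[j] < e_best):
                v_best, e_best = sub[j], sub_eff[j]
            lo = sub[max(j - 1, 0)]
            hi = sub[min(j + 1, sub.size - 1)]
        return float(e_best), float(v_best)

    max_c, v_max_c = _refine(v_grid < 0, np.argmax)
    min_e, v_min_e = _refine(v_grid > 0, np.argmin)
    return EfficiencyCurve(muscle=params.name, v_grid=v_grid, efficiency=eff,
                           max_concentric=max_c, v_at_max=v_max_c,
                           min_eccentric=min_e, v_at_min=v_min_e)


def aggregate_efficiency(curves: list[EfficiencyCurve]) -> EfficiencySummary:
    """Mean/min/max of the per-muscle efficiency extrema."""
    if not curves:
        raise ValueError("need at least one efficiency curve")
    mc = np.array([c.max_concentric for c in curves])
    me = np.array([c.min_eccentric for c in curves])
    return EfficiencySummary(
        n_muscles=len(curves),
        mean_max_concentric=float(mc.mean()),
        min_max_concentric=float(mc.min()),
        max_max_concentric=float(mc.max()),
        mean_min_eccentric=float(me.mean()),
        min_min_eccentric=float(me.min()),
        max_min_eccentric=float(me.max()),
    )


def gait_efficiency_ratios(trial, model, basal_rate: float = 0.0) -> dict:
    """Stride efficiencies of net and positive fiber work.

    ``eff_net = W_net(all fibers) / E_net_metab`` and
    ``eff_positive = W_pos(all fibers) / E_net_metab``, where the net
    metabolic energy is the summed stride-integrated metabolic energy minus
    ``basal_rate * stride_time`` (whole-body basal, W).
    """
    from .stride import fiber_work, trial_metabolic_energy

    w_pos = w_net = 0.0
    for traj in trial.muscles.values():
        w = fiber_work(traj)
        w_pos += w["W_pos"]
        w_net += w["W_net"]
    e_total = trial_metabolic_energy(trial, model)
    e_net = e_total - basal_rate * trial.stride_time
    if e_net <= 0.0:
        raise UndefinedEfficiencyError("net metabolic energy is not positive")
    return {"eff_net": w_net / e_net, "eff_positive": w_pos / e_net,
            "W_pos": w_pos, "W_net": w_net, "E_net": e_net}
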