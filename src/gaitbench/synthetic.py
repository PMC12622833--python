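"""Seeded synthetic-data generators for every pipeline stage.

The generators emulate the *structure* of muscle-driven gait data — a
lower-limb muscle parameter set, periodic ~1 s strides with bounded
excitations, and condition-level outcome tables with a known linear relation
between simulated and measured changes — so that every operation in the
package is testable without any download. They do not attempt biomechanical
realism of whole-body motion; trajectories are feasibility-by-construction
(MTU lengths oscillate around an operating point where the fiber-tendon
equilibrium is well conditioned).

A single root seed is expanded through ``numpy.random.SeedSequence`` spawn
keys (0 = muscles, 1 = trial, 2 = conditions) so subsystem draws are
independent and stable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .muscle import MuscleParams, MuscleTrajectory, solve_trajectory
from .normalization import Anthropometry, ConditionDataset
from .stride import GaitTrial

__all__ = [
    "SynthConfig",
    "gen_muscle_params",
    "gen_gait_trial",
    "gen_condition_dataset",
]


@dataclass(frozen=True)
class SynthConfig:
    """Generator configuration; the seed fixes all outputs bit-for-bit."""

    seed: int = 0
    n_muscles: int = 92
    stride_time: float = 1.1      # s, typical stride at ~1.1-1.3 m/s
    n_timesteps: int = 101
    speed: float = 1.3            # m/s
    body_mass: float = 62.0       # kg, matches the default model anthropometry
    stature: float = 1.70         # m
    frac_slow_beta: tuple[float, float] = (2.0, 2.0)
    excitation_level: float = 0.4     # mean excitation
    excitation_amplitude: float = 0.3
    mtu_excursion: float = 0.05   # MTU length amplitude, fraction of l_opt
    n_joints: int = 6
    n_contacts: int = 4

    def __post_init__(self) -> None:
        if self.n_timesteps < 50:
            raise ValueError("n_timesteps must be >= 50")
        if self.stride_time <= 0 or self.speed < 0:
            raise ValueError("stride_time must be > 0 and speed >= 0")

    @property
    def anthropometry(self) -> Anthropometry:
        return Anthropometry(body_mass=self.body_mass, stature=self.stature)

    def rng(self, stream: int) -> np.random.Generator:
        """Sub-stream generator: 0 = muscles, 1 = trial, 2 = conditions."""
        return np.random.default_rng(np.random.SeedSequence(self.seed).spawn(3)[stream])


def gen_muscle_params(cfg: SynthConfig) -> list[MuscleParams]:
    """Physiologically bounded random muscle parameter set.

    ``f_iso_max`` log-uniform on [100, 5000] N, ``l_opt`` uniform on
    [0.05, 0.15] m, tendon slack length proportional to ``l_opt`` with
    jitter, pennation up to ~20 degrees, ``frac_slow`` from the configured
    Beta distribution, ``v_max`` fixed at the default 10 optimal fiber
    lengths per second.
    """
    rng = cfg.rng(0)
    muscles = []
    for i in range(cfg.n_muscles):
        f_iso = float(np.exp(rng.uniform(math.log(100.0), math.log(5000.0))))
        l_opt = float(rng.uniform(0.05, 0.15))
        slack_ratio = float(rng.uniform(1.2, 2.5))
        alpha = float(rng.uniform(0.0, 0.35))
        frac_slow = float(rng.beta(*cfg.frac_slow_beta))
        muscles.append(MuscleParams(
            name=f"m{i:03d}", f_iso_max=f_iso, l_opt=l_opt,
            l_tendon_slack=slack_ratio * l_opt, alpha_opt=alpha,
            frac_slow=frac_slow))
    return muscles


def _fourier_series(t: np.ndarray, T: float, offset: float,
                    amps: np.ndarray, phases: np.ndarray,
                    derivative: int = 0) -> np.ndarray:
    """Truncated Fourier series (exactly periodic in T) or its derivatives."""
    out = np.full_like(t, offset if derivative == 0 else 0.0)
    for k, (A, ph) in enumerate(zip(amps, phases), start=1):
        w = 2.0 * math.pi * k / T
        arg = w * t + ph
        if derivative == 0:
            out = out + A * np.sin(arg)
        elif derivative == 1:
            out = out + A * w * np.cos(arg)
        elif derivative == 2:
            out = out - A * w * w * np.sin(arg)
        else:
            raise ValueError("derivative must be 0, 1 or 2")
    return out


def gen_gait_trial(cfg: SynthConfig,
                   params: list[MuscleParams] | None = None,
                   tendon_mode: str = "compliant") -> GaitTrial:
    """Periodic synthetic stride through the full muscle pipeline.

    MTU lengths are truncated Fourier series around an operating point just
    above tendon slack with the fiber near optimal length (guaranteeing a
    well-posed equilibrium at every sample); excitations are smooth periodic
    signals in [0, 1]; activations come from integrating the activation
    dynamics to a periodic orbit; fiber states from the equilibrium solver.
    Joint, arm, slack and stance-phase contact channels are consistent
    periodic signals. Every channel's first and last samples agree to 1e-9.
    """
    if params is None:
        params = gen_muscle_params(cfg)
    rng = cfg.rng(1)
    T = cfg.stride_time
    t = np.linspace(0.0, T, cfg.n_timesteps)

    muscles: dict[str, MuscleTrajectory] = {}
    for p in params:
        # operating point: fiber at optimal length, tendon just above slack
        l0 = p.l_tendon_slack * 1.002 + p.l_opt * math.cos(p.alpha_opt)
        n_harm = 3
        amps = cfg.mtu_excursion * p.l_opt * rng.uniform(0.3, 1.0, n_harm) / \
            np.arange(1, n_harm + 1)
        phases = rng.uniform(0.0, 2.0 * math.pi, n_harm)
        l_mtu = _fourier_series(t, T, l0, amps, phases)
        v_mtu = _fourier_series(t, T, l0, amps, phases, derivative=1)

        e0 = cfg.excitation_level
        e_amp = max(0.0, min(cfg.excitation_amplitude, e0 - 0.02, 0.98 - e0))
        e_amp *= float(rng.uniform(0.5, 1.0))
        e_phase = float(rng.uniform(0.0, 2.0 * math.pi))
        e = e0 + e_amp * np.sin(2.0 * math.pi * t / T + e_phase)
        e = np.clip(e, 0.0, 1.0)

        traj = solve_trajectory(t, l_mtu, e, p, tendon_mode=tendon_mode,
                                v_mtu=v_mtu, periodic=True, stride_time=T)
        muscles[p.name] = traj

    def periodic_table(n_cols, offset, amp, prefix, n_harm=2, clip=None):
        cols = {}
        for j in range(n_cols):
            amps = amp * rng.uniform(0.3, 1.0, n_harm) / np.arange(1, n_harm + 1)
            phases = rng.uniform(0.0, 2.0 * math.pi, n_harm)
            y = _fourier_series(t, T, offset, amps, phases)
            if clip is not None:
                y = np.clip(y, *clip)
            cols[f"{prefix}{j}"] = y
        return pd.DataFrame(cols, index=t)

    # joint kinematics as consistent Fourier series (qdot, qddot analytic)
    q_cols, qd_cols, qdd_cols = {}, {}, {}
    for j in range(cfg.n_joints):
        amps = 0.3 * rng.uniform(0.3, 1.0, 2) / np.array([1.0, 2.0])
        phases = rng.uniform(0.0, 2.0 * math.pi, 2)
        name = f"joint{j}"
        q_cols[name] = _fourier_series(t, T, 0.0, amps, phases)
        qd_cols[name] = _fourier_series(t, T, 0.0, amps, phases, derivative=1)
        qdd_cols[name] = _fourier_series(t, T, 0.0, amps, phases, derivative=2)
    q = pd.DataFrame(q_cols, index=t)
    qdot = pd.DataFrame(qd_cols, index=t)
    qddot = pd.DataFrame(qdd_cols, index=t)
    tau = periodic_table(cfg.n_joints, 0.0, 40.0, "joint")
    tau.columns = q.columns
    e_arms = periodic_table(4, 0.2, 0.15, "arm", clip=(0.0, 1.0))
    u_slack = periodic_table(4, 0.0, 0.01, "slack")

    # stance-phase vertical contact force profile (zero in swing), small
    # contact-point velocities -> mostly dissipative contact power
    stance_frac = 0.6
    s = (t / T) % 1.0
    bump = np.where(s < stance_frac,
                    np.sin(math.pi * s / stance_frac) ** 2, 0.0)
    f_cols, v_cols = {}, {}
    g = 9.81
    for j in range(cfg.n_contacts):
        share = float(rng.uniform(0.5, 1.5)) / cfg.n_contacts
        f_cols[f"c{j}"] = 1.1 * cfg.body_mass * g * share * bump
        v_cols[f"c{j}"] = -0.02 * float(rng.uniform(0.5, 1.5)) * bump
    contact_force = pd.DataFrame(f_cols, index=t)
    contact_velocity = pd.DataFrame(v_cols, index=t)

    return GaitTrial(
        t=t, muscles=muscles, stride_time=T, speed=cfg.speed,
        q=q, qdot=qdot, qddot=qddot, tau=tau,
        e_arms=e_arms, u_slack=u_slack,
        contact_force=contact_force, contact_velocity=contact_velocity,
        condition={"slope": 0.0, "added_mass": None, "crouch": False},
        body_mass=cfg.body_mass)


def gen_condition_dataset(cfg: SynthConfig,
                          true_slope: float = 0.73,
                          true_intercept: float = 0.0,
                          noise_sd: float = 5.0,
                          n_conditions: int = 100,
                          outcome: str = "metabolic_power",
                          baseline: float = 300.0,
                          delta_range: tuple[float, float] = (-50.0, 400.0),
                          ) -> tuple[ConditionDataset, ConditionDataset, dict]:
    """Paired condition datasets with a known sim-vs-exp linear relation.

    Experimental deltas (changes from the reference condition) are drawn
    uniformly over ``delta_range`` (W); simulated deltas follow
    ``true_intercept + true_slope * exp_delta`` plus seeded Gaussian noise
    with standard deviation ``noise_sd`` (noise on the simulated side, the
    regression response of :func:`gaitbench.normalization.compare`, so the
    slope is recovered without attenuation). Returns
    ``(sim_dataset, exp_dataset, truth)``.
    """
    rng = cfg.rng(2)
    exp_delta = rng.uniform(*delta_range, n_conditions)
    noise = rng.normal(0.0, noise_sd, n_conditions) if noise_sd > 0 else \
        np.zeros(n_conditions)
    sim_delta = true_intercept + true_slope * exp_delta + noise

    def build(deltas, source):
        rows = [{"condition": "ref", "speed": 1.1, "slope": 0.0,
                 "added_mass": 0.0, "outcome": outcome,
                 "value": baseline, "source": source}]
        for i, d in enumerate(deltas):
            rows.append({"condition": f"c{i:03d}", "speed": 1.1, "slope": 0.0,
                         "added_mass": 0.0, "outcome": outcome,
                         "value": baseline + float(d), "source": source})
        return ConditionDataset(pd.DataFrame(rows), reference="ref")

    truth = {"slope": true_slope, "intercept": true_intercept,
             "noise_sd": noise_sd, "exp_delta": exp_delta,
             "sim_delta": sim_delta}
    return build(sim_delta, "simulation"), build(exp_delta, "experiment"), truth
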