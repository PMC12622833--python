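"""Stride-level accounting: work, COT, activation cost, cost function, dissipation."""

import numpy as np
import pandas as pd
import pytest

from gaitbench import (
    CostWeights,
    JointPassiveCoeffs,
    MargariaModel,
    MuscleParams,
    MuscleTrajectory,
    activation_cost,
    cost_function_terms,
    cost_of_transport,
    dissipation_energy,
    energy_breakdown,
    fiber_work,
    passive_torque,
)
from gaitbench.stride import GaitTrial


def make_traj(t, p_fiber, a=None, params=None, stride_time=None):
    n = t.size
    a = np.full(n, 0.5) if a is None else np.asarray(a, dtype=float)
    return MuscleTrajectory(
        t=t, e=a.copy(), a=a, l_fiber_norm=np.ones(n),
        v_fiber_norm=np.zeros(n), f_fiber=np.zeros(n), f_tendon=np.zeros(n),
        p_fiber=np.asarray(p_fiber, dtype=float),
        stride_time=stride_time if stride_time else float(t[-1] - t[0]),
        params=params)


class TestFiberWork:
    def test_constant_positive_power(self):
        t = np.linspace(0.0, 1.0, 101)
        w = fiber_work(make_traj(t, np.full(t.size, 50.0)))
        assert w["W_pos"] == pytest.approx(50.0)
        assert w["W_neg"] == 0.0
        assert w["W_net"] == pytest.approx(50.0)

    def test_sinusoid_closed_form(self):
        A, T = 80.0, 1.2
        t = np.linspace(0.0, T, 4001)
        w = fiber_work(make_traj(t, A * np.sin(2 * np.pi * t / T)))
        assert w["W_net"] == pytest.approx(0.0, abs=1e-9)
        assert w["W_pos"] == pytest.approx(A * T / np.pi, rel=1e-6)
        assert w["W_neg"] == pytest.approx(-A * T / np.pi, rel=1e-6)

    def test_piecewise_cubic_analytic_oracle(self):
        # p(t) = t^3 - t on [0, 2]: negative on (0,1), positive on (1,2)
        t = np.linspace(0.0, 2.0, 200001)
        p = t ** 3 - t
        w = fiber_work(make_traj(t, p))
        # int_1^2 (t^3 - t) dt = 15/4 - 3/2 = 9/4 ; int_0^1 = -(1/4)
        assert w["W_pos"] == pytest.approx(9.0 / 4.0, rel=1e-9)
        assert w["W_neg"] == pytest.approx(-1.0 / 4.0, rel=1e-9)
        assert w["W_net"] == pytest.approx(w["W_pos"] + w["W_neg"], rel=1e-9)


class TestCostOfTransport:
    def test_arithmetic(self):
        assert cost_of_transport(310.0, 62.0, 1.0, 1.0) == pytest.approx(5.0)
        assert cost_of_transport(0.0, 62.0, 1.0, 1.0) == 0.0

    def test_random_inputs_match_definition(self, rng):
        for _ in range(20):
            E = rng.uniform(10, 1000)
            m = rng.uniform(40, 100)
            v = rng.uniform(0.5, 2.5)
            T = rng.uniform(0.8, 1.5)
            assert cost_of_transport(E, m, v, T) == pytest.approx(E / (m * v * T))

    def test_zero_distance_rejected(self):
        with pytest.raises(ValueError):
            cost_of_transport(100.0, 62.0, 0.0, 1.0)


class TestActivationCost:
    def _trial(self, acts, f_isos=None, l_opts=None):
        t = np.linspace(0.0, 1.0, 51)
        muscles = {}
        for i, a in enumerate(acts):
            params = None
            if f_isos is not None:
                params = MuscleParams(name=f"m{i}", f_iso_max=f_isos[i],
                                      l_opt=l_opts[i], l_tendon_slack=0.2)
            muscles[f"m{i}"] = make_traj(t, np.zeros(t.size),
                                         a=np.full(t.size, a), params=params)
        return GaitTrial(t=t, muscles=muscles, stride_time=1.0, speed=1.0)

    def test_constant_activation_both_weightings(self):
        trial = self._trial([0.3, 0.3, 0.3], f_isos=[100, 200, 300],
                            l_opts=[0.1, 0.1, 0.1])
        assert activation_cost(trial) == pytest.approx(0.3)
        assert activation_cost(trial, weighting="volume") == pytest.approx(0.3)

    def test_uniform_mean(self):
        trial = self._trial([0.0, 1.0])
        assert activation_cost(trial) == pytest.approx(0.5)

    def test_volume_weighted_mean_matches_hand_computation(self):
        acts, f_isos, l_opts = [0.2, 0.5, 0.9], [1000, 2000, 500], [0.1, 0.05, 0.2]
        trial = self._trial(acts, f_isos, l_opts)
        vols = np.array(f_isos) * np.array(l_opts)
        expected = float(np.sum(vols * acts) / vols.sum())
        assert activation_cost(trial, weighting="volume") == pytest.approx(expected)

    def test_external_volume_table(self):
        trial = self._trial([0.2, 0.8])
        got = activation_cost(trial, weighting="volume",
                              volumes={"m0": 3.0, "m1": 1.0})
        assert got == pytest.approx((3 * 0.2 + 1 * 0.8) / 4)

    def test_splitting_muscle_preserves_volume_weighted_cost(self):
        """Halving a muscle into two identical bundles shifts the uniform
        mean but not the volume-weighted one."""
        whole = self._trial([0.9, 0.1], f_isos=[2000, 2000], l_opts=[0.1, 0.1])
        split = self._trial([0.9, 0.9, 0.1], f_isos=[1000, 1000, 2000],
                            l_opts=[0.1, 0.1, 0.1])
        u_whole = activation_cost(whole)
        u_split = activation_cost(split)
        v_whole = activation_cost(whole, weighting="volume")
        v_split = activation_cost(split, weighting="volume")
        assert u_whole != pytest.approx(u_split)
        assert v_whole == pytest.approx(v_split, rel=1e-12)

    def test_unknown_muscle_rejected(self):
        trial = self._trial([0.5])
        with pytest.raises(KeyError):
            activation_cost(trial, subset=["nope"])


class TestPassiveTorque:
    def test_neutral_pose_near_zero(self):
        c = JointPassiveCoeffs()
        assert abs(passive_torque(0.0, 0.0, c)) < 0.1

    def test_pure_damping(self):
        c = JointPassiveCoeffs(damping=0.1)
        assert passive_torque(0.0, 1.0, c) == pytest.approx(-c.damping, abs=0.02)

    def test_formula_oracle(self):
        c = JointPassiveCoeffs(k=2.0, s=5.0, q_low=-1.0, q_high=1.0, damping=0.1)
        q = np.linspace(-1.4, 1.4, 57)
        qd = np.linspace(-2, 2, 57)
        expected = (-c.k * (np.exp(c.s * (q - c.q_high))
                            - np.exp(-c.s * (q - c.q_low))) - c.damping * qd)
        assert np.allclose(passive_torque(q, qd, c), expected, atol=1e-12)

    def test_resists_motion_beyond_limits(self):
        c = JointPassiveCoeffs()
        assert passive_torque(1.5, 0.0, c) < -1.0  # extension limit pushes back
        assert passive_torque(-1.5, 0.0, c) > 1.0


def _poly_trial(n_muscles=2, n_joints=2, T=1.0, n=2001):
    """Trial whose channels are simple polynomials with closed-form integrals."""
    t = np.linspace(0.0, T, n)
    muscles = {}
    for i in range(n_muscles):
        a = np.full(n, 0.5)
        muscles[f"m{i}"] = make_traj(t, np.zeros(n), a=a)
    q = pd.DataFrame({f"j{k}": np.zeros(n) for k in range(n_joints)}, index=t)
    qdot = q.copy()
    qdd = pd.DataFrame({f"j{k}": t ** (k + 1) for k in range(n_joints)}, index=t)
    e_arms = pd.DataFrame({"arm0": np.full(n, 0.2)}, index=t)
    u_slack = pd.DataFrame({"s0": t}, index=t)
    return GaitTrial(t=t, muscles=muscles, stride_time=T, speed=1.0,
                     q=q, qdot=qdot, qddot=qdd, e_arms=e_arms, u_slack=u_slack)


class TestCostFunctionTerms:
    def test_all_zero_channels_give_zero(self):
        t = np.linspace(0.0, 1.0, 101)
        muscles = {"m": make_traj(t, np.zeros(t.size), a=np.zeros(t.size))}
        trial = GaitTrial(t=t, muscles=muscles, stride_time=1.0, speed=1.0,
                          q=pd.DataFrame({"j": np.zeros(t.size)}, index=t),
                          qdot=pd.DataFrame({"j": np.zeros(t.size)}, index=t),
                          qddot=pd.DataFrame({"j": np.zeros(t.size)}, index=t),
                          e_arms=pd.DataFrame({"a": np.zeros(t.size)}, index=t),
                          u_slack=pd.DataFrame({"s": np.zeros(t.size)}, index=t))
        terms = cost_function_terms(trial, CostWeights(d=1.0), MargariaModel(),
                                    passive_coeffs={"j": JointPassiveCoeffs(k=0.0)})
        assert terms["total"] == pytest.approx(0.0, abs=1e-15)

    def test_single_activation_term(self):
        t = np.linspace(0.0, 1.0, 101)
        muscles = {"m": make_traj(t, np.zeros(t.size), a=np.full(t.size, 0.5))}
        trial = GaitTrial(t=t, muscles=muscles, stride_time=1.0, speed=1.0)
        w = CostWeights(w_metab=0, w_act=1, w_qdd=0, w_passive=0, w_arms=0,
                        w_slack=0, d=1.0)
        terms = cost_function_terms(trial, w, MargariaModel())
        assert terms["activation"] == pytest.approx(0.25)
        assert terms["total"] == pytest.approx(0.25)

    def test_polynomial_channels_match_analytic_integrals(self):
        trial = _poly_trial()
        w = CostWeights(w_metab=0, w_act=1, w_qdd=1, w_passive=0,
                        w_arms=1, w_slack=1, d=1.0)
        terms = cost_function_terms(trial, w, MargariaModel())
        # activations: 2 muscles at 0.5 -> int 2*0.25 dt = 0.5
        assert terms["activation"] == pytest.approx(0.5, rel=1e-9)
        # qddot: int t^2 + t^4 dt = 1/3 + 1/5
        assert terms["joint_acc"] == pytest.approx(1 / 3 + 1 / 5, rel=1e-6)
        # arms: int 0.04 dt
        assert terms["arm_excitation"] == pytest.approx(0.04, rel=1e-9)
        # slack: int t^2 = 1/3
        assert terms["slack"] == pytest.approx(1 / 3, rel=1e-6)

    def test_linearity_in_weights(self, small_trial):
        coeffs = {c: JointPassiveCoeffs() for c in small_trial.q.columns}
        w1 = CostWeights()
        w2 = CostWeights(w_metab=2.0)
        t1 = cost_function_terms(small_trial, w1, MargariaModel(), coeffs)
        t2 = cost_function_terms(small_trial, w2, MargariaModel(), coeffs)
        assert t2["metabolic"] == pytest.approx(2 * t1["metabolic"], rel=1e-12)
        for key in ("activation", "joint_acc", "passive_torque",
                    "arm_excitation", "slack"):
            assert t2[key] == pytest.approx(t1[key], rel=1e-12)

    def test_missing_channel_named_in_error(self):
        t = np.linspace(0.0, 1.0, 60)
        trial = GaitTrial(t=t, muscles={"m": make_traj(t, np.zeros(t.size))},
                          stride_time=1.0, speed=1.0)
        with pytest.raises(ValueError, match="qddot"):
            cost_function_terms(
                trial, CostWeights(w_metab=0, w_act=0, w_passive=0,
                                   w_arms=0, w_slack=0, d=1.0),
                MargariaModel())


class TestDissipation:
    def _trial(self, qdot_series, t):
        return GaitTrial(
            t=t, muscles={"m": make_traj(t, np.zeros(t.size))},
            stride_time=float(t[-1] - t[0]), speed=1.0,
            qdot=pd.DataFrame({"knee": qdot_series}, index=t))

    def test_zero_velocity_no_damper_loss(self):
        t = np.linspace(0.0, 1.0, 60)
        out = dissipation_energy(self._trial(np.zeros(t.size), t),
                                 damper_coeffs={"knee": 2.0})
        assert out["E_damper"] == 0.0

    def test_constant_velocity_rectangle(self):
        t = np.linspace(0.0, 1.0, 60)
        out = dissipation_energy(self._trial(np.ones(t.size), t),
                                 damper_coeffs={"knee": 2.0})
        assert out["E_damper"] == pytest.approx(2.0)

    def test_contact_dissipation_matches_trapezoid_oracle(self):
        T = 1.0
        t = np.linspace(0.0, T, 2001)
        f = 700.0 * np.sin(np.pi * t / T) ** 2
        v = -0.03 * np.sin(2 * np.pi * t / T)
        trial = GaitTrial(
            t=t, muscles={"m": make_traj(t, np.zeros(t.size))},
            stride_time=T, speed=1.0,
            contact_force=pd.DataFrame({"c": f}, index=t),
            contact_velocity=pd.DataFrame({"c": v}, index=t))
        power = f * v
        expected = -np.trapezoid(np.minimum(power, 0.0), t)
        out = dissipation_energy(trial)
        assert out["E_contact"] == pytest.approx(expected, rel=1e-9)
        assert out["E_contact"] > 0


class TestEnergyBreakdown:
    def test_totals_equal_sum_of_muscles(self, small_trial):
        bd = energy_breakdown(small_trial, MargariaModel())
        assert bd.W_pos == pytest.approx(bd.per_muscle["W_pos"].sum(), rel=1e-9)
        assert bd.W_neg == pytest.approx(bd.per_muscle["W_neg"].sum(), rel=1e-9)
        assert bd.E_total == pytest.approx(bd.per_muscle["E_total"].sum(), rel=1e-9)
        assert np.all(bd.per_muscle["W_pos"] >= 0)
        assert np.all(bd.per_muscle["W_neg"] <= 0)
        assert bd.W_net == pytest.approx(bd.W_pos + bd.W_neg, rel=1e-9)

    def test_basal_subtraction_and_cot(self, small_trial):
        bd0 = energy_breakdown(small_trial, MargariaModel())
        bd = energy_breakdown(small_trial, MargariaModel(), basal_rate=10.0)
        assert bd.E_net == pytest.approx(
            bd0.E_total - 10.0 * small_trial.stride_time)
        expected_cot = bd.E_net / (small_trial.body_mass * small_trial.speed
                                   * small_trial.stride_time)
        assert bd.cot == pytest.approx(expected_cot)

    def test_csv_export_round_trip(self, small_trial, tmp_path):
        bd = energy_breakdown(small_trial, MargariaModel())
        path = tmp_path / "breakdown.csv"
        bd.to_csv(path)
        df = pd.read_csv(path, index_col="muscle")
        assert df.loc["TOTAL", "E_total"] == pytest.approx(bd.E_total)
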