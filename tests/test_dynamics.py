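"""Passive joint torques and forward-simulation tests."""

import numpy as np
import pytest

from elbowstiff.dynamics import (PassiveJointParams, SegmentProperties, SimConfig,
                                 damping_torque, gravity_torque, mechanical_energy,
                                 passive_torque, simulate_forward, total_torque)
from elbowstiff.errors import DivergenceError
from elbowstiff.hill import tendon_force
from elbowstiff.parameters import default_ground_truth_vector, split_vector


@pytest.fixture(scope="module")
def params():
    return split_vector(default_ground_truth_vector())


class TestPassiveTorque:
    def test_symmetric_cancellation(self):
        p = PassiveJointParams(k1=5.0, k2=0.3, k4=5.0, k5=0.3, q1=4.0, q2=5.0, Bp=1.0)
        q = (p.q1 + p.q2) / 2
        assert passive_torque(q, p) == pytest.approx(0.0, abs=1e-12)

    def test_single_branch_at_q2(self):
        # k4 ~ 0 isolates the extension-side exponential: tau_p(q2) ~ k1
        p = PassiveJointParams(k1=7.0, k2=0.35, k4=1e-12, k5=1.0, q1=4.2, q2=5.25, Bp=1.0)
        assert passive_torque(p.q2, p) == pytest.approx(7.0, abs=1e-9)

    def test_against_high_precision_oracle(self):
        p = PassiveJointParams(k1=7.0, k2=0.35, k4=36.0, k5=0.026, q1=4.2, q2=5.25, Bp=1.0)
        # 40-digit arbitrary-precision evaluation of the double exponential
        assert passive_torque(1.0, p) == pytest.approx(-2.1438989921996157, abs=1e-12)


class TestSimpleTorques:
    def test_damping(self):
        assert damping_torque(0.0, 3.0) == 0.0
        assert damping_torque(1.0, 3.0) == -3.0
        qd = np.array([-2.0, -0.1, 0.1, 2.0])
        assert np.all(np.sign(damping_torque(qd, 3.0)) == -np.sign(qd))

    def test_gravity(self):
        s = SegmentProperties(m=1.2, r_cm=0.11)
        assert gravity_torque(np.pi / 2, s) == pytest.approx(0.0, abs=1e-12)
        assert gravity_torque(0.0, s) == pytest.approx(1.2 * 9.81 * 0.11)
        assert gravity_torque(np.pi / 3, s) == pytest.approx(0.64746)
        assert gravity_torque(0.3, s, horizontal=True) == 0.0

    def test_total_torque_conventions(self):
        assert total_torque(0, 0, 0, 0, 0) == 0
        assert total_torque(0, 0, 0, 0, 2.0, convention="paper_literal") == 2.0
        assert total_torque(0, 0, 0, 2.0, 0, convention="paper_literal") == -2.0
        assert total_torque(0, 0, 0, 2.0, 0, convention="flexion_positive") == 2.0
        assert total_torque(1.0, -0.5, 0.25, 2.0, 0.5) == pytest.approx(2.25)


def _grid(duration, fs=100.0):
    return np.arange(0, duration + 1e-9, 1 / fs)


class TestSimulateForward:
    def test_balanced_equilibrium_stays_at_rest(self, params):
        hill_p, _ = params
        joint = PassiveJointParams(k1=5.0, k2=0.3, k4=5.0, k5=0.3, q1=0.0, q2=0.0, Bp=2.0)
        t = _grid(1.0)
        z = np.zeros_like(t)
        cfg = SimConfig(gravity_mode="horizontal")
        res = simulate_forward(z, z, hill_p, joint, SegmentProperties(), cfg, time=t)
        assert np.all(np.abs(res.q) <= 1e-6)

    def test_agonist_activation_flexes(self, params):
        hill_p, joint = params
        t = _grid(0.5)
        res = simulate_forward(np.full_like(t, 0.3), np.zeros_like(t), hill_p, joint,
                               SegmentProperties(), time=t)
        assert np.all(np.diff(res.q) > 0)

    def test_step_halving_converges(self, params):
        hill_p, joint = params
        t = _grid(1.0)
        a = 0.3 * 0.5 * (1 - np.cos(2 * np.pi * t))
        z = np.zeros_like(t)
        seg = SegmentProperties()
        q1 = simulate_forward(a, z, hill_p, joint, seg, SimConfig(dt=5e-4), time=t).q[-1]
        q2 = simulate_forward(a, z, hill_p, joint, seg, SimConfig(dt=2.5e-4), time=t).q[-1]
        assert abs(q1 - q2) / abs(q2) < 1e-3

    def test_rk4_error_decays_at_least_fourth_order(self, params):
        hill_p, joint = params
        t = _grid(1.0)
        a = 0.3 * 0.5 * (1 - np.cos(2 * np.pi * t))
        z = np.zeros_like(t)
        seg = SegmentProperties()
        cfg = lambda dt: SimConfig(dt=dt, gravity_mode="horizontal")
        ref = simulate_forward(a, z, hill_p, joint, seg, cfg(6.25e-5), time=t).q[-1]
        e_coarse = abs(simulate_forward(a, z, hill_p, joint, seg, cfg(1e-3), time=t).q[-1] - ref)
        e_fine = abs(simulate_forward(a, z, hill_p, joint, seg, cfg(5e-4), time=t).q[-1] - ref)
        assert e_fine < e_coarse / 16.0  # halving the step gains >= 2^4

    def test_energy_dissipates_without_drive(self, params):
        hill_p, joint = params
        t = _grid(2.0)
        z = np.zeros_like(t)
        seg = SegmentProperties()
        res = simulate_forward(z, z, hill_p, joint, seg,
                               SimConfig(dt=1e-4, gravity_mode="horizontal"), time=t)
        e = mechanical_energy(res, hill_p, joint, seg)
        assert np.all(np.diff(e) <= 1e-9 * e[0])
        assert e[-1] < e[0]

    def test_deterministic_bitwise(self, params):
        hill_p, joint = params
        t = _grid(0.5)
        a = np.linspace(0, 0.4, len(t))
        r1 = simulate_forward(a, a / 2, hill_p, joint, SegmentProperties(), time=t)
        r2 = simulate_forward(a, a / 2, hill_p, joint, SegmentProperties(), time=t)
        assert np.array_equal(r1.q, r2.q)
        assert np.array_equal(r1.tau_J, r2.tau_J)

    def test_divergence_guard_raises_with_step(self, params):
        hill_p, joint = params
        t = _grid(2.0)
        cfg = SimConfig(q_guard=0.05)
        with pytest.raises(DivergenceError, match="step"):
            simulate_forward(np.full_like(t, 0.5), np.zeros_like(t), hill_p, joint,
                             SegmentProperties(), cfg, time=t)

    def test_check_false_returns_partial_result(self, params):
        hill_p, joint = params
        t = _grid(2.0)
        res = simulate_forward(np.full_like(t, 0.5), np.zeros_like(t), hill_p, joint,
                               SegmentProperties(), SimConfig(q_guard=0.05),
                               time=t, check=False)
        assert not res.ok and res.bad_index > 0

    def test_euler_available_and_close_to_rk4(self, params):
        hill_p, joint = params
        t = _grid(0.5)
        a = 0.2 * np.ones_like(t)
        z = np.zeros_like(t)
        seg = SegmentProperties()
        q_rk = simulate_forward(a, z, hill_p, joint, seg, SimConfig(dt=1e-4), time=t).q[-1]
        q_eu = simulate_forward(a, z, hill_p, joint, seg,
                                SimConfig(dt=1e-4, integrator="euler"), time=t).q[-1]
        assert q_eu == pytest.approx(q_rk, rel=1e-2)

    def test_recorded_torques_match_reference_formulas(self, params, clean_trial):
        """The jitted kernel's recorded components equal the NumPy reference."""
        hill_p, joint = params
        res = clean_trial.reference
        seg = SegmentProperties(load_mass=0.5)
        for i in (0, 50, 151, len(res.q) - 1):
            q, qd = res.q[i], res.q_dot[i]
            assert res.tau_p[i] == pytest.approx(passive_torque(q, joint), rel=1e-10)
            assert res.tau_d[i] == pytest.approx(damping_torque(qd, joint.Bp), rel=1e-10, abs=1e-12)
            assert res.tau_G[i] == pytest.approx(gravity_torque(q, seg), rel=1e-10)
            lt_ag = res.muscle_states["agonist"]["lt"][i]
            lt_ant = res.muscle_states["antagonist"]["lt"][i]
            assert res.tau_AG[i] == pytest.approx(tendon_force(lt_ag, hill_p) * seg.rp,
                                                  rel=1e-10, abs=1e-12)
            assert res.tau_ANT[i] == pytest.approx(tendon_force(lt_ant, hill_p) * seg.rp,
                                                   rel=1e-10, abs=1e-12)
            total = total_torque(res.tau_p[i], res.tau_d[i], res.tau_G[i],
                                 res.tau_AG[i], res.tau_ANT[i])
            assert res.tau_J[i] == pytest.approx(total, rel=1e-10, abs=1e-12)
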