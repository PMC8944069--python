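"""Hill-type muscle mechanics and elbow forward dynamics."""

import numpy as np
import pytest

import myosampler as ms
from myosampler.basis import CRBFBasis, ExcitationSet, excitations_from_amplitudes
from myosampler.elbow import (
    ElbowModelSpec,
    ModelState,
    MuscleParams,
    SimulationDivergedError,
    activation_rate,
    default_elbow_spec,
    fiber_kinematics,
    forward_simulate,
    joint_torque,
    muscle_force,
)


@pytest.fixture(scope="module")
def spec():
    return default_elbow_spec()


def _uniform_excitations(level, t_f=0.5, dt=0.001, n_muscles=6):
    n = int(round(t_f / dt))
    t = np.linspace(0.0, t_f, n + 1)
    return ExcitationSet(t=t, u=np.full((n_muscles, n + 1), level))


class TestActivationDynamics:
    @pytest.mark.parametrize(
        "u, a, expected",
        [
            (0.5, 0.5, 0.0),              # equilibrium
            (1.0, 0.0, 100.0),            # activation at tau_act = 0.01 s
            (0.0, 1.0, -25.0),            # deactivation at tau_deact = 0.04 s
        ],
    )
    def test_rate_values(self, u, a, expected):
        assert activation_rate(u, a, 0.01, 0.04) == pytest.approx(expected)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            activation_rate(1.5, 0.0, 0.01, 0.04)


class TestFiberKinematics:
    def test_zero_velocity_at_rest(self, spec):
        m = spec.muscles[0]
        _, v = fiber_kinematics(0.3, 0.0, m, spec)
        assert v == 0.0

    def test_zero_moment_arm_decouples_length_from_angle(self):
        m = MuscleParams(name="x", f_max=100, l_opt=0.1, l_ts=0.2, moment_arm=0.0)
        sp = ElbowModelSpec(muscles=(m,), l_mt0=(0.3,), m_g_d=0.0)
        l0, _ = fiber_kinematics(0.0, 0.0, m, sp)
        l1, _ = fiber_kinematics(1.2, 0.0, m, sp)
        assert l0 == l1 == pytest.approx(0.1)

    def test_constructed_optimal_length(self):
        # choose l_mt0 so the fiber sits exactly at l_opt when theta = pi/2
        r, l_opt, l_ts = 0.04, 0.1, 0.2
        m = MuscleParams(name="x", f_max=100, l_opt=l_opt, l_ts=l_ts, moment_arm=r)
        sp = ElbowModelSpec(muscles=(m,),
                            l_mt0=(l_ts + l_opt + r * np.pi / 2,), m_g_d=0.0)
        l, _ = fiber_kinematics(np.pi / 2, 0.0, m, sp)
        assert l / l_opt == pytest.approx(1.0)


class TestMuscleForce:
    def test_inactive_at_optimum_is_zero(self, spec):
        m = spec.muscles[0]
        assert muscle_force(0.0, m.l_opt, 0.0, m) == 0.0

    def test_isometric_maximal(self, spec):
        m = spec.muscles[0]
        f = muscle_force(1.0, m.l_opt, 0.0, m)
        assert f == pytest.approx(m.f_max * np.cos(m.alpha_0))

    def test_maximal_shortening_velocity_kills_force(self, spec):
        m = spec.muscles[0]
        v_max = 10.0 * m.l_opt
        assert muscle_force(1.0, m.l_opt, -v_max, m) == 0.0

    def test_force_bounds_over_state_grid(self, spec):
        """0 <= F <= ~1.5 F_max across physiological states (eccentric cap)."""
        m = spec.muscles[0]
        a = np.linspace(0, 1, 7)
        ln = np.linspace(0.5, 1.4, 10) * m.l_opt
        v = np.linspace(-1.5, 1.5, 9) * 10 * m.l_opt
        grid = np.stack(np.meshgrid(a, ln, v), axis=-1).reshape(-1, 3)
        f = np.array([muscle_force(ai, li, vi, m) for ai, li, vi in grid])
        assert np.all(f >= 0.0)
        assert np.all(f <= 1.5 * m.f_max)


class TestJointTorque:
    def test_zero_forces_zero_torque(self, spec):
        sp = ms.default_elbow_spec(m_g_d=0.0)
        assert joint_torque(np.zeros(6), sp, 0.7) == 0.0

    def test_single_flexor_product(self):
        m = [MuscleParams(name=f"m{i}", f_max=500, l_opt=0.1, l_ts=0.1,
                          moment_arm=r) for i, r in
             enumerate([0.04, 0.0, 0.0, 0.0, 0.0, 0.0])]
        sp = ElbowModelSpec(muscles=tuple(m), l_mt0=(0.2,) * 6, m_g_d=0.0)
        forces = np.array([100.0, 0, 0, 0, 0, 0])
        assert joint_torque(forces, sp, 0.0) == pytest.approx(4.0)

    def test_balanced_coactivation_cancels(self):
        m = [MuscleParams(name=f"m{i}", f_max=500, l_opt=0.1, l_ts=0.1,
                          moment_arm=r) for i, r in
             enumerate([0.03, 0.0, 0.0, -0.03, 0.0, 0.0])]
        sp = ElbowModelSpec(muscles=tuple(m), l_mt0=(0.2,) * 6, m_g_d=0.0)
        forces = np.array([200.0, 0, 0, 200.0, 0, 0])
        assert joint_torque(forces, sp, 0.0) == pytest.approx(0.0)


class TestForwardSimulate:
    def test_no_input_no_motion(self):
        """Zero excitation, zero initial activation, no gravity, fibers at
        optimum (no passive force) => the arm stays put."""
        sp = ms.default_elbow_spec(m_g_d=0.0)
        exc = _uniform_excitations(0.0)
        x0 = ModelState(activations=(0.0,) * 6)
        traj = forward_simulate(exc, x0, sp)
        # the fiber sits at l_opt only up to rounding of l_mt0 - l_ts, so a
        # vanishing passive residual (~1e-14 N) is tolerated
        assert traj.theta == pytest.approx(np.zeros_like(traj.theta), abs=1e-12)
        assert traj.omega == pytest.approx(np.zeros_like(traj.omega), abs=1e-12)

    def test_round_trip_reproduces_reference_truth(self, reference):
        """Ground-truth amplitudes re-simulated through the public API give
        the stored truth kinematics bit-exactly."""
        basis = CRBFBasis.default()
        post_grid = reference.truth_trajectory
        t_half = np.linspace(0.0, 0.5, 2 * (post_grid.t.size - 1) + 1)
        exc = excitations_from_amplitudes(basis, reference.truth_amplitudes, t_half)
        traj = forward_simulate(exc, ModelState(), ms.default_elbow_spec())
        assert np.array_equal(traj.theta, post_grid.theta)
        assert np.array_equal(traj.omega, post_grid.omega)
        assert np.array_equal(traj.forces, post_grid.forces)

    def test_rk4_step_halving_converges(self, spec):
        # constant mild excitation keeps activation dynamics smooth (no
        # activation/deactivation switching), the regime where RK4 shows
        # its full order
        basis = CRBFBasis.default()
        amps = np.full((6, 10), -1.0)
        t_fine = np.linspace(0, 0.5, 2001)
        exc = excitations_from_amplitudes(basis, amps, t_fine)
        th1 = forward_simulate(exc, ModelState(), spec, dt=0.002).theta[-1]
        th2 = forward_simulate(exc, ModelState(), spec, dt=0.001).theta[-1]
        assert abs(th1 - th2) < 1e-6

    def test_determinism(self, spec):
        exc = _uniform_excitations(0.3)
        t1 = forward_simulate(exc, ModelState(), spec)
        t2 = forward_simulate(exc, ModelState(), spec)
        assert np.array_equal(t1.theta, t2.theta)

    def test_activations_stay_in_unit_interval(self, spec):
        rng = np.random.default_rng(11)
        basis = CRBFBasis.default()
        for _ in range(5):
            amps = rng.uniform(-10, 10, (6, 10))
            exc = excitations_from_amplitudes(
                basis, amps, np.linspace(0, 0.5, 501))
            traj = forward_simulate(exc, ModelState(), spec)
            assert traj.activations.min() >= 0.0
            assert traj.activations.max() <= 1.0

    def test_flexors_accelerate_positively_from_rest(self):
        sp = ms.default_elbow_spec(m_g_d=0.0)
        u = np.zeros((6, 501))
        u[:3] = 0.8          # flexors only
        exc = ExcitationSet(t=np.linspace(0, 0.5, 501), u=u)
        traj = forward_simulate(exc, ModelState(activations=(0.0,) * 6), sp)
        assert traj.theta[-1] > 0.1

    def test_extensors_accelerate_negatively_from_rest(self):
        sp = ms.default_elbow_spec(m_g_d=0.0)
        u = np.zeros((6, 501))
        u[3:] = 0.8          # extensors only
        exc = ExcitationSet(t=np.linspace(0, 0.5, 501), u=u)
        traj = forward_simulate(exc, ModelState(activations=(0.0,) * 6), sp)
        assert traj.theta[-1] < -0.1

    def test_passive_free_coasting_conserves_kinetic_energy(self):
        """No excitation, no gravity, fibers kept below optimal length =>
        no torque at all, so the joint coasts at constant speed."""
        muscles = tuple(
            MuscleParams(name=f"m{i}", f_max=500, l_opt=0.2, l_ts=0.1,
                         moment_arm=0.01 * (1 if i < 3 else -1))
            for i in range(6)
        )
        sp = ElbowModelSpec(muscles=muscles, m_g_d=0.0,
                            l_mt0=tuple(0.1 + 0.8 * 0.2 for _ in range(6)))
        exc = _uniform_excitations(0.0)
        x0 = ModelState(omega=1.0, activations=(0.0,) * 6)
        traj = forward_simulate(exc, x0, sp)
        assert traj.omega == pytest.approx(np.ones_like(traj.omega), abs=1e-12)

    def test_divergence_reported_with_time(self):
        sp = ms.default_elbow_spec(inertia=1e-12)
        exc = _uniform_excitations(0.9)
        with pytest.raises(SimulationDivergedError) as err:
            forward_simulate(exc, ModelState(), sp)
        assert 0.0 < err.value.t_fail <= 0.5

    def test_kernel_consistent_with_python_curves(self, spec):
        """The compiled integrator and the NumPy muscle model agree:
        d(omega)/dt from the simulated states equals joint_torque/I."""
        basis = CRBFBasis.default()
        amps = np.random.default_rng(5).uniform(-6, 2, (6, 10))
        exc = excitations_from_amplitudes(basis, amps, np.linspace(0, 0.5, 501))
        traj = forward_simulate(exc, ModelState(), spec, dt=0.002)
        alpha = np.gradient(traj.omega, traj.dt)[2:-2]
        torque = joint_torque(traj.forces, spec, traj.theta)[2:-2]
        # tolerance covers the O(dt^2) error of differencing omega
        assert alpha == pytest.approx(torque / spec.inertia, rel=0.03, abs=0.5)
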