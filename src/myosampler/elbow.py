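"""Single-DOF elbow flexion-extension dynamics driven by six Hill-type muscles.

The joint is actuated by three elbow flexors (brachialis, biceps long and
short heads) and three extensors (triceps lateral, medial and long heads).
Each muscle-tendon unit uses a rigid tendon, so fiber length follows
directly from muscle-tendon length, which in turn is linear in the elbow
angle through a constant (signed) moment arm::

    l_mt = l_mt0 - r * theta,   l_fiber = (l_mt - l_ts) / cos(alpha_0)

Positive moment arms flex the elbow, negative ones extend it.  Muscle force
combines the classic Hill ingredients — active force-length (Gaussian around
the optimal fiber length), force-velocity (hyperbolic, zero at maximal
shortening, eccentric plateau at 1.4), and an exponential passive element —
scaled by the peak isometric force.  Excitation-to-activation coupling is a
first-order lag with separate activation/deactivation time constants.

The resulting 8-state ODE (angle, angular velocity, six activations) is
integrated with fixed-step classical RK4, which keeps forward simulations
bit-reproducible — a requirement for a deterministic MCMC likelihood.
The heavy per-proposal integration loop is compiled with numba
(:mod:`myosampler._kernels`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from ._kernels import (
    FL_WIDTH,
    FV_AF,
    FV_ECC_B,
    FV_ECC_PLATEAU,
    MIN_FIBER_FRAC,
    PE_SHAPE,
    PE_STRAIN,
    VMAX_LOPT_PER_S,
    rk4_elbow,
)

__all__ = [
    "MuscleParams",
    "ElbowModelSpec",
    "ModelState",
    "Trajectory",
    "SimulationDivergedError",
    "activation_rate",
    "fiber_kinematics",
    "muscle_force",
    "joint_torque",
    "forward_simulate",
    "default_elbow_spec",
]

log = logging.getLogger(__name__)

class SimulationDivergedError(RuntimeError):
    """Forward integration produced a non-finite state.

    Carries the simulation time at which the failure was detected.
    """

    def __init__(self, t_fail: float):
        super().__init__(f"simulation diverged at t = {t_fail:.4f} s")
        self.t_fail = t_fail


@dataclass(frozen=True)
class MuscleParams:
    """Hill-type muscle-tendon parameters for one muscle."""

    name: str
    f_max: float          # peak isometric force, N
    l_opt: float          # optimal fiber length, m
    l_ts: float           # tendon slack length (rigid tendon), m
    moment_arm: float     # signed constant moment arm, m (+ flexor, - extensor)
    alpha_0: float = 0.0  # pennation angle at optimum, rad
    tau_act: float = 0.01     # activation time constant, s
    tau_deact: float = 0.04   # deactivation time constant, s

    def __post_init__(self) -> None:
        if self.f_max <= 0 or self.l_opt <= 0:
            raise ValueError(f"{self.name}: f_max and l_opt must be positive")
        if self.tau_act <= 0 or self.tau_deact <= 0:
            raise ValueError(f"{self.name}: time constants must be positive")


@dataclass(frozen=True)
class ElbowModelSpec:
    """Joint mechanics plus the muscle set actuating the elbow.

    ``l_mt0`` (muscle-tendon length at theta = 0) is stored per muscle; the
    default spec chooses it so every fiber sits at its optimal length at
    full extension.  ``m_g_d`` is the peak gravitational torque coefficient
    (mass * g * COM distance); set it to 0 for gravity-free experiments.
    """

    muscles: tuple[MuscleParams, ...]
    inertia: float = 0.06        # forearm inertia about the elbow, kg m^2
    m_g_d: float = 2.5           # peak gravity torque, N m (0 disables gravity)
    l_mt0: tuple[float, ...] = ()
    theta_min: float = 0.0
    theta_max: float = float(np.pi)

    def __post_init__(self) -> None:
        if self.inertia <= 0:
            raise ValueError("inertia must be positive")
        if len(self.l_mt0) != len(self.muscles):
            raise ValueError("need one l_mt0 entry per muscle")

    @property
    def n_muscles(self) -> int:
        return len(self.muscles)

    @property
    def muscle_names(self) -> list[str]:
        return [m.name for m in self.muscles]

    def is_flexor(self) -> np.ndarray:
        return np.array([m.moment_arm > 0 for m in self.muscles])

    # flat parameter arrays for the numba kernel
    def _arrays(self) -> dict[str, np.ndarray]:
        m = self.muscles
        return {
            "f_max": np.array([x.f_max for x in m]),
            "l_opt": np.array([x.l_opt for x in m]),
            "l_ts": np.array([x.l_ts for x in m]),
            "cos_alpha": np.cos(np.array([x.alpha_0 for x in m])),
            "r": np.array([x.moment_arm for x in m]),
            "l_mt0": np.asarray(self.l_mt0, dtype=float),
            "tau_act": np.array([x.tau_act for x in m]),
            "tau_deact": np.array([x.tau_deact for x in m]),
        }

    def to_dict(self) -> dict:
        return {
            "inertia": float(self.inertia),
            "m_g_d": float(self.m_g_d),
            "l_mt0": [float(v) for v in self.l_mt0],
            "muscles": [
                {
                    "name": x.name, "f_max": float(x.f_max),
                    "l_opt": float(x.l_opt), "l_ts": float(x.l_ts),
                    "moment_arm": float(x.moment_arm),
                    "alpha_0": float(x.alpha_0), "tau_act": float(x.tau_act),
                    "tau_deact": float(x.tau_deact),
                }
                for x in self.muscles
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ElbowModelSpec":
        muscles = tuple(MuscleParams(**m) for m in d["muscles"])
        return cls(muscles=muscles, inertia=float(d["inertia"]),
                   m_g_d=float(d["m_g_d"]), l_mt0=tuple(d["l_mt0"]))


@dataclass(frozen=True)
class ModelState:
    """Dynamic state: elbow angle (rad), angular velocity (rad/s), activations."""

    theta: float = 0.0
    omega: float = 0.0
    activations: tuple[float, ...] = (0.02,) * 6

    def __post_init__(self) -> None:
        a = np.asarray(self.activations, dtype=float)
        if np.any((a < 0) | (a > 1)):
            raise ValueError("activations must lie in [0, 1]")


@dataclass(frozen=True)
class Trajectory:
    """Time series of joint kinematics with optional muscle states/forces."""

    t: np.ndarray
    theta: np.ndarray
    omega: np.ndarray
    activations: np.ndarray | None = None   # (nt, n_muscles)
    forces: np.ndarray | None = None        # (nt, n_muscles)

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        if t.size >= 2:
            dt = np.diff(t)
            if not np.allclose(dt, dt[0], rtol=1e-9, atol=1e-12):
                raise ValueError("time grid must be uniform")
        for name in ("theta", "omega"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != t.shape:
                raise ValueError(f"{name} does not match the time grid")
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"non-finite values in {name}")

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0])


# ----------------------------------------------------------------- curves

def force_length_active(l_norm):
    """Active force-length multiplier: Gaussian, peaking at l_norm = 1."""
    l_norm = np.asarray(l_norm, dtype=float)
    return np.exp(-(((l_norm - 1.0) / FL_WIDTH) ** 2))


def force_velocity(v_norm):
    """Force-velocity multiplier: 0 at full shortening (v_norm = -1), 1 at
    isometric, saturating below ``FV_ECC_PLATEAU`` for lengthening."""
    v = np.asarray(v_norm, dtype=float)
    out = np.empty_like(v)
    con = v < 0
    vc = np.clip(v[con], -1.0, 0.0)
    out[con] = (1.0 + vc) / (1.0 - vc / FV_AF)
    ve = v[~con]
    out[~con] = (FV_ECC_PLATEAU * ve + FV_ECC_B) / (ve + FV_ECC_B)
    return np.minimum(out, FV_ECC_PLATEAU) if out.ndim else float(min(out, FV_ECC_PLATEAU))


def force_length_passive(l_norm):
    """Passive multiplier: 0 up to optimal length, exponential beyond,
    normalized to 1 at strain ``PE_STRAIN``."""
    l_norm = np.asarray(l_norm, dtype=float)
    strain = np.maximum(l_norm - 1.0, 0.0)
    return np.expm1(PE_SHAPE * strain / PE_STRAIN) / np.expm1(PE_SHAPE)


def activation_rate(u, a, tau_act: float, tau_deact: float):
    """First-order excitation-to-activation dynamics da/dt (1/s)."""
    u = np.asarray(u, dtype=float)
    a = np.asarray(a, dtype=float)
    if np.any((u < 0) | (u > 1)) or np.any((a < 0) | (a > 1)):
        raise ValueError("excitation and activation must lie in [0, 1]")
    tau = np.where(u > a, tau_act, tau_deact)
    out = (u - a) / tau
    return float(out) if out.ndim == 0 else out


def fiber_kinematics(theta, omega, muscle: MuscleParams, spec: ElbowModelSpec):
    """Fiber length and velocity from joint state under the rigid tendon.

    l_fiber is floored at 1% of the optimal length; hitting that floor
    indicates the muscle-tendon unit has gone slack and is logged once.
    """
    idx = spec.muscles.index(muscle)
    l_mt = spec.l_mt0[idx] - muscle.moment_arm * np.asarray(theta, dtype=float)
    cos_a = np.cos(muscle.alpha_0)
    l_fiber = (l_mt - muscle.l_ts) / cos_a
    floor = MIN_FIBER_FRAC * muscle.l_opt
    if np.any(l_fiber < floor):
        log.warning("%s: fiber length floored (MTU at/below slack length)", muscle.name)
        l_fiber = np.maximum(l_fiber, floor)
    v_fiber = -muscle.moment_arm * np.asarray(omega, dtype=float) / cos_a
    return l_fiber, v_fiber


def muscle_force(a, l_fiber, v_fiber, muscle: MuscleParams):
    """Hill-type muscle force (N), never negative.

    ``F = F_max * [a * f_L(l~) * f_V(v~) + f_PE(l~)] * cos(alpha_0)`` with
    lengths normalized by l_opt and velocity by 10 l_opt/s.
    """
    a = np.asarray(a, dtype=float)
    if np.any((a < 0) | (a > 1)):
        raise ValueError("activation must lie in [0, 1]")
    l_norm = np.asarray(l_fiber, dtype=float) / muscle.l_opt
    v_norm = np.asarray(v_fiber, dtype=float) / (VMAX_LOPT_PER_S * muscle.l_opt)
    f = muscle.f_max * (
        a * force_length_active(l_norm) * force_velocity(v_norm)
        + force_length_passive(l_norm)
    ) * np.cos(muscle.alpha_0)
    out = np.maximum(f, 0.0)
    return float(out) if out.ndim == 0 else out


def joint_torque(forces, spec: ElbowModelSpec, theta):
    """Net elbow torque (N m, flexion positive) from muscle forces + gravity."""
    forces = np.asarray(forces, dtype=float)
    if forces.shape[-1] != spec.n_muscles:
        raise ValueError(f"expected {spec.n_muscles} forces")
    r = np.array([m.moment_arm for m in spec.muscles])
    return forces @ r - spec.m_g_d * np.sin(np.asarray(theta, dtype=float))


# ----------------------------------------------------------- integration

def _excitations_on_half_grid(exc, t_f: float, dt: float) -> np.ndarray:
    """Resample excitations onto the RK4 stage grid (spacing dt/2)."""
    n_steps = int(round(t_f / dt))
    t_half = np.linspace(0.0, n_steps * dt, 2 * n_steps + 1)
    if exc.t.size == t_half.size and np.allclose(exc.t, t_half, rtol=0, atol=1e-12):
        return np.ascontiguousarray(exc.u)
    if exc.t[0] > 1e-12 or exc.t[-1] < t_f - 1e-9:
        raise ValueError("excitation grid must cover [0, t_f]")
    return np.vstack([np.interp(t_half, exc.t, row) for row in exc.u])


def forward_simulate(
    excitations,
    x0: ModelState,
    spec: ElbowModelSpec,
    dt: float = 0.002,
    t_f: float | None = None,
    with_forces: bool = True,
) -> Trajectory:
    """Integrate the muscle-driven elbow ODE with fixed-step RK4.

    Parameters
    ----------
    excitations
        :class:`~myosampler.basis.ExcitationSet` whose grid covers [0, t_f].
        Signals are resampled (linearly) onto the RK4 stage grid if needed.
    x0, spec
        Initial state and model specification.
    dt
        Integrator step, default 0.002 s.
    t_f
        Final time; defaults to the excitation grid's last point.

    Returns the trajectory on the integer step grid, with activations and
    (optionally) muscle forces.  Raises :class:`SimulationDivergedError` if
    the state leaves the finite range.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if t_f is None:
        t_f = float(excitations.t[-1])
    n_steps = int(round(t_f / dt))
    u_half = _excitations_on_half_grid(excitations, t_f, dt)
    if u_half.shape[0] != spec.n_muscles:
        raise ValueError("excitation count does not match muscle count")

    arrs = spec._arrays()
    a0 = np.asarray(x0.activations, dtype=float)
    theta = np.empty(n_steps + 1)
    omega = np.empty(n_steps + 1)
    act = np.empty((n_steps + 1, spec.n_muscles))
    ok, k_fail = rk4_elbow(
        u_half, dt, n_steps, x0.theta, x0.omega, a0,
        spec.inertia, spec.m_g_d,
        arrs["f_max"], arrs["l_opt"], arrs["l_ts"], arrs["cos_alpha"],
        arrs["r"], arrs["l_mt0"], arrs["tau_act"], arrs["tau_deact"],
        theta, omega, act,
    )
    if not ok:
        raise SimulationDivergedError(k_fail * dt)

    t = np.linspace(0.0, n_steps * dt, n_steps + 1)
    forces = None
    if with_forces:
        forces = trajectory_forces(t, theta, omega, act, spec)
    return Trajectory(t=t, theta=theta, omega=omega, activations=act, forces=forces)


def trajectory_forces(t, theta, omega, activations, spec: ElbowModelSpec) -> np.ndarray:
    """Muscle forces (nt, n_muscles) recomputed from stored states."""
    nt = len(t)
    forces = np.empty((nt, spec.n_muscles))
    for j, m in enumerate(spec.muscles):
        l_f, v_f = fiber_kinematics(theta, omega, m, spec)
        forces[:, j] = muscle_force(activations[:, j], l_f, v_f, m)
    return forces


# ------------------------------------------------------------- defaults

def default_elbow_spec(m_g_d: float = 2.5, inertia: float = 0.06) -> ElbowModelSpec:
    """The default six-muscle elbow.

    Peak isometric forces and optimal fiber lengths follow common upper-arm
    model magnitudes; moment arms are constants in the 2.5-3.5 cm range.
    ``l_mt0`` places every fiber at its optimal length at full extension
    (theta = 0), so flexors shorten and extensors lengthen during flexion,
    giving the extensors a passive decelerating contribution near the top of
    the motion.
    """
    defs = [
        # name, f_max, l_opt, l_ts, moment arm
        ("brachialis", 987.3, 0.0858, 0.0535, +0.025),
        ("biceps_long", 624.3, 0.1157, 0.2723, +0.035),
        ("biceps_short", 435.6, 0.1321, 0.1923, +0.035),
        ("triceps_lat", 624.3, 0.1138, 0.0980, -0.025),
        ("triceps_med", 624.3, 0.1138, 0.0908, -0.025),
        ("triceps_long", 798.5, 0.1340, 0.1430, -0.030),
    ]
    muscles = tuple(
        MuscleParams(name=n, f_max=f, l_opt=lo, l_ts=ls, moment_arm=r)
        for n, f, lo, ls, r in defs
    )
    l_mt0 = tuple(float(m.l_ts + m.l_opt * np.cos(m.alpha_0)) for m in muscles)
    return ElbowModelSpec(muscles=muscles, inertia=inertia, m_g_d=m_g_d, l_mt0=l_mt0)
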