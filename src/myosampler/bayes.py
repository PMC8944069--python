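"""Log-likelihood, log-prior and log-posterior over the CRBF amplitudes.

The posterior encodes two plausibility assumptions about an observed elbow
motion:

* **Tracking likelihood** — a proposal's simulated kinematics should match
  the reference angle and angular-velocity trajectories::

      logLikelihood = -1/2 * sum_t [ ((theta_ref - theta_pro)/0.4)^2
                                   + ((dtheta_ref - dtheta_pro)/1.6)^2 ]

  with angles in radians.  The 0.4 rad / 1.6 rad/s denominators weight the
  two terms to contribute roughly equally.

* **Effort prior** — the nervous system is assumed to distribute load so
  that total muscle effort (sum over muscles of the integrated excitation
  cubed) stays low::

      logPrior = -1/2 * (sum_m integral u_m^3 dt / 0.08)^2 + U(A)

  where ``U(A)`` is 0 while every amplitude stays in [-30, 30] and -inf
  outside, i.e. a hard uniform box on the coefficients.

``logPosterior = logLikelihood + logPrior`` holds exactly for every
evaluated proposal.  Out-of-box amplitudes short-circuit to -inf without
running the (expensive) forward simulation, and a diverged simulation is
mapped to -inf (with a counter) so chains keep running.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .basis import (
    AMPLITUDE_BOUND,
    CRBFBasis,
    ExcitationSet,
    check_amplitudes,
    inverse_logit_stable,
)
from .elbow import (
    ElbowModelSpec,
    ModelState,
    SimulationDivergedError,
    Trajectory,
    forward_simulate,
)

__all__ = [
    "BayesConfig",
    "GridMismatchError",
    "PosteriorEval",
    "log_likelihood",
    "effort_integral",
    "log_prior",
    "ElbowPosterior",
]

log = logging.getLogger(__name__)


class GridMismatchError(ValueError):
    """Proposal and reference do not share the likelihood time grid."""


@dataclass(frozen=True)
class BayesConfig:
    """Scale constants of the posterior.

    sigma_pos / sigma_vel are the tracking denominators (radians, rad/s);
    sigma_effort the effort-prior denominator; amp_bound the uniform box
    half-width on amplitudes.  likelihood_dt sets the tracked sample grid;
    by default it equals the integrator reporting interval (0.002 s, so the
    sum runs over every simulated sample of the 0.5 s motion).
    """

    sigma_pos: float = 0.4
    sigma_vel: float = 1.6
    sigma_effort: float = 0.08
    amp_bound: float = AMPLITUDE_BOUND
    likelihood_dt: float = 0.002
    t_f: float = 0.5

    def __post_init__(self) -> None:
        if min(self.sigma_pos, self.sigma_vel, self.sigma_effort) <= 0:
            raise ValueError("all sigmas must be positive")
        if self.likelihood_dt <= 0 or self.t_f <= 0:
            raise ValueError("grid parameters must be positive")

    def likelihood_grid(self) -> np.ndarray:
        n = int(round(self.t_f / self.likelihood_dt))
        return np.linspace(0.0, n * self.likelihood_dt, n + 1)

    def to_dict(self) -> dict:
        return {
            "sigma_pos": self.sigma_pos, "sigma_vel": self.sigma_vel,
            "sigma_effort": self.sigma_effort, "amp_bound": self.amp_bound,
            "likelihood_dt": self.likelihood_dt, "t_f": self.t_f,
        }


class PosteriorEval(NamedTuple):
    """Log-density components of one proposal (posterior = likelihood + prior)."""

    logpost: float
    loglik: float
    logprior: float


def _loglik_arrays(theta_pro, omega_pro, theta_ref, omega_ref, cfg: BayesConfig) -> float:
    e_pos = (theta_ref - theta_pro) / cfg.sigma_pos
    e_vel = (omega_ref - omega_pro) / cfg.sigma_vel
    return -0.5 * (float(e_pos @ e_pos) + float(e_vel @ e_vel))


def log_likelihood(proposal: Trajectory, reference, cfg: BayesConfig | None = None) -> float:
    """Tracking log-likelihood of a proposal trajectory (always <= 0).

    ``reference`` is anything exposing ``t``, ``theta_ref``/``theta`` and
    ``omega_ref``/``omega`` on the same grid as the proposal.
    """
    cfg = cfg or BayesConfig()
    t_ref = np.asarray(reference.t, dtype=float)
    if proposal.t.shape != t_ref.shape or not np.allclose(proposal.t, t_ref,
                                                          rtol=0, atol=1e-9):
        raise GridMismatchError(
            f"proposal grid ({proposal.t.size} pts) does not match the "
            f"reference grid ({t_ref.size} pts)")
    theta_r = np.asarray(getattr(reference, "theta_ref", getattr(reference, "theta", None)), dtype=float)
    omega_r = np.asarray(getattr(reference, "omega_ref", getattr(reference, "omega", None)), dtype=float)
    return _loglik_arrays(proposal.theta, proposal.omega, theta_r, omega_r, cfg)


def effort_integral(excitations: ExcitationSet) -> float:
    """Total muscle effort: sum over muscles of the integral of u^3 dt
    (trapezoidal rule on the excitation grid)."""
    u3 = excitations.u ** 3
    return float(np.sum(np.trapezoid(u3, excitations.t, axis=1)))


def log_prior(amplitudes, excitations: ExcitationSet, cfg: BayesConfig | None = None) -> float:
    """Effort prior plus the uniform amplitude box U(A).

    Returns -inf (a legal value, not an error) when any amplitude magnitude
    exceeds the box; otherwise ``-1/2 (effort / sigma_effort)^2``.
    """
    cfg = cfg or BayesConfig()
    a = np.asarray(amplitudes, dtype=float)
    if not np.all(np.isfinite(a)):
        raise ValueError("non-finite amplitudes")
    if np.any(np.abs(a) > cfg.amp_bound):
        return -np.inf
    e = effort_integral(excitations)
    return -0.5 * (e / cfg.sigma_effort) ** 2


class ElbowPosterior:
    """Callable log-posterior over the flattened amplitude vector.

    Precomputes the basis design matrix on the RK4 stage grid so each
    evaluation is one matrix product, one sigmoid, and one compiled forward
    integration.  Calling the object returns a :class:`PosteriorEval`
    triple; :meth:`evaluate` additionally returns the simulated trajectory
    for reuse by posterior summaries.

    Divergent simulations are counted in :attr:`divergence_count` and
    mapped to -inf.
    """

    def __init__(
        self,
        reference,
        spec: ElbowModelSpec,
        basis: CRBFBasis | None = None,
        cfg: BayesConfig | None = None,
        dt: float = 0.002,
        x0: ModelState | None = None,
    ):
        self.cfg = cfg or BayesConfig()
        self.basis = basis or CRBFBasis.default(t_f=self.cfg.t_f)
        self.spec = spec
        self.dt = float(dt)
        self.x0 = x0 or ModelState(activations=(0.02,) * spec.n_muscles)

        self.n_steps = int(round(self.cfg.t_f / dt))
        self.t_half = np.linspace(0.0, self.n_steps * dt, 2 * self.n_steps + 1)
        self.t_grid = self.t_half[::2]
        self._phi_half_T = self.basis.design_matrix(self.t_half).T  # (nodes, nt)

        lik_grid = self.cfg.likelihood_grid()
        stride = (self.t_grid.size - 1) // (lik_grid.size - 1)
        if not np.allclose(self.t_grid[::stride], lik_grid, rtol=0, atol=1e-9):
            raise ValueError("integrator grid does not contain the likelihood grid")
        self._lik_stride = stride
        self.t_lik = lik_grid

        theta_ref = np.asarray(reference.theta_ref, dtype=float)
        omega_ref = np.asarray(reference.omega_ref, dtype=float)
        t_ref = np.asarray(getattr(reference, "t", lik_grid), dtype=float)
        if theta_ref.size != t_ref.size:
            raise GridMismatchError("reference arrays do not match their grid")
        if t_ref.size == lik_grid.size and np.allclose(t_ref, lik_grid,
                                                       rtol=0, atol=1e-9):
            self.theta_ref, self.omega_ref = theta_ref, omega_ref
        elif t_ref[0] <= lik_grid[0] + 1e-9 and t_ref[-1] >= lik_grid[-1] - 1e-9:
            # observations sampled below the model rate: interpolate
            self.theta_ref = np.interp(lik_grid, t_ref, theta_ref)
            self.omega_ref = np.interp(lik_grid, t_ref, omega_ref)
        else:
            raise GridMismatchError("reference grid does not cover the likelihood grid")

        self.dim = spec.n_muscles * self.basis.n_nodes
        self.divergence_count = 0
        self.n_evals = 0
        self.n_short_circuit = 0

        # cached kernel arguments for the hot path
        self._arrs = spec._arrays()
        self._a0 = np.asarray(self.x0.activations, dtype=float)
        ar = self._arrs
        self._kernel_params = (
            spec.inertia, spec.m_g_d, ar["f_max"], ar["l_opt"], ar["l_ts"],
            ar["cos_alpha"], ar["r"], ar["l_mt0"], ar["tau_act"],
            ar["tau_deact"],
        )
        n, nm = self.n_steps, spec.n_muscles
        self._scratch = (np.empty((nm, 2 * n + 1)), np.empty(n + 1),
                         np.empty(n + 1), np.empty((n + 1, nm)))

    # -- helpers -----------------------------------------------------------

    def excitations(self, a_flat: np.ndarray) -> ExcitationSet:
        """Excitation signals for a flattened amplitude vector (stage grid)."""
        amps = np.asarray(a_flat, dtype=float).reshape(self.spec.n_muscles, -1)
        check_amplitudes(amps, self.cfg.amp_bound)
        return ExcitationSet(t=self.t_half,
                             u=inverse_logit_stable(amps @ self._phi_half_T))

    # -- evaluation --------------------------------------------------------

    def evaluate(self, a_flat, return_trajectory: bool = False):
        """Evaluate the log-posterior; optionally return the trajectory.

        Out-of-box amplitudes short-circuit to -inf with *no* forward
        simulation executed.
        """
        from ._kernels import elbow_logpost

        a = np.asarray(a_flat, dtype=float)
        if not np.all(np.isfinite(a)):
            raise ValueError("non-finite amplitudes")
        self.n_evals += 1
        n = self.n_steps
        nm = self.spec.n_muscles
        if return_trajectory:
            u = np.empty((nm, 2 * n + 1))
            theta = np.empty(n + 1)
            omega = np.empty(n + 1)
            act = np.empty((n + 1, nm))
        else:
            # reusable scratch: plain evaluations never hand these out
            u, theta, omega, act = self._scratch
        status, ll, lp = elbow_logpost(
            a, self._phi_half_T, nm, self.dt, n,
            self.x0.theta, self.x0.omega, self._a0, *self._kernel_params,
            self.theta_ref, self.omega_ref, self._lik_stride,
            1.0 / self.cfg.sigma_pos, 1.0 / self.cfg.sigma_vel,
            1.0 / self.cfg.sigma_effort, self.cfg.amp_bound,
            u, theta, omega, act,
        )
        if status == 1:
            self.n_short_circuit += 1
            ev = PosteriorEval(-np.inf, 0.0, -np.inf)
            return (ev, None) if return_trajectory else ev
        if status == 2:
            self.divergence_count += 1
            log.warning("proposal diverged; mapped to -inf")
            ev = PosteriorEval(-np.inf, -np.inf, 0.0)
            return (ev, None) if return_trajectory else ev
        ev = PosteriorEval(ll + lp, ll, lp)
        if return_trajectory:
            traj = Trajectory(t=self.t_grid, theta=theta, omega=omega,
                              activations=act)
            return ev, traj
        return ev

    def __call__(self, a_flat) -> PosteriorEval:
        return self.evaluate(a_flat)

    def simulate(self, a_flat, with_forces: bool = True) -> Trajectory:
        """Forward-simulate a proposal, with muscle forces."""
        exc = self.excitations(a_flat)
        traj = forward_simulate(exc, self.x0, self.spec, dt=self.dt,
                                t_f=self.cfg.t_f, with_forces=with_forces)
        return traj
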