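"""Numba-compiled inner loop for the elbow forward dynamics.

One MCMC iteration costs one forward integration, so the RK4 loop is the
hot path of the whole package.  The Hill-curve shape constants here are the
single source of truth; :mod:`myosampler.elbow` imports them so the
vectorized NumPy curve functions and this kernel cannot drift apart (a unit
test cross-checks the two paths on identical states).
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

# Hill-curve shape constants (dimensionless).
FL_WIDTH = 0.45
FV_AF = 0.25
FV_ECC_PLATEAU = 1.4
FV_ECC_B = 0.08
PE_SHAPE = 4.0
PE_STRAIN = 0.6
VMAX_LOPT_PER_S = 10.0
MIN_FIBER_FRAC = 0.01

_PE_NORM = math.expm1(PE_SHAPE)


@njit(cache=True)
def _derivative(theta, omega, a, u, inertia, m_g_d,
                f_max, l_opt, l_ts, cos_alpha, r, l_mt0,
                tau_act, tau_deact, da_out):
    """State derivative of the 8-state elbow ODE; returns (dtheta, domega)."""
    torque = 0.0
    n = f_max.shape[0]
    for m in range(n):
        l_mt = l_mt0[m] - r[m] * theta
        l_f = (l_mt - l_ts[m]) / cos_alpha[m]
        floor = MIN_FIBER_FRAC * l_opt[m]
        if l_f < floor:
            l_f = floor
        v_f = -r[m] * omega / cos_alpha[m]
        ln = l_f / l_opt[m]
        vn = v_f / (VMAX_LOPT_PER_S * l_opt[m])

        x = (ln - 1.0) / FL_WIDTH
        fl = math.exp(-x * x)

        if vn < 0.0:
            vc = vn if vn > -1.0 else -1.0
            fv = (1.0 + vc) / (1.0 - vc / FV_AF)
        else:
            fv = (FV_ECC_PLATEAU * vn + FV_ECC_B) / (vn + FV_ECC_B)
            if fv > FV_ECC_PLATEAU:
                fv = FV_ECC_PLATEAU

        strain = ln - 1.0
        if strain < 0.0:
            fpe = 0.0
        else:
            fpe = math.expm1(PE_SHAPE * strain / PE_STRAIN) / _PE_NORM

        force = f_max[m] * (a[m] * fl * fv + fpe) * cos_alpha[m]
        if force < 0.0:
            force = 0.0
        torque += r[m] * force

        um = u[m]
        if um > a[m]:
            da_out[m] = (um - a[m]) / tau_act[m]
        else:
            da_out[m] = (um - a[m]) / tau_deact[m]

    domega = (torque - m_g_d * math.sin(theta)) / inertia
    return omega, domega


@njit(cache=True)
def elbow_logpost(a_flat, phi_t, n_muscles, dt, n_steps, theta0, omega0, a0,
                  inertia, m_g_d, f_max, l_opt, l_ts, cos_alpha, r, l_mt0,
                  tau_act, tau_deact, theta_ref, omega_ref, lik_stride,
                  inv_sig_pos, inv_sig_vel, inv_sig_effort, amp_bound,
                  u_out, theta_out, omega_out, act_out):
    """Fused posterior evaluation: basis -> sigmoid -> RK4 -> likelihood/prior.

    Returns (status, loglik, logprior): status 0 ok, 1 out-of-bounds
    (short-circuited before simulating), 2 diverged.  Fills u_out (the
    stage-grid excitations) and the trajectory arrays for reuse.
    """
    n_nodes = phi_t.shape[0]
    nt = phi_t.shape[1]
    for i in range(a_flat.shape[0]):
        if abs(a_flat[i]) > amp_bound:
            return 1, 0.0, -np.inf
    # excitations on the stage grid
    for m in range(n_muscles):
        base = m * n_nodes
        for j in range(nt):
            f = 0.0
            for i in range(n_nodes):
                f += a_flat[base + i] * phi_t[i, j]
            if f > 0.0:
                u_out[m, j] = 1.0 / (1.0 + math.exp(-f))
            else:
                ef = math.exp(f)
                u_out[m, j] = ef / (1.0 + ef)
    ok, k_fail = rk4_elbow(u_out, dt, n_steps, theta0, omega0, a0,
                           inertia, m_g_d, f_max, l_opt, l_ts, cos_alpha,
                           r, l_mt0, tau_act, tau_deact,
                           theta_out, omega_out, act_out)
    if not ok:
        return 2, -np.inf, 0.0
    # tracking likelihood on the subsampled grid
    sse = 0.0
    n_lik = (n_steps // lik_stride) + 1
    for j in range(n_lik):
        k = j * lik_stride
        ep = (theta_ref[j] - theta_out[k]) * inv_sig_pos
        ev = (omega_ref[j] - omega_out[k]) * inv_sig_vel
        sse += ep * ep + ev * ev
    loglik = -0.5 * sse
    # effort: trapezoid over the likelihood grid (stage stride = 2*lik_stride)
    h = dt * lik_stride
    effort = 0.0
    for m in range(n_muscles):
        acc = 0.0
        for j in range(n_lik):
            u = u_out[m, 2 * lik_stride * j]
            w = 0.5 if (j == 0 or j == n_lik - 1) else 1.0
            acc += w * u * u * u
        effort += acc * h
    e = effort * inv_sig_effort
    logprior = -0.5 * e * e
    return 0, loglik, logprior


@njit(cache=True)
def rk4_elbow(u_half, dt, n_steps, theta0, omega0, a0, inertia, m_g_d,
              f_max, l_opt, l_ts, cos_alpha, r, l_mt0, tau_act, tau_deact,
              out_theta, out_omega, out_act):
    """Classical RK4 over n_steps; excitations sampled on the dt/2 grid.

    Fills the output arrays in place and returns (ok, fail_step).
    """
    n_m = a0.shape[0]
    theta = theta0
    omega = omega0
    a = a0.copy()
    out_theta[0] = theta
    out_omega[0] = omega
    for m in range(n_m):
        out_act[0, m] = a[m]

    k1a = np.empty(n_m)
    k2a = np.empty(n_m)
    k3a = np.empty(n_m)
    k4a = np.empty(n_m)
    a_tmp = np.empty(n_m)

    for k in range(n_steps):
        u0 = u_half[:, 2 * k]
        u1 = u_half[:, 2 * k + 1]
        u2 = u_half[:, 2 * k + 2]

        k1t, k1w = _derivative(theta, omega, a, u0, inertia, m_g_d,
                               f_max, l_opt, l_ts, cos_alpha, r, l_mt0,
                               tau_act, tau_deact, k1a)
        for m in range(n_m):
            a_tmp[m] = a[m] + 0.5 * dt * k1a[m]
        k2t, k2w = _derivative(theta + 0.5 * dt * k1t, omega + 0.5 * dt * k1w,
                               a_tmp, u1, inertia, m_g_d,
                               f_max, l_opt, l_ts, cos_alpha, r, l_mt0,
                               tau_act, tau_deact, k2a)
        for m in range(n_m):
            a_tmp[m] = a[m] + 0.5 * dt * k2a[m]
        k3t, k3w = _derivative(theta + 0.5 * dt * k2t, omega + 0.5 * dt * k2w,
                               a_tmp, u1, inertia, m_g_d,
                               f_max, l_opt, l_ts, cos_alpha, r, l_mt0,
                               tau_act, tau_deact, k3a)
        for m in range(n_m):
            a_tmp[m] = a[m] + dt * k3a[m]
        k4t, k4w = _derivative(theta + dt * k3t, omega + dt * k3w,
                               a_tmp, u2, inertia, m_g_d,
                               f_max, l_opt, l_ts, cos_alpha, r, l_mt0,
                               tau_act, tau_deact, k4a)

        theta = theta + dt / 6.0 * (k1t + 2.0 * k2t + 2.0 * k3t + k4t)
        omega = omega + dt / 6.0 * (k1w + 2.0 * k2w + 2.0 * k3w + k4w)
        for m in range(n_m):
            a[m] = a[m] + dt / 6.0 * (k1a[m] + 2.0 * k2a[m] + 2.0 * k3a[m] + k4a[m])

        if not (math.isfinite(theta) and math.isfinite(omega)):
            return False, k + 1
        out_theta[k + 1] = theta
        out_omega[k + 1] = omega
        for m in range(n_m):
            out_act[k + 1, m] = a[m]

    return True, 0
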