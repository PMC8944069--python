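"""Compact radial basis function (CRBF) parameterization of muscle excitations.

A muscle excitation signal ``u(t)`` must lie strictly between 0 and 1 (no
drive / maximal drive).  Rather than sampling the excitation value at every
time step, each muscle's signal is described by the amplitudes of a small
set of compactly supported bumps (CRBFs) with fixed, evenly spaced centers
``c_i`` and a shared width ``w``::

    F_m(t) = sum_i A_{m,i} * exp[1 - 1/(1 - ((t - c_i)/w)^2)]   for |t-c_i| < w

with each bump defined to be exactly zero outside its support ``|t-c_i| >= w``
(the value at the boundary is taken as the continuous limit, 0).  The summed
signal is then squashed into (0, 1) with a numerically stable inverse-logit.
Compact support is the point of the construction: changing one amplitude
changes the excitation only inside that node's time window, which keeps the
MCMC parameters locally decoupled.

The default basis uses 10 nodes per muscle with centers spanning -0.05 s to
0.55 s (node spacing 0.6/9 s) around a 0.5 s motion, and width equal to two
node spacings (~0.133 s).  With six muscles this yields the 60-dimensional
amplitude vector the sampler explores.  Amplitudes are physically meaningful
only within [-30, 30]: past +/-30 the logistic saturates (sigmoid(-30) ~ 1e-13),
so wider excursions are redundant and are rejected by the prior.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "AMPLITUDE_BOUND",
    "AmplitudeBoundsError",
    "CRBFBasis",
    "ExcitationSet",
    "eval_crbf",
    "sum_basis",
    "inverse_logit_stable",
    "excitations_from_amplitudes",
]

#: Amplitudes outside [-AMPLITUDE_BOUND, AMPLITUDE_BOUND] are invalid parameters.
AMPLITUDE_BOUND = 30.0

DEFAULT_N_NODES = 10
DEFAULT_N_MUSCLES = 6
_DEFAULT_SPAN = (-0.05, 0.55)


class AmplitudeBoundsError(ValueError):
    """Raised when an amplitude vector leaves the valid [-30, 30] box.

    Distinct from generic numeric errors so callers (the prior) can map it
    to a -inf log-density instead of aborting.
    """


@dataclass(frozen=True)
class CRBFBasis:
    """Fixed centers and width shared by every muscle's excitation signal.

    Parameters
    ----------
    centers
        Node centers in seconds, strictly increasing and evenly spaced.
    width
        Shared bump half-width ``w`` in seconds (> 0).
    t_f
        Motion duration in seconds; centers may extend beyond [0, t_f] so
        the boundary of the motion is still covered by full bumps.
    """

    centers: np.ndarray
    width: float
    t_f: float = 0.5

    def __post_init__(self) -> None:
        centers = np.asarray(self.centers, dtype=float)
        object.__setattr__(self, "centers", centers)
        if centers.ndim != 1 or centers.size < 2:
            raise ValueError("centers must be a 1-D array with >= 2 nodes")
        if not np.all(np.isfinite(centers)) or not np.isfinite(self.width):
            raise ValueError("non-finite basis definition")
        if self.width <= 0:
            raise ValueError("width must be positive")
        d = np.diff(centers)
        if np.any(d <= 0):
            raise ValueError("centers must be strictly increasing")
        if not np.allclose(d, d[0], rtol=1e-8, atol=1e-12):
            raise ValueError("centers must be evenly spaced")
        if self.t_f <= 0:
            raise ValueError("t_f must be positive")

    @property
    def n_nodes(self) -> int:
        return int(self.centers.size)

    @property
    def spacing(self) -> float:
        return float(self.centers[1] - self.centers[0])

    @classmethod
    def default(cls, n_nodes: int = DEFAULT_N_NODES, t_f: float = 0.5) -> "CRBFBasis":
        """The default 10-node basis: centers -0.05..0.55 s, width two spacings."""
        lo, hi = _DEFAULT_SPAN[0], t_f + 0.05
        centers = np.linspace(lo, hi, n_nodes)
        spacing = (hi - lo) / (n_nodes - 1)
        return cls(centers=centers, width=2.0 * spacing, t_f=t_f)

    def design_matrix(self, t: np.ndarray) -> np.ndarray:
        """Evaluate every unit-amplitude bump on a time grid.

        Returns an ``(len(t), n_nodes)`` matrix ``Phi`` so that the summed
        signal for one muscle is ``Phi @ A_row``.
        """
        t = _as_finite_array(t, "t")
        s = (t[:, None] - self.centers[None, :]) / self.width
        out = np.zeros_like(s)
        mask = np.abs(s) < 1.0
        out[mask] = np.exp(1.0 - 1.0 / (1.0 - s[mask] ** 2))
        return out

    def to_dict(self) -> dict:
        return {
            "centers": [float(c) for c in self.centers],
            "width": float(self.width),
            "t_f": float(self.t_f),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CRBFBasis":
        return cls(centers=np.asarray(d["centers"], dtype=float),
                   width=float(d["width"]), t_f=float(d.get("t_f", 0.5)))


@dataclass(frozen=True)
class ExcitationSet:
    """Per-muscle excitation signals on a common time grid; values in (0, 1)."""

    t: np.ndarray
    u: np.ndarray  # (n_muscles, len(t))

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        u = np.atleast_2d(np.asarray(self.u, dtype=float))
        if u.shape[1] != t.size:
            raise ValueError(f"u has {u.shape[1]} columns but t has {t.size} points")
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "u", u)

    @property
    def n_muscles(self) -> int:
        return int(self.u.shape[0])


def _as_finite_array(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"non-finite values in {name}")
    return arr


def eval_crbf(t, c: float, w: float, a: float):
    """Evaluate one compact radial basis function.

    ``a * exp[1 - 1/(1 - ((t-c)/w)^2)]`` for ``|t-c| < w`` and exactly 0
    outside (the continuous limit at the support boundary).  ``eval_crbf(c)``
    equals ``a`` since the exponent vanishes at the center.
    """
    t_arr = _as_finite_array(t, "t")
    for name, val in (("c", c), ("w", w), ("A", a)):
        if not np.isfinite(val):
            raise ValueError(f"non-finite {name}")
    if w <= 0:
        raise ValueError("width must be positive")
    s = (t_arr - c) / w
    out = np.zeros_like(s, dtype=float)
    mask = np.abs(s) < 1.0
    out[mask] = a * np.exp(1.0 - 1.0 / (1.0 - s[mask] ** 2))
    if np.isscalar(t) or np.ndim(t) == 0:
        return float(out)
    return out


def sum_basis(basis: CRBFBasis, a_row: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Sum the basis bumps for one muscle: ``F_m(t) = sum_i A_i * crbf_i(t)``."""
    a_row = _as_finite_array(a_row, "A_row")
    if a_row.ndim != 1 or a_row.size != basis.n_nodes:
        raise ValueError(
            f"A_row has length {a_row.size}, basis has {basis.n_nodes} nodes")
    return basis.design_matrix(t) @ a_row


def inverse_logit_stable(f):
    """Logistic map onto (0, 1), exponentiating only negative arguments.

    Uses the two-branch form ``1/(1+e^-F)`` for ``F > 0`` and
    ``e^F/(1+e^F)`` otherwise, so there is no overflow even for |F| ~ 1e4.
    """
    f_arr = np.asarray(f, dtype=float)
    if np.any(np.isnan(f_arr)):
        raise ValueError("NaN input to inverse_logit_stable")
    out = np.empty_like(f_arr)
    pos = f_arr > 0
    out[pos] = 1.0 / (1.0 + np.exp(-f_arr[pos]))
    ef = np.exp(f_arr[~pos])
    out[~pos] = ef / (1.0 + ef)
    if np.isscalar(f) or np.ndim(f) == 0:
        return float(out)
    return out


def check_amplitudes(a: np.ndarray, bound: float = AMPLITUDE_BOUND) -> np.ndarray:
    """Validate an amplitude matrix/vector against the [-bound, bound] box."""
    arr = np.asarray(a, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("non-finite amplitudes")
    if np.any(np.abs(arr) > bound):
        worst = float(np.max(np.abs(arr)))
        raise AmplitudeBoundsError(
            f"amplitude magnitude {worst:.3g} exceeds bound {bound:g}")
    return arr


def excitations_from_amplitudes(
    basis: CRBFBasis,
    amplitudes: np.ndarray,
    t: np.ndarray,
    check_bounds: bool = True,
) -> ExcitationSet:
    """Map an (n_muscles, n_nodes) amplitude matrix to excitation signals.

    Deterministic composition ``inverse_logit_stable(sum_basis(...))`` per
    muscle.  With ``check_bounds`` (default) an out-of-box amplitude raises
    :class:`AmplitudeBoundsError` rather than being clipped; the sampler's
    prior relies on this distinction.
    """
    amplitudes = np.atleast_2d(np.asarray(amplitudes, dtype=float))
    if check_bounds:
        check_amplitudes(amplitudes)
    elif not np.all(np.isfinite(amplitudes)):
        raise ValueError("non-finite amplitudes")
    if amplitudes.shape[1] != basis.n_nodes:
        raise ValueError(
            f"amplitudes have {amplitudes.shape[1]} nodes, basis has {basis.n_nodes}")
    t_arr = _as_finite_array(t, "t")
    phi = basis.design_matrix(t_arr)          # (nt, n_nodes)
    f = amplitudes @ phi.T                    # (n_muscles, nt)
    return ExcitationSet(t=t_arr, u=inverse_logit_stable(f))
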