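"""Figure helpers: chain traces, rank histograms, posterior envelopes.

Thin matplotlib layer over the diagnostics/summary containers; every
function returns the Figure so callers can style or save it.  matplotlib
is imported lazily so headless library use never touches a GUI backend.
"""

from __future__ import annotations

import numpy as np

__all__ = ["trace_plot", "rank_plot", "envelope_plot"]


def _mpl():
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    return plt


def trace_plot(results, which: str = "logpost", max_points: int = 2000):
    """Per-chain traces of the log-density components (equilibration view)."""
    plt = _mpl()
    fig, ax = plt.subplots(figsize=(7, 3.2))
    for res in results:
        y = getattr(res, which)
        stride = max(1, y.size // max_points)
        ax.plot(np.arange(y.size)[::stride], y[::stride], lw=0.8,
                label=f"chain {res.chain_id}")
    ax.set_xlabel("iteration")
    ax.set_ylabel(which)
    ax.legend(fontsize=7, ncol=4)
    fig.tight_layout()
    return fig


def rank_plot(hist, title: str = ""):
    """Per-chain histograms of pooled ranks; flat bars indicate mixing."""
    plt = _mpl()
    m = hist.counts.shape[0]
    fig, axes = plt.subplots(1, m, figsize=(2.2 * m, 2.2), sharey=True)
    axes = np.atleast_1d(axes)
    centers = 0.5 * (hist.edges[:-1] + hist.edges[1:])
    width = hist.edges[1] - hist.edges[0]
    expected = hist.counts.sum() / (m * hist.counts.shape[1])
    for i, ax in enumerate(axes):
        ax.bar(centers, hist.counts[i], width=width * 0.9)
        ax.axhline(expected, color="k", ls="--", lw=0.8)
        ax.set_title(f"chain {i}", fontsize=8)
    if title:
        fig.suptitle(title, fontsize=9)
    fig.tight_layout()
    return fig


def envelope_plot(summary, reference=None):
    """Kinematic and muscle-force mean +/- SD envelopes, with the ground
    truth overlaid when a reference is given."""
    plt = _mpl()
    n_m = summary.force_mean.shape[1]
    fig, axes = plt.subplots(2 + (n_m + 2) // 3, 3,
                             figsize=(9, 2.2 * (2 + (n_m + 2) // 3)))
    t = summary.t

    ax = axes[0, 0]
    ax.fill_between(t, np.degrees(summary.theta_mean - 2 * summary.theta_sd),
                    np.degrees(summary.theta_mean + 2 * summary.theta_sd),
                    alpha=0.3)
    ax.plot(t, np.degrees(summary.theta_mean), "k", lw=1)
    ax.set_ylabel("angle (deg)")

    ax = axes[0, 1]
    ax.fill_between(t, np.degrees(summary.omega_mean - 2 * summary.omega_sd),
                    np.degrees(summary.omega_mean + 2 * summary.omega_sd),
                    alpha=0.3)
    ax.plot(t, np.degrees(summary.omega_mean), "k", lw=1)
    ax.set_ylabel("velocity (deg/s)")
    axes[0, 2].axis("off")

    stride = None
    if reference is not None:
        stride = (t.size - 1) // (reference.t.size - 1)
    for j in range(n_m):
        ax = axes[1 + j // 3, j % 3]
        ax.fill_between(t, summary.force_mean[:, j] - summary.force_sd[:, j],
                        summary.force_mean[:, j] + summary.force_sd[:, j],
                        alpha=0.3)
        ax.plot(t, summary.force_mean[:, j], "k", lw=1)
        if reference is not None:
            ax.plot(reference.t, reference.truth_forces[:, j], "r--", lw=1)
        ax.set_title(summary.muscle_names[j], fontsize=8)
        ax.set_ylabel("force (N)")
    for ax in axes.ravel():
        if not ax.has_data():
            ax.axis("off")
    fig.tight_layout()
    return fig
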