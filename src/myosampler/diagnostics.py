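"""Convergence diagnostics and posterior summaries.

Implements the standard modern MCMC diagnostics in-package:

* **Split-R-hat** (potential scale reduction): each chain is halved, draws
  are rank-normalized (pooled average ranks mapped through the normal
  quantile function), and the classic between/within variance ratio is
  computed; the reported value is the max over the raw and folded
  (|x - median|) transforms.  Values below ~1.10 are conventionally taken
  as converged.
* **Effective sample size**: autocorrelation-based, combining split chains
  with Geyer's initial monotone positive-sequence truncation.
* **Rank plots**: per-chain histograms of pooled-sample ranks scaled to
  (0, 1); uniform histograms in every chain indicate the chains explore the
  same distribution.  A chi-square uniformity statistic summarizes each.
* **Parameter correlations**: Pearson correlations between amplitude
  parameters, viewable across muscles within a time node or across nodes
  within a muscle.

Posterior summarization follows the study recipe: subsample a fixed number
of evenly spaced post-burn-in proposals per chain (25/chain at the
full-scale geometry, i.e. one every 10,000 iterations, 175 proposals over
7 chains), forward-simulate each, and report mean +/- SD envelopes of
kinematics and muscle forces plus average tracking RMSEs in degrees.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import ndtri
from scipy.stats import chi2, rankdata

__all__ = [
    "DiagnosticsReport",
    "PosteriorSummary",
    "split_rhat",
    "effective_sample_size",
    "rank_histograms",
    "parameter_correlations",
    "subsample_chains",
    "summarize_posterior",
    "compute_diagnostics",
]

log = logging.getLogger(__name__)


def _as_chains(chains) -> np.ndarray:
    arr = np.asarray(chains, dtype=float)
    if arr.ndim != 2:
        raise ValueError("expected draws shaped (n_chains, n_draws)")
    return arr


def _split(chains: np.ndarray) -> np.ndarray:
    """Halve each chain (dropping one draw if odd) -> (2m, n//2)."""
    m, n = chains.shape
    half = n // 2
    return np.vstack([chains[:, :half], chains[:, n - half:]])


def _z_scale(chains: np.ndarray) -> np.ndarray:
    """Rank-normalize pooled draws: average ranks -> normal quantiles."""
    shape = chains.shape
    rank = rankdata(chains, method="average").reshape(shape)
    size = chains.size
    return ndtri((rank - 3.0 / 8.0) / (size - 2.0 * 3.0 / 8.0 + 1.0))


def _rhat_identity(chains: np.ndarray) -> float:
    """Classic split-R-hat on already-transformed split chains."""
    m, n = chains.shape
    chain_means = chains.mean(axis=1)
    chain_vars = chains.var(axis=1, ddof=1)
    w = chain_vars.mean()
    b = n * chain_means.var(ddof=1)
    var_hat = (n - 1) / n * w + b / n
    if w == 0:
        return np.nan
    return float(np.sqrt(var_hat / w))


def split_rhat(chains) -> float:
    """Rank-normalized split-R-hat for one parameter.

    ``chains`` has shape (n_chains, n_draws); needs >= 2 chains of >= 4
    draws.  Degenerate (zero within-chain variance) inputs return NaN with
    a warning rather than raising, flagging a stuck chain.
    """
    arr = _as_chains(chains)
    if arr.shape[0] < 2 or arr.shape[1] < 4:
        raise ValueError("need >= 2 chains with >= 4 draws each")
    split = _split(arr)
    if np.all(split.var(axis=1) == 0):
        log.warning("degenerate (constant) chains: R-hat undefined")
        return float("nan")
    rhat_bulk = _rhat_identity(_z_scale(split))
    folded = np.abs(arr - np.median(arr))
    rhat_tail = _rhat_identity(_z_scale(_split(folded)))
    return float(np.nanmax([rhat_bulk, rhat_tail]))


def _autocovariance(x: np.ndarray) -> np.ndarray:
    """Biased autocovariance of one chain via FFT."""
    n = x.size
    m = 2 ** int(np.ceil(np.log2(2 * n)))
    xc = x - x.mean()
    f = np.fft.rfft(xc, m)
    acov = np.fft.irfft(f * np.conjugate(f), m)[:n].real
    return acov / n


def effective_sample_size(chains) -> float:
    """Autocorrelation-adjusted count of independent draws.

    Split chains, average per-chain autocovariances, form the combined
    autocorrelation, and truncate with Geyer's initial monotone positive
    sequence.  May legitimately exceed the number of draws for
    anticorrelated (superefficient) chains.  Degenerate chains report 0.
    """
    arr = _as_chains(chains)
    if arr.shape[0] < 1 or arr.shape[1] < 4:
        raise ValueError("need chains with >= 4 draws each")
    split = _split(arr) if arr.shape[0] >= 1 else arr
    m, n = split.shape
    if np.all(split.var(axis=1) == 0):
        log.warning("degenerate (constant) chains: ESS reported as 0")
        return 0.0

    acov = np.vstack([_autocovariance(split[i]) for i in range(m)])
    chain_mean = split.mean(axis=1)
    mean_var = acov[:, 0].mean() * n / (n - 1.0)
    var_plus = mean_var * (n - 1.0) / n
    if m > 1:
        var_plus += chain_mean.var(ddof=1)

    rho_hat = np.zeros(n)
    rho_hat[0] = 1.0
    rho_hat_even = 1.0
    rho_hat_odd = 1.0 - (mean_var - acov[:, 1].mean()) / var_plus
    rho_hat[1] = rho_hat_odd
    # Geyer initial positive sequence
    t = 1
    while t < n - 3 and (rho_hat_even + rho_hat_odd) > 0.0:
        rho_hat_even = 1.0 - (mean_var - acov[:, t + 1].mean()) / var_plus
        rho_hat_odd = 1.0 - (mean_var - acov[:, t + 2].mean()) / var_plus
        if rho_hat_even + rho_hat_odd >= 0:
            rho_hat[t + 1] = rho_hat_even
            rho_hat[t + 2] = rho_hat_odd
        t += 2
    max_t = t - 2
    if rho_hat_even > 0:
        rho_hat[max_t + 1] = rho_hat_even
    # Geyer initial monotone sequence
    t = 1
    while t <= max_t - 2:
        if rho_hat[t + 1] + rho_hat[t + 2] > rho_hat[t - 1] + rho_hat[t]:
            rho_hat[t + 1] = (rho_hat[t - 1] + rho_hat[t]) / 2.0
            rho_hat[t + 2] = rho_hat[t + 1]
        t += 2
    ess = m * n
    tau_hat = -1.0 + 2.0 * np.sum(rho_hat[: max_t + 1]) + np.sum(
        rho_hat[max_t + 1: max_t + 2])
    tau_hat = max(tau_hat, 1.0 / np.log10(ess)) if ess > 10 else max(tau_hat, 1e-8)
    return float(ess / tau_hat)


@dataclass(frozen=True)
class RankHistograms:
    """Per-chain histograms of pooled ranks scaled into (0, 1)."""

    edges: np.ndarray               # bin edges in (0, 1)
    counts: np.ndarray              # (n_chains, n_bins)
    chisq: np.ndarray               # per-chain uniformity statistic
    pvalues: np.ndarray


def rank_histograms(chains, bins: int = 20) -> RankHistograms:
    """Pooled-rank histograms per chain, with chi-square uniformity stats.

    Ranks use average tie-handling and are scaled by (rank - 1/2)/N so
    every value lies strictly inside (0, 1).
    """
    arr = _as_chains(chains)
    m, n = arr.shape
    rank = rankdata(arr, method="average").reshape(arr.shape)
    scaled = (rank - 0.5) / arr.size
    edges = np.linspace(0.0, 1.0, bins + 1)
    counts = np.vstack([np.histogram(scaled[i], bins=edges)[0] for i in range(m)])
    expected = n / bins
    chisq = ((counts - expected) ** 2 / expected).sum(axis=1)
    pvalues = chi2.sf(chisq, df=bins - 1)
    return RankHistograms(edges=edges, counts=counts, chisq=chisq, pvalues=pvalues)


def parameter_correlations(samples, labels=None) -> pd.DataFrame:
    """Pearson correlation matrix between parameters from pooled draws.

    ``samples`` is (n_draws, d) with n_draws >= 30.  Zero-variance
    parameters yield masked (NaN) rows/columns.  With default labels for
    the elbow problem, index entries are (muscle, node) pairs, so both the
    across-muscles-within-a-node view and the across-nodes-within-a-muscle
    view are plain cross-sections.
    """
    arr = np.asarray(samples, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 30:
        raise ValueError("need pooled draws shaped (n >= 30, d)")
    d = arr.shape[1]
    sd = arr.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(arr, rowvar=False)
    corr[sd == 0, :] = np.nan
    corr[:, sd == 0] = np.nan
    if labels is None:
        labels = [f"p{j}" for j in range(d)]
    if isinstance(labels[0], tuple):
        idx = pd.MultiIndex.from_tuples(labels, names=["muscle", "node"])
    else:
        idx = pd.Index(labels)
    return pd.DataFrame(corr, index=idx, columns=idx)


def elbow_parameter_labels(muscle_names, n_nodes: int) -> list[tuple[str, int]]:
    """(muscle, node) labels matching the flattened amplitude layout."""
    return [(m, i + 1) for m in muscle_names for i in range(n_nodes)]


def subsample_chains(results, per_chain: int = 25,
                     burn_in_frac: float | None = None) -> np.ndarray:
    """Evenly spaced post-burn-in proposals from each chain.

    With the full-scale geometry (500,000 iterations, 50% burn-in,
    25/chain) the spacing is 10,000 iterations and 7 chains give 175
    proposals.  Returns a (n_chains * per_chain, d) array.
    """
    selected = []
    for res in results:
        frac = res.config["burn_in_frac"] if burn_in_frac is None else burn_in_frac
        post = res.samples[int(res.n_iter * frac):]
        n_post = post.shape[0]
        if n_post < per_chain:
            raise ValueError(
                f"chain {res.chain_id}: {n_post} post-burn-in draws < "
                f"per_chain = {per_chain}")
        spacing = n_post // per_chain
        idx = spacing * np.arange(1, per_chain + 1) - 1
        selected.append(post[idx])
    return np.vstack(selected)


def subsample_indices(n_iter: int, burn_in_frac: float, per_chain: int) -> np.ndarray:
    """Absolute iteration indices of the evenly spaced subsample."""
    burn = int(n_iter * burn_in_frac)
    spacing = (n_iter - burn) // per_chain
    if spacing < 1:
        raise ValueError(f"post-burn-in length {n_iter - burn} < per_chain")
    return burn + spacing * np.arange(1, per_chain + 1) - 1


@dataclass
class DiagnosticsReport:
    """Per-parameter convergence diagnostics for a chain ensemble."""

    rhat: np.ndarray
    ess: np.ndarray
    rank_hists: list            # per parameter: RankHistograms
    correlations: pd.DataFrame
    labels: list
    n_chains: int
    n_draws_per_chain: int

    def to_dict(self) -> dict:
        return {
            "n_chains": self.n_chains,
            "n_draws_per_chain": self.n_draws_per_chain,
            "parameters": [
                {
                    "label": list(l) if isinstance(l, tuple) else l,
                    "rhat": None if np.isnan(self.rhat[j]) else float(self.rhat[j]),
                    "ess": float(self.ess[j]),
                    "rank_chisq": self.rank_hists[j].chisq.tolist(),
                }
                for j, l in enumerate(self.labels)
            ],
            "rhat_max": float(np.nanmax(self.rhat)),
            "rhat_below_1p1": int(np.sum(self.rhat < 1.1)),
            "ess_min": float(np.min(self.ess)),
        }


def within_chain_correlations(results, labels=None, max_draws: int = 500,
                              burn_in_frac: float | None = None) -> pd.DataFrame:
    """Parameter correlations computed per chain and averaged.

    When chains have not mixed, pooling draws across chains lets the
    between-chain displacement masquerade as correlation; computing the
    Pearson matrix within each chain's post-burn-in draws (thinned to at
    most ``max_draws``) and averaging isolates the posterior's local
    trade-off structure instead.
    """
    mats = []
    for res in results:
        frac = res.config["burn_in_frac"] if burn_in_frac is None else burn_in_frac
        post = res.post_burn_in(frac)
        stride = max(1, post.shape[0] // max_draws)
        mats.append(parameter_correlations(post[::stride], labels=labels))
    return sum(mats) / len(mats)


def compute_diagnostics(results, burn_in_frac: float | None = None,
                        labels=None, corr_per_chain: int = 25) -> DiagnosticsReport:
    """R-hat, ESS and rank histograms per parameter, plus the within-chain
    averaged correlation matrix."""
    frac = results[0].config["burn_in_frac"] if burn_in_frac is None else burn_in_frac
    post = np.stack([r.post_burn_in(frac) for r in results])  # (m, n, d)
    m, n, d = post.shape
    if labels is None:
        labels = [f"p{j}" for j in range(d)]
    rhat = np.array([split_rhat(post[:, :, j]) for j in range(d)])
    ess = np.array([effective_sample_size(post[:, :, j]) for j in range(d)])
    hists = [rank_histograms(post[:, :, j]) for j in range(d)]
    corr = within_chain_correlations(results, labels=labels, burn_in_frac=frac)
    return DiagnosticsReport(rhat=rhat, ess=ess, rank_hists=hists,
                             correlations=corr, labels=labels,
                             n_chains=m, n_draws_per_chain=n)


@dataclass
class PosteriorSummary:
    """Mean/SD envelopes and tracking errors of subsampled proposals."""

    t: np.ndarray
    theta_mean: np.ndarray
    theta_sd: np.ndarray
    omega_mean: np.ndarray
    omega_sd: np.ndarray
    force_mean: np.ndarray      # (len(t), n_muscles)
    force_sd: np.ndarray
    rmse_pos_deg: float         # average over proposals
    rmse_vel_deg_s: float
    efforts: np.ndarray         # per-proposal effort integrals
    n_proposals: int
    n_excluded: int
    muscle_names: list

    def to_dict(self) -> dict:
        return {
            "rmse_pos_deg": self.rmse_pos_deg,
            "rmse_vel_deg_s": self.rmse_vel_deg_s,
            "n_proposals": self.n_proposals,
            "n_excluded": self.n_excluded,
            "effort_mean": float(np.mean(self.efforts)),
            "effort_sd": float(np.std(self.efforts)),
            "muscle_names": list(self.muscle_names),
        }


def summarize_posterior(proposals, posterior, reference) -> PosteriorSummary:
    """Forward-simulate each proposal and summarize kinematics and forces.

    ``posterior`` is the :class:`~myosampler.bayes.ElbowPosterior` used for
    sampling; ``reference`` supplies the tracked theta_ref / omega_ref.
    RMSEs are computed per proposal against the reference and then
    averaged, and reported in degrees / degrees per second.  Proposals
    whose simulation diverges are excluded (counted).
    """
    from .elbow import SimulationDivergedError

    proposals = np.asarray(proposals, dtype=float)
    s = posterior._lik_stride
    t = posterior.t_lik
    thetas, omegas, forces, efforts = [], [], [], []
    rmse_p, rmse_v = [], []
    excluded = 0
    # the posterior holds the reference resampled onto the likelihood grid
    theta_ref = posterior.theta_ref
    omega_ref = posterior.omega_ref
    for a in proposals:
        try:
            traj = posterior.simulate(a, with_forces=True)
        except SimulationDivergedError:
            excluded += 1
            log.warning("excluded a diverged stored proposal")
            continue
        th = traj.theta[::s]
        om = traj.omega[::s]
        thetas.append(th)
        omegas.append(om)
        forces.append(traj.forces[::s])
        exc = posterior.excitations(a)
        efforts.append(float(np.sum(np.trapezoid(
            exc.u[:, ::2 * s] ** 3, t, axis=1))))
        rmse_p.append(np.sqrt(np.mean((th - theta_ref) ** 2)))
        rmse_v.append(np.sqrt(np.mean((om - omega_ref) ** 2)))
    if not thetas:
        raise ValueError("every proposal diverged; nothing to summarize")
    th = np.array(thetas)
    om = np.array(omegas)
    fo = np.array(forces)
    return PosteriorSummary(
        t=t,
        theta_mean=th.mean(axis=0), theta_sd=th.std(axis=0),
        omega_mean=om.mean(axis=0), omega_sd=om.std(axis=0),
        force_mean=fo.mean(axis=0), force_sd=fo.std(axis=0),
        rmse_pos_deg=float(np.degrees(np.mean(rmse_p))),
        rmse_vel_deg_s=float(np.degrees(np.mean(rmse_v))),
        efforts=np.array(efforts),
        n_proposals=len(thetas),
        n_excluded=excluded,
        muscle_names=posterior.spec.muscle_names,
    )
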