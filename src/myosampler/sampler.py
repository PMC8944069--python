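"""Delayed-Rejection Adaptive Metropolis (DRAM) MCMC.

The posterior over CRBF amplitudes is a black box (each evaluation runs a
forward dynamics simulation), so sampling uses a random-walk Metropolis
scheme with two standard accelerations:

* **Adaptive Metropolis (AM)** — the multivariate-normal proposal
  covariance is tuned from the chain's own history,
  ``C = s_d * (cov + eps * I)`` with the usual scale ``s_d = 2.4^2 / d``,
  recomputed every ``adapt_interval`` iterations once ``adapt_start``
  iterations have accrued.  By default the covariance is an exponentially
  weighted estimate with ``adapt_window`` memory, so the proposal tracks
  the chain's current neighbourhood rather than the whole burn-in descent
  (``adapt_window=None`` gives the classic full-history recursion).

* **Delayed rejection (DR)** — after a first-stage rejection of ``y1`` a
  second, narrowed proposal ``y2 ~ N(x, shrink^2 C)`` is tried and accepted
  with the two-stage probability

      alpha_2 = min{1, [pi(y2) q1(y2,y1) (1 - alpha_1(y2,y1))]
                      / [pi(x)  q1(x,y1)  (1 - alpha_1(x,y1))]}

  which preserves detailed balance.  If both stages reject, the previous
  state is copied forward.

Chains start from independent uniform[-15, -5] amplitude draws (so every
muscle starts nearly silent) and the initial proposal is always accepted.
Each chain is fully reproducible from ``(seed, chain_id)`` via independent
``SeedSequence`` streams.  Results carry the parameter samples, the
log-density traces, per-iteration acceptance stage flags and proposal
covariance snapshots.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.linalg import cholesky, solve_triangular

__all__ = [
    "SamplerConfig",
    "ChainResult",
    "ChainFailure",
    "initial_proposal",
    "mh_accept",
    "dr_second_stage",
    "adapt_covariance",
    "run_chain",
    "resume_chain",
    "run_chains",
]

log = logging.getLogger(__name__)

STAGE_REJECTED = 0
STAGE_FIRST = 1
STAGE_SECOND = 2


@dataclass(frozen=True)
class SamplerConfig:
    """DRAM settings.  Defaults mirror the full-scale study geometry
    (500,000 iterations, 7 chains, 50% burn-in) and standard AM/DR tuning."""

    dim: int
    n_iter: int = 500_000
    n_chains: int = 7
    burn_in_frac: float = 0.5
    init_low: float = -15.0
    init_high: float = -5.0
    seed: int = 0
    init_proposal_sd: float = 0.5
    adapt_start: int | None = None     # default max(1000, n_iter // 100)
    adapt_interval: int = 100
    am_scale: float | None = None      # default 2.4^2 / dim
    am_epsilon: float = 1e-6
    dr_shrink: float = 0.2
    adapt_window: int | None = 10_000  # EW memory; None = full history

    def __post_init__(self) -> None:
        if self.dim < 1:
            raise ValueError("dim must be >= 1")
        if self.n_iter < 2:
            raise ValueError("n_iter must be >= 2")
        if not 0.0 < self.burn_in_frac < 1.0:
            raise ValueError("burn_in_frac must be in (0, 1)")
        if not 0.0 < self.dr_shrink < 1.0:
            raise ValueError("dr_shrink must be in (0, 1)")
        if self.init_high <= self.init_low:
            raise ValueError("init_high must exceed init_low")

    @property
    def adapt_start_effective(self) -> int:
        if self.adapt_start is not None:
            return self.adapt_start
        return max(1000, self.n_iter // 100)

    @property
    def am_scale_effective(self) -> float:
        return self.am_scale if self.am_scale is not None else 2.4 ** 2 / self.dim

    @property
    def n_burn_in(self) -> int:
        return int(self.n_iter * self.burn_in_frac)

    def to_dict(self) -> dict:
        return {
            "dim": self.dim, "n_iter": self.n_iter, "n_chains": self.n_chains,
            "burn_in_frac": self.burn_in_frac, "init_low": self.init_low,
            "init_high": self.init_high, "seed": self.seed,
            "init_proposal_sd": self.init_proposal_sd,
            "adapt_start": self.adapt_start_effective,
            "adapt_interval": self.adapt_interval,
            "am_scale": self.am_scale_effective,
            "am_epsilon": self.am_epsilon, "dr_shrink": self.dr_shrink,
            "adapt_window": self.adapt_window,
        }


@dataclass
class ChainResult:
    """Everything one chain produced.

    ``stage[i]`` records how iteration i entered the chain: 1 first-stage
    accept, 2 delayed-rejection accept, 0 rejection (state copied).  The
    initial draw is recorded as stage 1 (always accepted).
    """

    samples: np.ndarray            # (n_iter, dim)
    logpost: np.ndarray
    loglik: np.ndarray
    logprior: np.ndarray
    stage: np.ndarray              # int8
    chain_id: int
    seed: int
    config: dict
    cov_snapshots: list = field(default_factory=list)   # [(iteration, cov)]
    resume_state: dict | None = None   # sampler state after the last iteration

    @property
    def n_iter(self) -> int:
        return self.samples.shape[0]

    @property
    def accepted(self) -> np.ndarray:
        return self.stage > 0

    @property
    def acceptance_rate(self) -> float:
        return float(np.mean(self.stage[1:] > 0))

    def stage_counts(self) -> dict:
        s = self.stage[1:]
        return {
            "first_stage": int(np.sum(s == STAGE_FIRST)),
            "second_stage": int(np.sum(s == STAGE_SECOND)),
            "rejected": int(np.sum(s == STAGE_REJECTED)),
        }

    def post_burn_in(self, burn_in_frac: float | None = None) -> np.ndarray:
        frac = self.config["burn_in_frac"] if burn_in_frac is None else burn_in_frac
        return self.samples[int(self.n_iter * frac):]

    # -- persistence ------------------------------------------------------

    def save(self, path) -> Path:
        """Write the chain as <path>.npz plus a JSON metadata sidecar."""
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        arrays = dict(
            samples=self.samples, logpost=self.logpost, loglik=self.loglik,
            logprior=self.logprior, stage=self.stage,
            cov_iters=np.array([i for i, _ in self.cov_snapshots], dtype=np.int64),
            cov_mats=np.array([c for _, c in self.cov_snapshots])
            if self.cov_snapshots else np.empty((0, 0, 0)),
        )
        meta = {"chain_id": self.chain_id, "seed": self.seed, "config": self.config}
        if self.resume_state is not None:
            rs = self.resume_state
            arrays.update(resume_x=rs["x"], resume_chol=rs["chol_lower"],
                          resume_mean=rs["moments"]["mean"],
                          resume_cov=rs["moments"]["cov"])
            meta["resume"] = {
                "next_it": rs["next_it"], "lp": list(rs["lp"]),
                "rng_state": rs["rng_state"],
                "moments_n": rs["moments"]["n"],
                "moments_window": rs["moments"]["window"],
            }
        np.savez(path.with_suffix(".npz"), **arrays)
        path.with_suffix(".json").write_text(json.dumps(meta, indent=1, sort_keys=True))
        return path.with_suffix(".npz")

    @classmethod
    def load(cls, path) -> "ChainResult":
        path = Path(path)
        with np.load(path.with_suffix(".npz")) as z:
            arrays = {k: z[k] for k in z.files}
        meta = json.loads(path.with_suffix(".json").read_text())
        snaps = list(zip(arrays["cov_iters"].tolist(), arrays["cov_mats"])) \
            if arrays["cov_mats"].size else []
        resume_state = None
        if "resume" in meta:
            r = meta["resume"]
            # JSON round-trips the generator state's key arrays as lists
            rng_state = r["rng_state"]
            if isinstance(rng_state.get("state"), dict):
                st = rng_state["state"]
                if isinstance(st.get("key"), list):
                    st["key"] = np.array(st["key"], dtype=np.uint64)
            resume_state = {
                "next_it": r["next_it"], "x": arrays["resume_x"],
                "lp": tuple(r["lp"]), "rng_state": rng_state,
                "chol_lower": arrays["resume_chol"],
                "moments": {"n": r["moments_n"], "window": r["moments_window"],
                            "mean": arrays["resume_mean"],
                            "cov": arrays["resume_cov"]},
            }
        return cls(samples=arrays["samples"], logpost=arrays["logpost"],
                   loglik=arrays["loglik"], logprior=arrays["logprior"],
                   stage=arrays["stage"], chain_id=meta["chain_id"],
                   seed=meta["seed"], config=meta["config"], cov_snapshots=snaps,
                   resume_state=resume_state)

    def to_csv(self, path) -> Path:
        """Interoperable CSV export (samples + traces)."""
        import pandas as pd

        d = self.samples.shape[1]
        df = pd.DataFrame(self.samples, columns=[f"a{j}" for j in range(d)])
        df["logpost"] = self.logpost
        df["loglik"] = self.loglik
        df["logprior"] = self.logprior
        df["stage"] = self.stage
        path = Path(path)
        df.to_csv(path, index=False)
        return path


class ChainFailure(RuntimeError):
    """A chain aborted; completed chains are preserved on .partial_results."""

    def __init__(self, message: str, partial_results: list):
        super().__init__(message)
        self.partial_results = partial_results


# --------------------------------------------------------------- pieces

def chain_rng(seed: int, chain_id: int) -> np.random.Generator:
    """Independent, reproducible RNG stream for one chain."""
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(chain_id,)))


def initial_proposal(dim: int, rng: np.random.Generator,
                     low: float = -15.0, high: float = -5.0) -> np.ndarray:
    """Independent uniform[low, high] draws; the default starts every muscle
    nearly silent (sigmoid(-5) ~ 0.0067)."""
    return rng.uniform(low, high, size=dim)


def mh_accept(logpost_new: float, logpost_old: float,
              rng: np.random.Generator) -> bool:
    """Metropolis rule: accept uphill moves always, downhill ones with
    probability equal to the density ratio."""
    if math.isnan(logpost_new) or math.isnan(logpost_old):
        raise ValueError("NaN log-posterior in acceptance test")
    if logpost_new == -math.inf:
        # zero-density proposals are always rejected, even from a
        # zero-density state (otherwise a chain could drift while invalid)
        return False
    if logpost_new >= logpost_old:
        return True
    return rng.random() < math.exp(logpost_new - logpost_old)


def adapt_covariance(history: np.ndarray, cfg: SamplerConfig) -> np.ndarray:
    """AM proposal covariance from the chain history:
    ``s_d * (cov + eps I)``, guaranteed symmetric positive definite."""
    history = np.asarray(history, dtype=float)
    if history.shape[0] < 2:
        raise ValueError("need at least 2 history points")
    s = cfg.am_scale_effective
    cov = np.cov(history, rowvar=False).reshape(cfg.dim, cfg.dim)
    c = s * (cov + cfg.am_epsilon * np.eye(cfg.dim))
    return 0.5 * (c + c.T)


def _log1m_exp(log_a: float) -> float:
    """log(1 - exp(log_a)) for log_a < 0."""
    if log_a >= 0.0:
        return -math.inf
    if log_a > -0.693:
        return math.log(-math.expm1(log_a))
    return math.log1p(-math.exp(log_a))


def _quad_form(chol_lower: np.ndarray, diff: np.ndarray) -> float:
    """diff^T C^-1 diff given the lower Cholesky factor of C."""
    z = solve_triangular(chol_lower, diff, lower=True, check_finite=False)
    return float(z @ z)


def dr_second_stage(x, lp_x: float, y1, lp_y1: float, chol_lower,
                    target, rng, dr_shrink: float = 0.2):
    """One delayed-rejection stage after a first-stage rejection.

    Draws ``y2 ~ N(x, shrink^2 C)`` and applies the two-stage acceptance
    probability.  Returns ``(accepted, y2, eval_y2)`` where ``eval_y2`` is
    the target's evaluation triple (or None if y2 was never evaluated
    because the acceptance is structurally zero).
    """
    d = x.size
    y2 = x + dr_shrink * (chol_lower @ rng.standard_normal(d))
    ev2 = target(y2)
    lp_y2 = ev2[0]
    if lp_y2 == -math.inf:
        return False, y2, ev2
    # alpha_1(y2, y1): if y1 beats y2 the numerator factor (1 - alpha) is 0.
    if lp_y1 >= lp_y2:
        return False, y2, ev2
    log_num_1m = _log1m_exp(lp_y1 - lp_y2)
    if lp_y1 >= lp_x:
        # cannot happen: stage 1 rejected means lp_y1 < lp_x
        log_den_1m = 0.0
    elif lp_y1 == -math.inf:
        log_den_1m = 0.0
    else:
        log_den_1m = _log1m_exp(lp_y1 - lp_x)
    # q1 ratio: N(y1; y2, C) / N(y1; x, C)
    lq = -0.5 * (_quad_form(chol_lower, y1 - y2) - _quad_form(chol_lower, y1 - x))
    log_alpha2 = (lp_y2 - lp_x) + lq + log_num_1m - log_den_1m
    accept = log_alpha2 >= 0.0 or rng.random() < math.exp(log_alpha2)
    return accept, y2, ev2


# ----------------------------------------------------------------- chains

def _normalize_eval(out):
    """Targets may return a scalar log-density or a (post, lik, prior) triple."""
    if isinstance(out, tuple):
        return float(out[0]), float(out[1]), float(out[2])
    return float(out), float(out), 0.0


class _RunningMoments:
    """Welford accumulators for the AM sample covariance.

    With ``window`` set, the update weight is 1/min(n, window): exact
    running moments up to ``window`` draws, then an exponentially weighted
    estimate with that memory.  The forgetting keeps the proposal matched
    to the chain's *current* neighbourhood instead of the whole transient,
    which is what rescues chains that descend a long way during burn-in.
    """

    def __init__(self, dim: int, window: int | None = None):
        self.n = 0
        self.window = window
        self.mean = np.zeros(dim)
        self.cov_ = np.zeros((dim, dim))

    def push(self, x: np.ndarray) -> None:
        self.n += 1
        if self.n == 1:
            self.mean = x.astype(float).copy()
            return
        eta = 1.0 / (self.n if self.window is None else min(self.n, self.window))
        delta = x - self.mean
        self.mean += eta * delta
        self.cov_ = (1.0 - eta) * (self.cov_ + eta * np.outer(delta, delta))

    def cov(self) -> np.ndarray:
        # the (1-eta) recursion is the standard recursive covariance: for
        # eta = 1/n it reproduces the biased sample covariance, rescale to
        # the unbiased convention used by np.cov
        if self.n < 2:
            return self.cov_
        if self.window is None or self.n <= self.window:
            return self.cov_ * self.n / (self.n - 1)
        return self.cov_


def run_chain(target, cfg: SamplerConfig, chain_id: int = 0,
              initial: np.ndarray | None = None) -> ChainResult:
    """Run one DRAM chain.

    ``target`` is a callable mapping a parameter vector to either a scalar
    log-posterior or a ``(logpost, loglik, logprior)`` triple.  Fully
    reproducible from ``(cfg.seed, chain_id)``.
    """
    rng = chain_rng(cfg.seed, chain_id)
    d = cfg.dim
    n = cfg.n_iter

    samples = np.empty((n, d))
    logpost = np.empty(n)
    loglik = np.empty(n)
    logprior = np.empty(n)
    stage = np.zeros(n, dtype=np.int8)

    x = np.asarray(initial, dtype=float) if initial is not None \
        else initial_proposal(d, rng, cfg.init_low, cfg.init_high)
    try:
        lp_x, ll_x, lpr_x = _normalize_eval(target(x))
    except Exception as err:  # surface context for debugging
        raise ChainFailure(
            f"chain {chain_id}: target failed on the initial proposal: {err}", []
        ) from err

    samples[0] = x
    logpost[0], loglik[0], logprior[0] = lp_x, ll_x, lpr_x
    stage[0] = STAGE_FIRST  # initial proposal is always accepted

    c0 = cfg.init_proposal_sd ** 2 * np.eye(d)
    chol_lower = cholesky(c0, lower=True)
    moments = _RunningMoments(d, window=cfg.adapt_window)
    moments.push(x)
    cov_snapshots = [(0, c0.copy())]
    adapt_start = cfg.adapt_start_effective

    return _advance(target, cfg, chain_id, rng, x, (lp_x, ll_x, lpr_x),
                    chol_lower, moments, samples, logpost, loglik, logprior,
                    stage, cov_snapshots, start_it=1)


def _advance(target, cfg, chain_id, rng, x, lp_triple, chol_lower, moments,
             samples, logpost, loglik, logprior, stage, cov_snapshots,
             start_it):
    """DRAM inner loop from ``start_it`` to the end of the arrays."""
    d = cfg.dim
    n = samples.shape[0]
    lp_x, ll_x, lpr_x = lp_triple
    adapt_start = cfg.adapt_start_effective

    def _target3(v):
        return _normalize_eval(target(v))

    for it in range(start_it, n):
        y1 = x + chol_lower @ rng.standard_normal(d)
        try:
            lp1, ll1, lpr1 = _target3(y1)
        except Exception as err:
            raise ChainFailure(
                f"chain {chain_id}: target raised at iteration {it}: {err}",
                []) from err
        if mh_accept(lp1, lp_x, rng):
            x, lp_x, ll_x, lpr_x = y1, lp1, ll1, lpr1
            stage[it] = STAGE_FIRST
        else:
            accepted, y2, ev2 = dr_second_stage(
                x, lp_x, y1, lp1, chol_lower, _target3, rng, cfg.dr_shrink)
            if accepted:
                x = y2
                lp_x, ll_x, lpr_x = ev2
                stage[it] = STAGE_SECOND
            else:
                stage[it] = STAGE_REJECTED

        samples[it] = x
        logpost[it], loglik[it], logprior[it] = lp_x, ll_x, lpr_x
        moments.push(x)

        if it >= adapt_start and it % cfg.adapt_interval == 0:
            c = cfg.am_scale_effective * (
                moments.cov() + cfg.am_epsilon * np.eye(d))
            try:
                chol_lower = cholesky(0.5 * (c + c.T), lower=True)
            except np.linalg.LinAlgError:
                c += cfg.am_scale_effective * cfg.am_epsilon * 10 * np.eye(d)
                chol_lower = cholesky(0.5 * (c + c.T), lower=True)
            cov_snapshots.append((it, c))

    resume_state = {
        "next_it": n,
        "x": x.copy(),
        "lp": (lp_x, ll_x, lpr_x),
        "rng_state": rng.bit_generator.state,
        "chol_lower": chol_lower.copy(),
        "moments": {"n": moments.n, "window": moments.window,
                    "mean": moments.mean.copy(), "cov": moments.cov_.copy()},
    }

    # keep at most 5 covariance snapshots (first, last, evenly between)
    if len(cov_snapshots) > 5:
        idx = np.unique(np.linspace(0, len(cov_snapshots) - 1, 5).astype(int))
        cov_snapshots = [cov_snapshots[i] for i in idx]

    return ChainResult(samples=samples, logpost=logpost, loglik=loglik,
                       logprior=logprior, stage=stage, chain_id=chain_id,
                       seed=cfg.seed, config=cfg.to_dict(),
                       cov_snapshots=cov_snapshots, resume_state=resume_state)


def resume_chain(result: ChainResult, target, n_extra: int) -> ChainResult:
    """Continue a stored chain for ``n_extra`` iterations.

    The continuation consumes the RNG stream and adaptation state exactly
    where the original run stopped, so `run (a+b)` equals
    `run a, resume b` bit for bit.
    """
    if result.resume_state is None:
        raise ValueError("chain carries no resume state")
    rs = result.resume_state
    cfg = SamplerConfig(**result.config)
    n_old = result.n_iter
    n = n_old + n_extra
    d = cfg.dim

    samples = np.empty((n, d))
    logpost = np.empty(n)
    loglik = np.empty(n)
    logprior = np.empty(n)
    stage = np.zeros(n, dtype=np.int8)
    samples[:n_old] = result.samples
    logpost[:n_old] = result.logpost
    loglik[:n_old] = result.loglik
    logprior[:n_old] = result.logprior
    stage[:n_old] = result.stage

    rng = chain_rng(result.seed, result.chain_id)
    rng.bit_generator.state = rs["rng_state"]
    moments = _RunningMoments(d, window=rs["moments"]["window"])
    moments.n = int(rs["moments"]["n"])
    moments.mean = np.asarray(rs["moments"]["mean"], dtype=float).copy()
    moments.cov_ = np.asarray(rs["moments"]["cov"], dtype=float).copy()

    return _advance(target, cfg, result.chain_id, rng,
                    np.asarray(rs["x"], dtype=float).copy(), tuple(rs["lp"]),
                    np.asarray(rs["chol_lower"], dtype=float).copy(), moments,
                    samples, logpost, loglik, logprior, stage,
                    list(result.cov_snapshots), start_it=n_old)


def run_chains(target, cfg: SamplerConfig, progress: bool = False) -> list[ChainResult]:
    """Run ``cfg.n_chains`` independent chains serially.

    Each chain uses its own RNG stream, so the ensemble is identical no
    matter how chains would be scheduled.  If a chain fails, previously
    completed chains are preserved on the raised :class:`ChainFailure`.
    """
    results: list[ChainResult] = []
    for cid in range(cfg.n_chains):
        if progress:
            log.info("running chain %d / %d", cid + 1, cfg.n_chains)
        try:
            results.append(run_chain(target, cfg, chain_id=cid))
        except ChainFailure as err:
            raise ChainFailure(str(err), results) from err
    return results
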