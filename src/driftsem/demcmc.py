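"""Differential-evolution MCMC for per-participant diffusion-model fits.

Each chain proposes ``x_k' = x_k + gamma * (x_m - x_n) + U(-eps, eps)`` with
``m != n != k`` drawn without replacement, accepted by a Metropolis step on the
log posterior (diffusion likelihood + flat bounded priors).  Convergence is
judged by the multivariate potential scale reduction factor computed from the
between- and within-chain covariance matrices (largest-eigenvalue form); point
estimates are posterior means over post-burn-in samples pooled across chains.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .ddm import DDMParams, _loglik, _GL_X, _GL_W, _as_arrays

__all__ = ["SamplerConfig", "ChainSet", "ConvergenceReport", "run_demc",
           "compute_mpsf", "point_estimates", "fit_participants"]

PARAM_NAMES = ["v", "a", "t0", "st0", "sv"]

_DEFAULT_PRIORS = {
    "v": (-10.0, 10.0),
    "a": (0.2, 5.0),
    "t0": (0.05, 1.0),
    "st0": (0.0, 0.5),
    "sv": (0.0, 5.0),
}
MIN_TRIALS = 40
_T0_MARGIN = 0.05  # joint support: t0 - st0/2 > 0.05 s


@dataclass
class SamplerConfig:
    """DE-MCMC tuning knobs.

    Defaults follow common practice for a 5-parameter target: 15 chains
    (3 x number of parameters), 2000 iterations with the first 1000 discarded,
    ``gamma = 2.38 / sqrt(2 d)`` and uniform jitter of half-width 0.001.
    """

    n_chains: int = 15
    n_iter: int = 2000
    burn_in: int = 1000
    gamma: float | None = None
    jitter_half_width: float = 0.001
    seed: int = 0
    priors: dict = field(default_factory=lambda: dict(_DEFAULT_PRIORS))
    migration_prob: float = 0.10  # burn-in only; rescues outlier chains

    def __post_init__(self) -> None:
        d = len(PARAM_NAMES)
        if self.n_chains < 2 * d:
            raise ValueError(f"need at least {2 * d} chains for {d} parameters")
        if not (0 <= self.burn_in < self.n_iter):
            raise ValueError("burn_in must lie in [0, n_iter)")
        if self.gamma is None:
            self.gamma = 2.38 / math.sqrt(2 * d)


@dataclass
class ChainSet:
    """Posterior draws: ``samples`` has shape (chains, iterations, 5)."""

    samples: np.ndarray
    log_posterior: np.ndarray   # (chains, iterations)
    accepted: np.ndarray        # accepted moves per chain
    burn_in: int
    param_names: tuple = tuple(PARAM_NAMES)
    degenerate_responses: bool = False  # all-correct or all-error data

    def retained(self) -> np.ndarray:
        return self.samples[:, self.burn_in:, :]


@dataclass
class ConvergenceReport:
    mpsf: float
    psrf: dict
    threshold: float = 1.15

    @property
    def converged(self) -> bool:
        return self.mpsf < self.threshold

    def to_dict(self) -> dict:
        return {"mpsf": self.mpsf, "psrf": dict(self.psrf),
                "threshold": self.threshold, "converged": self.converged}


def _in_support(x: np.ndarray, bounds: np.ndarray) -> bool:
    if np.any(x < bounds[:, 0]) or np.any(x > bounds[:, 1]):
        return False
    # joint constraint keeping the earliest nondecision time positive
    return x[2] - x[3] / 2.0 > _T0_MARGIN


def run_demc(trials, cfg: SamplerConfig, log_density=None) -> ChainSet:
    """Sample the diffusion posterior for one participant-condition block.

    ``trials`` is a filtered trial DataFrame (columns ``rt``, ``response``) or
    an ``(rt, correct)`` tuple.  ``log_density`` may replace the diffusion
    log-likelihood with an arbitrary function of the 5-vector (used by the
    sampler's own tests against analytic targets); the trial-count guard is
    then skipped.
    """
    degenerate = False
    if log_density is None:
        rt, correct = _as_arrays(trials)
        if rt.shape[0] < MIN_TRIALS:
            raise ValueError(
                f"need at least {MIN_TRIALS} trials, got {rt.shape[0]}")
        degenerate = bool(correct.min() == correct.max())

        def log_density(x):
            return _loglik(rt, correct, x[0], x[1], x[2], x[3], x[4],
                           _GL_X, _GL_W)

    rng = np.random.default_rng(cfg.seed)
    d = len(PARAM_NAMES)
    m = cfg.n_chains
    bounds = np.array([cfg.priors[p] for p in PARAM_NAMES])

    # initialize chains from the prior, honouring the joint support
    cur = np.empty((m, d))
    for k in range(m):
        for _ in range(10_000):
            x = bounds[:, 0] + rng.random(d) * (bounds[:, 1] - bounds[:, 0])
            if _in_support(x, bounds):
                break
        cur[k] = x
    cur_lp = np.array([log_density(x) for x in cur])

    samples = np.empty((m, cfg.n_iter, d))
    lp_trace = np.empty((m, cfg.n_iter))
    accepted = np.zeros(m, dtype=int)

    for it in range(cfg.n_iter):
        if it < cfg.burn_in and rng.random() < cfg.migration_prob:
            # migration (burn-in only): cyclically propose states along a
            # random subset of chains, Metropolis-accepting each handoff;
            # lets chains stranded in low-density regions jump to the mode
            size = int(rng.integers(1, m + 1))
            idx = rng.choice(m, size=size, replace=False)
            prev_states = cur[idx].copy()
            prev_lps = cur_lp[idx].copy()
            for j in range(size):
                src = (j - 1) % size
                cand, cand_lp = prev_states[src], prev_lps[src]
                if math.log(rng.random()) < cand_lp - cur_lp[idx[j]]:
                    cur[idx[j]] = cand
                    cur_lp[idx[j]] = cand_lp
        for k in range(m):
            # pick two distinct partner chains, both != k
            mn = rng.choice(m - 1, size=2, replace=False)
            mn[mn >= k] += 1
            prop = cur[k] + cfg.gamma * (cur[mn[0]] - cur[mn[1]]) \
                + rng.uniform(-cfg.jitter_half_width, cfg.jitter_half_width, d)
            if _in_support(prop, bounds):
                lp = log_density(prop)
                if math.log(rng.random()) < lp - cur_lp[k]:
                    cur[k] = prop
                    cur_lp[k] = lp
                    accepted[k] += 1
            samples[k, it] = cur[k]
            lp_trace[k, it] = cur_lp[k]

    return ChainSet(samples=samples, log_posterior=lp_trace, accepted=accepted,
                    burn_in=cfg.burn_in, degenerate_responses=degenerate)


def compute_mpsf(chains: ChainSet | np.ndarray, threshold: float = 1.15
                 ) -> ConvergenceReport:
    """Multivariate potential scale reduction factor on post-burn-in samples.

    Uses the largest-eigenvalue form ``R^2 = 1 + (m+1)/m * lambda_max(W^-1 B_n)``
    where ``W`` is the pooled within-chain covariance and ``B_n`` the
    covariance of the chain means; equal chains give exactly 1 and the
    statistic is always >= 1.  Univariate PSRFs use the same form per
    parameter.
    """
    x = chains.retained() if isinstance(chains, ChainSet) else np.asarray(chains)
    if x.ndim == 2:
        x = x[:, :, None]
    m, n, d = x.shape
    if m < 2 or n < 10:
        raise ValueError("need >= 2 chains and >= 10 retained iterations")

    means = x.mean(axis=1)                      # (m, d)
    W = np.zeros((d, d))
    for k in range(m):
        dev = x[k] - means[k]
        W += dev.T @ dev / (n - 1)
    W /= m
    gm = means.mean(axis=0)
    B_n = (means - gm).T @ (means - gm) / (m - 1)   # B/n in ANOVA notation

    # symmetric generalized eigenproblem via Cholesky of W
    try:
        L = np.linalg.cholesky(W)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "within-chain covariance is singular; chains may be stuck "
            "(zero variance in some parameter)") from exc
    Linv = np.linalg.inv(L)
    lam_max = float(np.linalg.eigvalsh(Linv @ B_n @ Linv.T).max())
    mpsf = math.sqrt(1.0 + (m + 1) / m * max(lam_max, 0.0))

    names = chains.param_names if isinstance(chains, ChainSet) \
        else tuple(f"p{i}" for i in range(d))
    psrf = {}
    for j, name in enumerate(names):
        w = W[j, j]
        if w <= 0:
            raise np.linalg.LinAlgError(f"zero within-chain variance for {name}")
        psrf[name] = math.sqrt(1.0 + (m + 1) / m * B_n[j, j] / w)
    return ConvergenceReport(mpsf=mpsf, psrf=psrf, threshold=threshold)


def point_estimates(chains: ChainSet, check_convergence: bool = True):
    """Posterior-mean parameter estimates pooled over post-burn-in samples.

    Returns ``(DDMParams, warnings)``; a non-converged chain set still yields
    an estimate but carries a warning string.
    """
    warnings = []
    if check_convergence:
        try:
            rep = compute_mpsf(chains)
            if not rep.converged:
                warnings.append(f"not converged: MPSF = {rep.mpsf:.3f}")
        except np.linalg.LinAlgError as exc:
            warnings.append(f"convergence diagnostic failed: {exc}")
    mean = chains.retained().reshape(-1, len(chains.param_names)).mean(axis=0)
    est = dict(zip(chains.param_names, mean))
    # posterior means can sit fractionally outside the strict support
    if est["t0"] - est["st0"] / 2 <= 0:
        est["st0"] = max(2 * est["t0"] - 1e-6, 0.0)
    params = DDMParams(**est)
    if chains.degenerate_responses:
        warnings.append("all responses on one boundary")
    return params, warnings


def fit_participants(trials, cfg: SamplerConfig, progress: bool = False):
    """Fit every participant x condition block in a trial table.

    Returns ``(estimates, convergence)``: a DataFrame with one row per
    participant (columns ``<param>_<condition>`` and ``mpsf_<condition>``) and
    a dict of per-block ConvergenceReports keyed ``(participant, condition)``.
    Per-block seeds are derived deterministically from ``cfg.seed``.
    """
    import dataclasses

    import pandas as pd

    rows: dict = {}
    reports = {}
    blocks = list(trials.groupby(["participant_id", "condition"], sort=True))
    ss = np.random.SeedSequence([cfg.seed, 15485863])
    seeds = ss.generate_state(len(blocks))
    for i, ((pid, cond), grp) in enumerate(blocks):
        sub_cfg = dataclasses.replace(cfg, seed=int(seeds[i] % (2**31 - 1)))
        chains = run_demc(grp, sub_cfg)
        rep = compute_mpsf(chains)
        est, _ = point_estimates(chains, check_convergence=False)
        row = rows.setdefault(pid, {"participant_id": pid})
        for name in PARAM_NAMES:
            row[f"{name}_{cond}"] = getattr(est, name)
        row[f"mpsf_{cond}"] = rep.mpsf
        reports[(pid, cond)] = rep
        if progress:
            print(f"  fitted {pid}/{cond}: MPSF = {rep.mpsf:.3f}")
    return pd.DataFrame(list(rows.values())), reports
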