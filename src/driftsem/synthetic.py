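"""Synthetic dot-probe studies with a latent social-cognition layer.

The generator emulates the data structure the analysis pipeline assumes:

- two correlated latent traits per participant — social cognitive capacity
  (SCC) and social cognitive bias (SCB) — drawn from a bivariate standard
  normal;
- per-participant diffusion-model parameters for two task conditions
  (``baseline``: neutral-neutral faces; ``angry``: neutral-angry faces), drawn
  around population means with optional linear coupling to the latents and a
  configurable cross-condition residual correlation;
- trial-level reaction times and accuracies simulated from those parameters
  (two runs of ``trials_per_run`` trials; simulated responses slower than a
  response deadline are recorded as misses);
- observed indicator scores (one per questionnaire/task) generated as
  loading x latent + Gaussian residual, and outcome variables PSI (perceived
  social isolation, UCLA-R-like) and OSI (objective social isolation,
  reversed-SNS-like) generated from the structural paths;
- optional item-level matrices (20 UCLA-R-like and 6 SNS-like items) from a
  one-factor model per questionnaire, for reliability analyses.

Latents and the standardized outcome scale have unit variance, matching the
standardized reporting the downstream models use.  Everything is a
deterministic function of the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ddm import DDMParams, simulate_trials

__all__ = ["GeneratorConfig", "generate_participant_params", "generate_trials",
           "generate_scores", "generate_study"]

SCC_INDICATORS = ["MiniPONS", "PENN_ER40", "RMET", "Hinting"]
SCB_INDICATORS = ["DACOBS_AB", "AIHQ_BS"]
DDM_PARAM_NAMES = ["v", "a", "t0", "st0", "sv"]
CONDITIONS = ["baseline", "angry"]

# population means per condition; t0 and v differ between conditions the way a
# threat manipulation shifts them (slightly faster encoding, lower drift)
_DEFAULT_MEANS = {
    "baseline": {"v": 4.098, "a": 1.2, "t0": 0.347, "st0": 0.15, "sv": 1.0},
    "angry": {"v": 4.003, "a": 1.2, "t0": 0.343, "st0": 0.15, "sv": 1.0},
}
_DEFAULT_SDS = {"v": 0.443, "a": 0.15, "t0": 0.039, "st0": 0.04, "sv": 0.25}

# one-factor loadings chosen so the questionnaire totals show the reliability
# levels typical of these instruments (alpha ~ 0.94 / 0.84)
_UCLA_ITEM_LOADING = 0.663
_SNS_ITEM_LOADING = 0.683


def _default_loadings() -> dict:
    return {
        "MiniPONS": 0.60, "PENN_ER40": 0.70, "RMET": 0.65, "Hinting": 0.55,
        "DACOBS_AB": 0.75, "AIHQ_BS": 0.60,
    }


def _default_paths() -> dict:
    return {
        ("SCB", "PSI"): 0.56,
        ("SCB", "OSI"): 0.31,
        ("SCC", "OSI"): -0.26,
        ("SCC", "PSI"): 0.0,
    }


def _default_residual_sds(loadings: dict, paths: dict, latent_corr: float) -> dict:
    """Residual SDs that give every indicator and outcome unit total variance."""
    out = {}
    for ind, lam in loadings.items():
        out[ind] = float(np.sqrt(max(1.0 - lam**2, 1e-6)))
    for outcome in ("PSI", "OSI"):
        b_scc = paths.get(("SCC", outcome), 0.0)
        b_scb = paths.get(("SCB", outcome), 0.0)
        explained = b_scc**2 + b_scb**2 + 2 * b_scc * b_scb * latent_corr
        out[outcome] = float(np.sqrt(max(1.0 - explained, 1e-6)))
    return out


@dataclass
class GeneratorConfig:
    """Configuration of the synthetic-study generator.

    Structural paths are keyed ``(predictor, outcome)`` with predictors in
    ``{SCC, SCB, t0, v}`` (DDM predictors act through their condition-specific
    standardized values).  ``ddm_latent_coupling`` is keyed
    ``(ddm_param, latent)`` and gives the correlation-scale weight of the
    latent in that parameter's person-level variation.
    """

    n_participants: int = 271
    trials_per_run: int = 160
    seed: int = 0
    latent_corr: float = -0.32
    latent_loadings: dict = field(default_factory=_default_loadings)
    structural_paths: dict = field(default_factory=_default_paths)
    residual_sds: dict | None = None
    outcome_residual_corr: float = 0.30
    ddm_population_means: dict = field(
        default_factory=lambda: {c: dict(m) for c, m in _DEFAULT_MEANS.items()})
    ddm_population_sds: dict = field(default_factory=lambda: dict(_DEFAULT_SDS))
    ddm_latent_coupling: dict = field(default_factory=dict)
    ddm_cross_condition_corr: float = 0.7
    response_deadline: float = 1.5  # s; slower responses become misses

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ValueError("n_participants must be >= 1")
        if self.trials_per_run < 1:
            raise ValueError("trials_per_run must be >= 1")
        if any(sd < 0 for sd in self.ddm_population_sds.values()):
            raise ValueError("population SDs must be nonnegative")
        if self.residual_sds is None:
            self.residual_sds = _default_residual_sds(
                self.latent_loadings, self.structural_paths, self.latent_corr)
        if any(sd < 0 for sd in self.residual_sds.values()):
            raise ValueError("residual SDs must be nonnegative")
        lc = self.latent_covariance()
        if np.linalg.eigvalsh(lc).min() <= 0:
            raise ValueError("latent covariance matrix is not positive definite")

    def latent_covariance(self) -> np.ndarray:
        return np.array([[1.0, self.latent_corr], [self.latent_corr, 1.0]])


def _coupling_weights(cfg: GeneratorConfig, name: str) -> np.ndarray:
    return np.array([
        cfg.ddm_latent_coupling.get((name, "SCC"), 0.0),
        cfg.ddm_latent_coupling.get((name, "SCB"), 0.0),
    ])


def implied_param_latent_correlation(cfg: GeneratorConfig, name: str,
                                     latent: str) -> float:
    """Correlation between a DDM parameter and a latent implied by the config."""
    c = _coupling_weights(cfg, name)
    R = cfg.latent_covariance()
    var = c @ R @ c
    if var > 1:
        raise ValueError(f"couplings for {name} imply variance share > 1")
    idx = 0 if latent == "SCC" else 1
    return float((R @ c)[idx])


def generate_participant_params(cfg: GeneratorConfig) -> pd.DataFrame:
    """Draw per-participant latent traits and true DDM parameters per condition.

    Returns one row per participant with columns ``participant_id``, ``SCC``,
    ``SCB`` and ``<param>_<condition>`` for the five DDM parameters in both
    conditions.  Parameters violating the support constraints
    (``a > 0.2``, ``t0 - st0/2 > 0.05``) are redrawn up to 1000 times and then
    clipped.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_participants
    latents = rng.multivariate_normal([0.0, 0.0], cfg.latent_covariance(), size=n,
                                      method="cholesky")

    rows = {"participant_id": [f"P{i + 1:04d}" for i in range(n)],
            "SCC": latents[:, 0], "SCB": latents[:, 1]}
    rho = cfg.ddm_cross_condition_corr
    resid_cov = np.array([[1.0, rho], [rho, 1.0]])
    for name in DDM_PARAM_NAMES:
        c = _coupling_weights(cfg, name)
        shared_var = float(c @ cfg.latent_covariance() @ c)
        if shared_var > 1:
            raise ValueError(f"couplings for {name} imply variance share > 1")
        resid_sd = np.sqrt(1.0 - shared_var)
        shared = latents @ c  # standardized latent contribution
        eps = rng.multivariate_normal([0.0, 0.0], resid_cov, size=n,
                                      method="cholesky")
        for j, cond in enumerate(CONDITIONS):
            mu = cfg.ddm_population_means[cond][name]
            sd = cfg.ddm_population_sds[name]
            rows[f"{name}_{cond}"] = mu + sd * (shared + resid_sd * eps[:, j])

    df = pd.DataFrame(rows)
    _enforce_validity(df, cfg, rng)
    return df


def _enforce_validity(df: pd.DataFrame, cfg: GeneratorConfig,
                      rng: np.random.Generator) -> None:
    """Redraw (up to 1000 times), then clip, parameters outside their support."""
    for cond in CONDITIONS:
        a = df[f"a_{cond}"].to_numpy()
        t0 = df[f"t0_{cond}"].to_numpy()
        st0 = df[f"st0_{cond}"].to_numpy()
        sv = df[f"sv_{cond}"].to_numpy()
        mu = cfg.ddm_population_means[cond]
        sds = cfg.ddm_population_sds
        bad = _invalid_mask(a, t0, st0, sv)
        for _ in range(1000):
            if not bad.any():
                break
            k = int(bad.sum())
            a[bad] = mu["a"] + sds["a"] * rng.standard_normal(k)
            t0[bad] = mu["t0"] + sds["t0"] * rng.standard_normal(k)
            st0[bad] = mu["st0"] + sds["st0"] * rng.standard_normal(k)
            sv[bad] = mu["sv"] + sds["sv"] * rng.standard_normal(k)
            bad = _invalid_mask(a, t0, st0, sv)
        if bad.any():
            a[bad] = np.maximum(a[bad], 0.2 + 1e-6)
            st0[bad] = np.clip(st0[bad], 0.0, None)
            sv[bad] = np.clip(sv[bad], 0.0, None)
            t0[bad] = np.maximum(t0[bad], 0.05 + st0[bad] / 2 + 1e-6)
        df[f"a_{cond}"] = a
        df[f"t0_{cond}"] = t0
        df[f"st0_{cond}"] = st0
        df[f"sv_{cond}"] = sv


def _invalid_mask(a, t0, st0, sv):
    return (a <= 0.2) | (st0 < 0) | (sv < 0) | (t0 - st0 / 2 <= 0.05)


def generate_trials(params: DDMParams, n: int, seed: int,
                    participant_id: str = "P0001", condition: str = "baseline",
                    response_deadline: float | None = None) -> pd.DataFrame:
    """Simulate one participant-condition block of dot-probe trials.

    Reaction times come from the exact-bridge diffusion simulator; responses
    slower than ``response_deadline`` (if given) are recorded as misses
    (``response = "none"``, rt missing).  ``trial_index`` is 1-based.
    """
    rt, correct = simulate_trials(params, n, seed)
    resp = np.where(correct == 1, "correct", "incorrect").astype(object)
    rt = rt.copy()
    if response_deadline is not None:
        late = rt > response_deadline
        resp[late] = "none"
        rt[late] = np.nan
    return pd.DataFrame({
        "participant_id": participant_id,
        "condition": condition,
        "trial_index": np.arange(1, n + 1),
        "rt": rt,
        "response": resp,
    })


def _study_trials(cfg: GeneratorConfig, params: pd.DataFrame) -> pd.DataFrame:
    blocks = []
    ss = np.random.SeedSequence([cfg.seed, 7919])
    seeds = ss.generate_state(len(params) * 2)
    k = 0
    for _, row in params.iterrows():
        for cond in CONDITIONS:
            p = DDMParams(v=row[f"v_{cond}"], a=row[f"a_{cond}"],
                          t0=row[f"t0_{cond}"], st0=row[f"st0_{cond}"],
                          sv=row[f"sv_{cond}"])
            blocks.append(generate_trials(
                p, cfg.trials_per_run, int(seeds[k] % (2**31 - 1)),
                participant_id=row["participant_id"], condition=cond,
                response_deadline=cfg.response_deadline))
            k += 1
    return pd.concat(blocks, ignore_index=True)


def generate_scores(cfg: GeneratorConfig, participant_params: pd.DataFrame,
                    items: bool = False):
    """Generate the participant-level score table (and optional item matrices).

    Indicators are ``loading x latent + N(0, residual_sd)``.  PSI and OSI are
    built on a standardized scale from the structural paths (latents and, if
    configured, standardized baseline-condition DDM parameters) plus residuals
    with correlation ``outcome_residual_corr``; they are then mapped linearly
    onto the questionnaire total scales (UCLA-R-like 20-80, reversed-SNS-like
    0-30).  With ``items=True``, item-level matrices are generated from a
    one-factor model per questionnaire with the outcome's standardized score
    as the factor.
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 104729]))
    n = len(participant_params)
    out = {"participant_id": participant_params["participant_id"].to_numpy()}

    missing = [ind for ind in SCC_INDICATORS + SCB_INDICATORS
               if ind not in cfg.latent_loadings]
    if missing:
        raise KeyError(f"no loading configured for indicator(s): {missing}")

    latents = {"SCC": participant_params["SCC"].to_numpy(),
               "SCB": participant_params["SCB"].to_numpy()}
    for ind, lam in cfg.latent_loadings.items():
        target = "SCC" if ind in SCC_INDICATORS else "SCB"
        out[ind] = lam * latents[target] + cfg.residual_sds[ind] * \
            rng.standard_normal(n)

    # standardized DDM predictor values, available to structural paths
    zddm = {}
    for cond in CONDITIONS:
        for name in ("t0", "v"):
            col = participant_params[f"{name}_{cond}"].to_numpy()
            mu = cfg.ddm_population_means[cond][name]
            sd = cfg.ddm_population_sds[name]
            zddm[(name, cond)] = (col - mu) / sd if sd > 0 else col - mu

    rho = cfg.outcome_residual_corr
    eps = rng.multivariate_normal([0.0, 0.0],
                                  [[1.0, rho], [rho, 1.0]], size=n,
                                  method="cholesky")
    z_outcome = {}
    for j, outcome in enumerate(("PSI", "OSI")):
        y = cfg.residual_sds[outcome] * eps[:, j]
        for (pred, out_name), beta in cfg.structural_paths.items():
            if out_name != outcome or beta == 0.0:
                continue
            if pred in latents:
                y = y + beta * latents[pred]
            else:  # DDM predictor: baseline-condition standardized value
                y = y + beta * zddm[(pred, "baseline")]
        z_outcome[outcome] = y

    out["PSI"] = 50.0 + 10.0 * z_outcome["PSI"]   # UCLA-R-like total scale
    out["OSI"] = 15.0 + 4.0 * z_outcome["OSI"]    # reversed-SNS-like scale

    for cond in CONDITIONS:
        for name in ("t0", "v"):
            out[f"{name}_{cond}"] = participant_params[f"{name}_{cond}"].to_numpy()

    scores = pd.DataFrame(out)
    if not items:
        return scores

    item_frames = {}
    for outcome, (n_items, lam, prefix) in {
            "PSI": (20, _UCLA_ITEM_LOADING, "ucla"),
            "OSI": (6, _SNS_ITEM_LOADING, "sns")}.items():
        factor = z_outcome[outcome]
        resid = np.sqrt(1 - lam**2) * rng.standard_normal((n, n_items))
        mat = lam * factor[:, None] + resid
        item_frames[prefix] = pd.DataFrame(
            mat, columns=[f"{prefix}_{i + 1:02d}" for i in range(n_items)])
    return scores, item_frames


def generate_study(cfg: GeneratorConfig, items: bool = False) -> dict:
    """Generate a complete synthetic study.

    Returns a dict with ``truth`` (participant table with generating values),
    ``trials`` (trial-level data) and ``scores`` (participant-level score
    table); with ``items=True`` also ``items`` (item-level matrices).
    """
    truth = generate_participant_params(cfg)
    trials = _study_trials(cfg, truth)
    res = generate_scores(cfg, truth, items=items)
    if items:
        scores, item_frames = res
        return {"truth": truth, "trials": trials, "scores": scores,
                "items": item_frames}
    return {"truth": truth, "trials": trials, "scores": res}
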