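"""Structural equation models: specification, ML estimation, indirect effects.

Models are declared as a measurement part (latents with >= 2 indicators each,
first loading fixed to 1 for identification), structural regressions among
latent and observed variables, and free (residual or exogenous) covariances.
Estimation minimizes the maximum-likelihood discrepancy

    F(theta) = log|Sigma(theta)| + tr(S Sigma(theta)^-1) - log|S| - p

over the free parameters, where ``Sigma(theta)`` is the model-implied
covariance of the p observed variables computed from the RAM representation
``Sigma = F (I - A)^-1 S_res (I - A)^-T F'``.  The chi-square statistic is
``(n - 1) F`` at the minimum (Wishart convention), RMSEA and CFI follow their
standard definitions with the independence baseline, standard errors come
from the inverse expected information, and indirect effects use the
product-of-coefficients estimate with a delta-method standard error.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import minimize

__all__ = ["SemModelSpec", "SemFit", "count_df", "fit_ml", "indirect_effects",
           "detect_suppression", "product_delta_se",
           "overt_two_factor_model", "extended_ddm_model"]


@dataclass
class SemModelSpec:
    """Declarative path-model structure.

    ``latents`` maps each latent name to its indicator list; ``regressions``
    is a list of ``(outcome, predictor)`` pairs; ``covariances`` lists free
    covariance pairs (between residuals of endogenous variables or between
    exogenous variables); ``observed_exogenous`` names observed variables that
    only ever act as predictors.
    """

    latents: dict = field(default_factory=dict)
    regressions: list = field(default_factory=list)
    covariances: list = field(default_factory=list)
    observed_exogenous: list = field(default_factory=list)

    def __post_init__(self) -> None:
        for lat, inds in self.latents.items():
            if len(inds) < 2:
                raise ValueError(f"latent {lat} needs >= 2 indicators")

    @property
    def observed(self) -> list:
        """Observed variables in canonical order: indicators, endogenous, exogenous."""
        seen = []
        for inds in self.latents.values():
            seen.extend(inds)
        for out, pred in self.regressions:
            for v in (out, pred):
                if v not in seen and v not in self.latents \
                        and v not in self.observed_exogenous:
                    seen.append(v)
        seen.extend(self.observed_exogenous)
        return seen

    @property
    def variables(self) -> list:
        return self.observed + list(self.latents)

    def free_parameters(self) -> list:
        """Names of free parameters: ``lhs=~rhs`` loadings, ``lhs~rhs``
        regressions, ``a~~b`` (co)variances.  Every variable gets a free
        (residual) variance; first loadings are fixed, not listed."""
        names = []
        for lat, inds in self.latents.items():
            names += [f"{lat}=~{ind}" for ind in inds[1:]]
        names += [f"{out}~{pred}" for out, pred in self.regressions]
        names += [f"{v}~~{v}" for v in self.variables]
        names += [f"{a}~~{b}" for a, b in self.covariances]
        return names


def count_df(spec: SemModelSpec, p: int | None = None) -> int:
    """Model degrees of freedom: ``p(p+1)/2`` sample moments minus free parameters."""
    if p is None:
        p = len(spec.observed)
    df = p * (p + 1) // 2 - len(spec.free_parameters())
    if df < 0:
        raise ValueError(f"model not identified: df = {df} < 0")
    return df


class _Ram:
    """Maps the free-parameter vector into RAM matrices A (paths) and S (covariances)."""

    def __init__(self, spec: SemModelSpec):
        self.spec = spec
        self.variables = spec.variables
        self.observed = spec.observed
        self.index = {v: i for i, v in enumerate(self.variables)}
        self.nv = len(self.variables)
        self.np_obs = len(self.observed)
        self.names = spec.free_parameters()
        self.a_slots, self.s_slots = [], []   # (param_idx, i, j)
        self.fixed_a = []                     # first loadings, value 1
        for lat, inds in spec.latents.items():
            self.fixed_a.append((self.index[inds[0]], self.index[lat]))
        for k, name in enumerate(self.names):
            if "=~" in name:
                lat, ind = name.split("=~")
                self.a_slots.append((k, self.index[ind], self.index[lat]))
            elif "~~" in name:
                a, b = name.split("~~")
                self.s_slots.append((k, self.index[a], self.index[b]))
            else:
                out, pred = name.split("~")
                self.a_slots.append((k, self.index[out], self.index[pred]))

    def matrices(self, theta):
        A = np.zeros((self.nv, self.nv))
        S = np.zeros((self.nv, self.nv))
        for i, j in self.fixed_a:
            A[i, j] = 1.0
        for k, i, j in self.a_slots:
            A[i, j] = theta[k]
        for k, i, j in self.s_slots:
            S[i, j] = theta[k]
            S[j, i] = theta[k]
        return A, S

    def full_covariance(self, theta):
        A, S = self.matrices(theta)
        ima_inv = np.linalg.inv(np.eye(self.nv) - A)
        return ima_inv @ S @ ima_inv.T

    def implied_sigma(self, theta):
        return self.full_covariance(theta)[:self.np_obs, :self.np_obs]

    def start_values(self, sample_cov):
        theta = np.zeros(len(self.names))
        obs_var = np.diag(sample_cov)
        first_ind = {lat: inds[0] for lat, inds in self.spec.latents.items()}
        for k, name in enumerate(self.names):
            if "=~" in name:
                theta[k] = 1.0
            elif "~~" in name:
                a, b = name.split("~~")
                if a == b:
                    if a in self.spec.latents:
                        j = self.observed.index(first_ind[a])
                        theta[k] = 0.5 * obs_var[j]
                    else:
                        theta[k] = 0.5 * obs_var[self.observed.index(a)]
        return theta


@dataclass
class SemFit:
    """Fitted model: parameter table, fit indices, and the pieces downstream
    computations (indirect effects, suppression reports) need."""

    spec: SemModelSpec
    params: pd.DataFrame          # name, estimate, se, z, p, std
    chi_square: float
    df: int
    p_value: float
    cfi: float
    rmsea: float
    r_squared: dict
    n: int
    fmin: float
    converged: bool
    warnings: list
    acov: np.ndarray              # asymptotic covariance of free parameters
    theta: np.ndarray
    _ram: _Ram

    def estimate(self, name: str, standardized: bool = False) -> float:
        row = self.params.loc[self.params["name"] == name]
        if row.empty:
            raise KeyError(f"no free parameter {name!r} in the model")
        return float(row["std" if standardized else "estimate"].iloc[0])

    def _pidx(self, name: str) -> int:
        if name not in self._ram.names:
            raise KeyError(f"no free parameter {name!r} in the model")
        return self._ram.names.index(name)

    def to_dict(self) -> dict:
        return {
            "chi_square": self.chi_square, "df": self.df,
            "p_value": self.p_value, "cfi": self.cfi, "rmsea": self.rmsea,
            "n": self.n, "converged": self.converged,
            "r_squared": dict(self.r_squared),
            "warnings": list(self.warnings),
            "parameters": self.params.drop(columns=[]).to_dict("records"),
        }


def _discrepancy(sigma, S, logdet_S, p):
    sign, logdet = np.linalg.slogdet(sigma)
    if sign <= 0:
        return None
    try:
        sinv_s = np.linalg.solve(sigma, S)
    except np.linalg.LinAlgError:
        return None
    return logdet + np.trace(sinv_s) - logdet_S - p


def product_delta_se(a: float, b: float, var_a: float, var_b: float,
                     cov_ab: float = 0.0) -> float:
    """Delta-method SE of the product ``a*b``:
    ``sqrt(b^2 Var(a) + a^2 Var(b) + 2ab Cov(a,b))``."""
    return math.sqrt(max(b * b * var_a + a * a * var_b + 2 * a * b * cov_ab,
                         0.0))


def fit_ml(spec: SemModelSpec, data: pd.DataFrame | None = None, *,
           sample_cov: np.ndarray | None = None, n: int | None = None,
           theta0: np.ndarray | None = None, max_iter: int = 2000) -> SemFit:
    """Fit a model by maximum likelihood.

    Either ``data`` (a DataFrame containing the observed columns; complete
    cases are used) or ``sample_cov`` together with ``n`` must be given.
    Optimization runs quasi-Newton (L-BFGS-B) from a deterministic start
    (loadings 1, paths 0, residual variances at half the observed variances)
    with an analytic gradient, then verifies the gradient norm.
    """
    ram = _Ram(spec)
    obs = spec.observed
    p = len(obs)
    if sample_cov is None:
        if data is None:
            raise ValueError("provide either data or sample_cov")
        rows = data[obs].dropna()
        n = len(rows)
        if n <= p:
            raise ValueError(f"need n > {p} complete cases, got {n}")
        S = np.cov(rows.to_numpy(dtype=float), rowvar=False, ddof=1)
    else:
        S = np.asarray(sample_cov, dtype=float)
        if n is None:
            raise ValueError("n is required with sample_cov")
    sign, logdet_S = np.linalg.slogdet(S)
    if sign <= 0:
        raise ValueError("sample covariance matrix is not positive definite")

    df = count_df(spec, p)

    # optimize in a unit-variance metric (ML is scale-equivariant); estimates
    # are mapped back to the raw metric afterwards.  Keeps the optimizer
    # well-conditioned when observed variances differ by orders of magnitude.
    scale = np.sqrt(np.diag(S))
    S_w = S / np.outer(scale, scale)
    sign_w, logdet_Sw = np.linalg.slogdet(S_w)

    # per-variable scale: observed = sample SD; latent = SD of its first
    # indicator (the fixed-1 loading ties the latent to that indicator)
    var_scale = {}
    for i, v in enumerate(obs):
        var_scale[v] = scale[i]
    for lat, inds in spec.latents.items():
        var_scale[lat] = scale[obs.index(inds[0])]

    def _to_raw(theta_w):
        out = theta_w.copy()
        for k, name in enumerate(ram.names):
            if "=~" in name:
                lat, ind = name.split("=~")
                out[k] = theta_w[k] * var_scale[ind] / var_scale[lat]
            elif "~~" in name:
                a, b = name.split("~~")
                out[k] = theta_w[k] * var_scale[a] * var_scale[b]
            else:
                o_, pr = name.split("~")
                out[k] = theta_w[k] * var_scale[o_] / var_scale[pr]
        return out

    def _to_scaled(theta_raw):
        out = theta_raw.copy()
        for k, name in enumerate(ram.names):
            if "=~" in name:
                lat, ind = name.split("=~")
                out[k] = theta_raw[k] * var_scale[lat] / var_scale[ind]
            elif "~~" in name:
                a, b = name.split("~~")
                out[k] = theta_raw[k] / (var_scale[a] * var_scale[b])
            else:
                o_, pr = name.split("~")
                out[k] = theta_raw[k] * var_scale[pr] / var_scale[o_]
        return out

    def objective(theta):
        f = _discrepancy(ram.implied_sigma(theta), S_w, logdet_Sw, p)
        if f is None or not np.isfinite(f):
            return 1e10
        return f

    def gradient(theta):
        sigma = ram.implied_sigma(theta)
        try:
            sigma_inv = np.linalg.inv(sigma)
        except np.linalg.LinAlgError:
            return np.zeros_like(theta)
        M = sigma_inv - sigma_inv @ S_w @ sigma_inv
        g = np.empty_like(theta)
        h = 1e-6
        for k in range(theta.size):
            tp = theta.copy(); tp[k] += h
            tm = theta.copy(); tm[k] -= h
            dsig = (ram.implied_sigma(tp) - ram.implied_sigma(tm)) / (2 * h)
            g[k] = np.sum(M * dsig)   # tr(M dSigma): Sigma derivative is exact-linear here
        return g

    starts = []
    if theta0 is not None:
        starts.append(_to_scaled(np.asarray(theta0, dtype=float)))
    starts.append(ram.start_values(S_w))   # deterministic default start

    res, gnorm, converged = None, np.inf, False
    for s0 in starts:
        cand = minimize(objective, s0, jac=gradient, method="L-BFGS-B",
                        options={"maxiter": max_iter, "ftol": 1e-14,
                                 "gtol": 1e-9})
        # polish: restart once from the solution (helps tight curvature ridges)
        cand2 = minimize(objective, cand.x, jac=gradient, method="L-BFGS-B",
                         options={"maxiter": max_iter, "ftol": 1e-15,
                                  "gtol": 1e-10})
        if cand2.fun <= cand.fun:
            cand = cand2
        g = float(np.max(np.abs(gradient(cand.x))))
        if res is None or cand.fun < res.fun:
            res, gnorm = cand, g
        if cand.success or g < 1e-4:
            res, gnorm, converged = cand, g, True
            break
    if not converged:
        raise RuntimeError(
            f"SEM optimization did not converge (gradient max-norm {gnorm:.2e})")
    theta_w = res.x
    fmin = float(res.fun)
    theta = _to_raw(theta_w)

    warnings_ = []
    for k, name in enumerate(ram.names):
        if "~~" in name:
            a, b = name.split("~~")
            if a == b and theta[k] < 0:
                warnings_.append(f"Heywood case: negative variance for {a} "
                                 f"({theta[k]:.4f})")

    # fit indices
    chi2 = (n - 1) * fmin
    p_value = float(stats.chi2.sf(chi2, df)) if df > 0 else 1.0
    rmsea = math.sqrt(max(chi2 - df, 0.0) / (df * (n - 1))) if df > 0 else 0.0
    d = np.sqrt(np.diag(S))
    corr = S / np.outer(d, d)
    f_base = -np.linalg.slogdet(corr)[1]
    chi2_base = (n - 1) * f_base
    df_base = p * (p - 1) // 2
    denom = max(chi2_base - df_base, chi2 - df, 0.0)
    cfi = 1.0 - max(chi2 - df, 0.0) / denom if denom > 0 else 1.0

    # standard errors from the inverse expected information
    sigma = ram.implied_sigma(theta)
    sigma_inv = np.linalg.inv(sigma)
    h = 1e-6
    dsigs = []
    for k in range(theta.size):
        tp = theta.copy(); tp[k] += h
        tm = theta.copy(); tm[k] -= h
        dsigs.append((ram.implied_sigma(tp) - ram.implied_sigma(tm)) / (2 * h))
    info = np.empty((theta.size, theta.size))
    for i_ in range(theta.size):
        si = sigma_inv @ dsigs[i_]
        for j_ in range(i_, theta.size):
            info[i_, j_] = info[j_, i_] = \
                0.5 * (n - 1) * np.sum(si.T * (sigma_inv @ dsigs[j_]))
    try:
        acov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        acov = np.linalg.pinv(info)
        warnings_.append("information matrix singular; SEs use pseudo-inverse")
    se = np.sqrt(np.clip(np.diag(acov), 0, None))

    # standardized solution from the full model-implied covariance
    C = ram.full_covariance(theta)
    sds = np.sqrt(np.clip(np.diag(C), 1e-300, None))
    std = np.empty_like(theta)
    for k, name in enumerate(ram.names):
        if "=~" in name:
            lat, ind = name.split("=~")
            i, j = ram.index[ind], ram.index[lat]
            std[k] = theta[k] * sds[j] / sds[i]
        elif "~~" in name:
            a, b = name.split("~~")
            i, j = ram.index[a], ram.index[b]
            std[k] = theta[k] / (sds[i] * sds[j])
        else:
            out, pred = name.split("~")
            i, j = ram.index[out], ram.index[pred]
            std[k] = theta[k] * sds[j] / sds[i]

    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, theta / se, np.nan)
    pvals = 2 * stats.norm.sf(np.abs(z))
    params = pd.DataFrame({
        "name": ram.names, "estimate": theta, "se": se, "z": z, "p": pvals,
        "std": std,
    })

    # R^2 for endogenous variables: 1 - standardized residual variance
    endo = {out for out, _ in spec.regressions}
    r_squared = {}
    for v in endo:
        i = ram.index[v]
        Avar, Svar = ram.matrices(theta)
        r_squared[v] = float(1.0 - Svar[i, i] / C[i, i])

    return SemFit(spec=spec, params=params, chi_square=float(chi2), df=df,
                  p_value=p_value, cfi=float(cfi), rmsea=float(rmsea),
                  r_squared=r_squared, n=int(n), fmin=fmin,
                  converged=converged, warnings=warnings_, acov=acov,
                  theta=theta, _ram=ram)


def indirect_effects(fit: SemFit, paths) -> pd.DataFrame:
    """Product-of-coefficients indirect effects with delta-method SEs.

    ``paths`` is a list of ``(predictor, mediator, outcome)`` triples; both
    segments must be free regression parameters of the fitted model.  Returns
    a DataFrame with unstandardized and standardized estimates, SE, z and
    two-sided p (from the unstandardized solution).
    """
    rows = []
    for pred, med, out in paths:
        name_a = f"{med}~{pred}"
        name_b = f"{out}~{med}"
        ia, ib = fit._pidx(name_a), fit._pidx(name_b)
        a, b = fit.theta[ia], fit.theta[ib]
        var_a, var_b = fit.acov[ia, ia], fit.acov[ib, ib]
        cov_ab = fit.acov[ia, ib]
        est = a * b
        se = product_delta_se(a, b, var_a, var_b, cov_ab)
        z = est / se if se > 0 else np.nan
        pval = 2 * stats.norm.sf(abs(z)) if np.isfinite(z) else np.nan
        rows.append({
            "predictor": pred, "mediator": med, "outcome": out,
            "estimate": est, "se": se, "z": z, "p": pval,
            "std": fit.estimate(name_a, standardized=True)
                   * fit.estimate(name_b, standardized=True),
        })
    return pd.DataFrame(rows)


def detect_suppression(fit: SemFit, predictor: str, outcome: str,
                       mediator: str, alpha: float = 0.05) -> dict:
    """Flag a suppression pattern on a predictor -> outcome relation.

    Suppression is reported when the direct path and the indirect path through
    ``mediator`` have opposite signs and both are significant at ``alpha``.
    """
    direct_name = f"{outcome}~{predictor}"
    idx = fit._pidx(direct_name)
    direct = float(fit.theta[idx])
    direct_p = float(fit.params.loc[fit.params["name"] == direct_name, "p"].iloc[0])
    ind = indirect_effects(fit, [(predictor, mediator, outcome)]).iloc[0]

    opposite = np.sign(direct) == -np.sign(ind["estimate"]) \
        and direct != 0 and ind["estimate"] != 0
    both_sig = direct_p < alpha and ind["p"] < alpha
    suppression = bool(opposite and both_sig)
    reason = None
    if not opposite:
        reason = "direct and indirect effects share the same sign"
    elif not both_sig:
        reason = "direct and/or indirect effect not significant"
    return {
        "suppression": suppression, "reason": reason,
        "direct": direct, "direct_p": direct_p,
        "indirect": float(ind["estimate"]), "indirect_p": float(ind["p"]),
        "total": direct + float(ind["estimate"]),
    }


SCC_INDICATORS = ["MiniPONS", "PENN_ER40", "RMET", "Hinting"]
SCB_INDICATORS = ["DACOBS_AB", "AIHQ_BS"]


def overt_two_factor_model() -> SemModelSpec:
    """Two correlated latents (SCC, SCB) regressed onto observed PSI and OSI,
    with a PSI-OSI residual covariance; 8 observed variables, 16 df."""
    return SemModelSpec(
        latents={"SCC": list(SCC_INDICATORS), "SCB": list(SCB_INDICATORS)},
        regressions=[("PSI", "SCC"), ("PSI", "SCB"),
                     ("OSI", "SCC"), ("OSI", "SCB")],
        covariances=[("SCC", "SCB"), ("PSI", "OSI")],
    )


def extended_ddm_model(t0: str = "t0", v: str = "v") -> SemModelSpec:
    """The overt model extended with correlated observed exogenous diffusion
    parameters (nondecision time and drift rate), each predicting SCC, SCB,
    PSI and OSI; 10 observed variables, 24 df."""
    base = overt_two_factor_model()
    regressions = base.regressions + [
        (out, pred) for pred in (t0, v) for out in ("SCC", "SCB", "PSI", "OSI")]
    return SemModelSpec(
        latents=base.latents,
        regressions=regressions,
        covariances=base.covariances + [(t0, v)],
        observed_exogenous=[t0, v],
    )
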