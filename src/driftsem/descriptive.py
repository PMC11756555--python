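"""Descriptive statistics: correlations, condition contrasts, reliability, power.

Covers the participant-level analyses that sit around the latent-variable
models: zero-order Pearson correlations with two-sided p-values, paired
t-tests between task conditions, Cronbach's alpha for questionnaire item
matrices, and the Fisher-z power analysis for a Pearson correlation.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import brentq

__all__ = ["zero_order_correlations", "paired_t", "cronbach_alpha",
           "power_correlation", "solve_r"]

SCORE_COLUMNS = ["PENN_ER40", "MiniPONS", "RMET", "Hinting", "AIHQ_BS",
                 "DACOBS_AB", "PSI", "OSI",
                 "t0_baseline", "t0_angry", "v_baseline", "v_angry"]


def zero_order_correlations(table: pd.DataFrame, columns=None):
    """Pairwise Pearson correlations with two-sided p-values.

    Complete-case deletion is applied per pair.  Returns ``(r, p)`` DataFrames;
    pairs involving a zero-variance column get NaN entries.
    Requires at least 4 complete rows per pair.
    """
    if columns is None:
        columns = [c for c in SCORE_COLUMNS if c in table.columns]
    k = len(columns)
    r = pd.DataFrame(np.eye(k), index=columns, columns=columns)
    p = pd.DataFrame(np.zeros((k, k)), index=columns, columns=columns)
    for i in range(k):
        for j in range(i + 1, k):
            pair = table[[columns[i], columns[j]]].dropna()
            if len(pair) < 4:
                raise ValueError(
                    f"need >= 4 complete rows for {columns[i]} vs {columns[j]}")
            x, y = pair.iloc[:, 0], pair.iloc[:, 1]
            if x.std() == 0 or y.std() == 0:
                rij, pij = np.nan, np.nan
            else:
                res = stats.pearsonr(x, y)
                rij, pij = res.statistic, res.pvalue
            r.iloc[i, j] = r.iloc[j, i] = rij
            p.iloc[i, j] = p.iloc[j, i] = pij
    return r, p


def paired_t(x, y) -> dict:
    """Paired-samples t-test (two-sided).

    ``t = mean(d) / (sd(d)/sqrt(n))`` with ``d = x - y`` and ``df = n - 1``.
    Raises on zero variance of the differences (the t statistic is undefined
    or infinite there).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-d vectors")
    n = x.shape[0]
    if n < 2:
        raise ValueError("need at least 2 pairs")
    d = x - y
    sd_d = d.std(ddof=1)
    if sd_d == 0:
        if d.mean() == 0:   # identical vectors: no effect, no evidence
            t, pval = 0.0, 1.0
        else:
            raise ValueError("zero variance of nonzero differences: "
                             "t is infinite")
    else:
        t = d.mean() / (sd_d / math.sqrt(n))
        pval = 2 * stats.t.sf(abs(t), n - 1)
    return {"t": float(t), "df": n - 1, "p": float(pval),
            "mean_x": float(x.mean()), "mean_y": float(y.mean()),
            "sd_x": float(x.std(ddof=1)), "sd_y": float(y.std(ddof=1))}


def cronbach_alpha(items) -> float:
    """Cronbach's alpha of a participants x items matrix.

    ``alpha = k/(k-1) * (1 - sum(item variances) / var(total))`` with
    unbiased (n-1) sample variances and complete cases only.
    """
    x = np.asarray(items, dtype=float)
    if x.ndim != 2:
        raise ValueError("items must be a 2-d matrix")
    x = x[~np.isnan(x).any(axis=1)]
    n, k = x.shape
    if k < 2 or n < 3:
        raise ValueError("need >= 2 items and >= 3 complete rows")
    total_var = x.sum(axis=1).var(ddof=1)
    if total_var <= 0:
        raise ValueError("zero total-score variance: alpha undefined")
    item_var = x.var(axis=0, ddof=1).sum()
    return float(k / (k - 1) * (1 - item_var / total_var))


def power_correlation(n: int, r: float, alpha: float = 0.05,
                      tail: str = "two") -> float:
    """Power to detect a Pearson correlation ``r`` at sample size ``n``.

    Fisher-z approximation: ``power = Phi(atanh(|r|) sqrt(n-3) - z_crit)``
    with ``z_crit`` the (two- or one-sided) normal critical value; the
    vanishing opposite-tail rejection mass is ignored.
    """
    if n <= 3:
        raise ValueError("n must exceed 3")
    if not (0 < abs(r) < 1):
        raise ValueError("r must lie strictly between 0 and 1 in magnitude")
    if not (0 < alpha < 1):
        raise ValueError("alpha must lie in (0, 1)")
    zcrit = stats.norm.ppf(1 - alpha / 2) if tail == "two" \
        else stats.norm.ppf(1 - alpha)
    return float(stats.norm.cdf(math.atanh(abs(r)) * math.sqrt(n - 3) - zcrit))


def solve_r(n: int, power: float = 0.80, alpha: float = 0.05,
            tail: str = "two") -> float:
    """Smallest correlation detectable with the given power (inverse of above)."""
    if not (0 < power < 1):
        raise ValueError("power must lie in (0, 1)")
    hi = 1 - 1e-12
    if power_correlation(n, hi, alpha, tail) < power:
        raise ValueError("requested power unattainable at this n")
    return float(brentq(
        lambda r: power_correlation(n, r, alpha, tail) - power, 1e-12, hi,
        xtol=1e-12))
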