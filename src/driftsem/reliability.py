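"""Odd-even split-half reliability of diffusion-model point estimates.

Trials are split by the parity of their original (pre-filter) 1-based
``trial_index`` within each participant x condition, the model is fitted to
each half, and agreement between the two half-estimates is summarized by
ICC(2,1): the two-way random-effects, single-measure, absolute-agreement
intraclass correlation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .demcmc import SamplerConfig, fit_participants

__all__ = ["SplitHalfResult", "split_odd_even", "icc_2_1", "split_half_icc"]


def split_odd_even(trials: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Partition trials by parity of ``trial_index`` (odd half, even half).

    Parity refers to the original presentation index, so gaps left by
    filtering do not shift trials between halves; the two halves partition the
    input exactly.
    """
    odd_mask = trials["trial_index"] % 2 == 1
    return trials[odd_mask].copy(), trials[~odd_mask].copy()


def icc_2_1(matrix) -> float:
    """ICC(2,1) for an n x k matrix of targets by raters/halves.

    Two-way random effects, single measure, absolute agreement:

        ICC(2,1) = (MSR - MSE) / (MSR + (k-1) MSE + (k/n)(MSC - MSE))

    from the two-way ANOVA decomposition (MSR rows, MSC columns, MSE
    residual).  Requires >= 3 rows, >= 2 columns, no missing cells.
    """
    x = np.asarray(matrix, dtype=float)
    if x.ndim != 2:
        raise ValueError("matrix must be 2-dimensional")
    n, k = x.shape
    if n < 3 or k < 2:
        raise ValueError("need at least 3 rows and 2 columns")
    if not np.all(np.isfinite(x)):
        raise ValueError("missing cells are not supported")

    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_total = ((x - grand) ** 2).sum()
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    if ss_total <= 0:
        raise ValueError("zero total variance: ICC undefined")

    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    return float((msr - mse) / (msr + (k - 1) * mse + k / n * (msc - mse)))


@dataclass
class SplitHalfResult:
    """Half-wise DDM estimates and their ICC(2,1) per parameter x condition."""

    odd_estimates: pd.DataFrame
    even_estimates: pd.DataFrame
    icc: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {f"{param}_{cond}": val for (param, cond), val in self.icc.items()}


def split_half_icc(trials: pd.DataFrame, cfg: SamplerConfig,
                   params: tuple = ("v", "t0"),
                   progress: bool = False) -> SplitHalfResult:
    """Fit odd and even halves separately and compute ICC(2,1) per parameter.

    ``trials`` should already be cleaned; the split uses original trial
    indices.  Half-fits reuse ``cfg`` as given (callers may pass a reduced
    iteration budget for desk-scale runtimes).
    """
    import dataclasses

    odd, even = split_odd_even(trials)
    odd_cfg = dataclasses.replace(cfg, seed=cfg.seed * 2 + 1)
    even_cfg = dataclasses.replace(cfg, seed=cfg.seed * 2 + 2)
    est_odd, _ = fit_participants(odd, odd_cfg, progress=progress)
    est_even, _ = fit_participants(even, even_cfg, progress=progress)

    merged = est_odd.merge(est_even, on="participant_id",
                           suffixes=("_odd", "_even"))
    result = SplitHalfResult(odd_estimates=est_odd, even_estimates=est_even)
    for cond in ("baseline", "angry"):
        if f"v_{cond}_odd" not in merged.columns:
            continue
        for param in params:
            mat = merged[[f"{param}_{cond}_odd", f"{param}_{cond}_even"]]
            result.icc[(param, cond)] = icc_2_1(mat.to_numpy())
    return result
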