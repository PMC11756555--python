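"""Trial- and participant-level exclusion rules for dot-probe reaction-time data.

Trials are pandas DataFrames with columns:

- ``participant_id``: identifier
- ``condition``: ``"baseline"`` (run 1, neutral-neutral) or ``"angry"``
  (run 2, neutral-angry)
- ``trial_index``: 1-based index within participant x condition, assigned at
  presentation time (before any filtering)
- ``rt``: reaction time in seconds; NaN iff no response
- ``response``: ``"correct"``, ``"incorrect"`` or ``"none"``

Cleaning applies three rules in order, in a single pass per participant x
condition: drop non-responses, drop responses faster than 200 ms, then drop
reaction times outside mean +/- 2 SD, where mean and SD are computed on the
trials surviving the first two rules.  The 2-SD window is closed (values
exactly on the boundary are retained).  Participants who responded on fewer
than 50% of all presented trials (both runs pooled) are excluded entirely;
exactly 50% is retained.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "PreprocessReport",
    "filter_trials",
    "exclude_participants",
    "response_rates",
    "FAST_RT_CUTOFF",
    "MIN_RESPONSE_RATE",
]

FAST_RT_CUTOFF = 0.200  # seconds
MIN_RESPONSE_RATE = 0.50
SD_WINDOW = 2.0

TRIAL_COLUMNS = ["participant_id", "condition", "trial_index", "rt", "response"]


@dataclass
class PreprocessReport:
    """Per participant x condition exclusion accounting.

    ``counts`` maps ``(participant_id, condition)`` to a dict with keys
    ``n_input``, ``n_no_response``, ``n_fast``, ``n_outlier``, ``n_retained``;
    the four exclusion categories always sum to ``n_input``.
    """

    counts: dict = field(default_factory=dict)
    excluded_participants: list = field(default_factory=list)

    def total(self, key: str) -> int:
        return int(sum(c[key] for c in self.counts.values()))

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"participant_id": pid, "condition": cond, **c}
            for (pid, cond), c in self.counts.items()
        ]
        return pd.DataFrame(
            rows,
            columns=["participant_id", "condition", "n_input", "n_no_response",
                     "n_fast", "n_outlier", "n_retained"],
        )

    def to_dict(self) -> dict:
        return {
            "per_cell": [
                {"participant_id": str(pid), "condition": cond, **c}
                for (pid, cond), c in self.counts.items()
            ],
            "excluded_participants": [str(p) for p in self.excluded_participants],
            "totals": {
                k: self.total(k)
                for k in ("n_input", "n_no_response", "n_fast", "n_outlier",
                          "n_retained")
            },
        }


def filter_trials(trials: pd.DataFrame) -> tuple[pd.DataFrame, PreprocessReport]:
    """Apply the three trial-level exclusion rules.

    Returns the retained trials (original rows and order preserved) and a
    :class:`PreprocessReport`.  Empty input yields an empty frame and an empty
    report.
    """
    report = PreprocessReport()
    if len(trials) == 0:
        return trials.copy(), report

    keep_masks = []
    for (pid, cond), grp in trials.groupby(["participant_id", "condition"], sort=False):
        rt = grp["rt"].to_numpy(dtype=float)
        responded = grp["response"].to_numpy() != "none"
        no_resp = ~responded
        fast = responded & (rt < FAST_RT_CUTOFF)
        candidate = responded & ~fast
        n_cand = int(candidate.sum())
        if n_cand > 0:
            m = rt[candidate].mean()
            sd = rt[candidate].std(ddof=1) if n_cand > 1 else 0.0
            lo, hi = m - SD_WINDOW * sd, m + SD_WINDOW * sd
            outlier = candidate & ((rt < lo) | (rt > hi))
        else:
            outlier = np.zeros(len(grp), dtype=bool)
        retained = candidate & ~outlier
        report.counts[(pid, cond)] = {
            "n_input": len(grp),
            "n_no_response": int(no_resp.sum()),
            "n_fast": int(fast.sum()),
            "n_outlier": int(outlier.sum()),
            "n_retained": int(retained.sum()),
        }
        keep_masks.append(pd.Series(retained, index=grp.index))

    keep = pd.concat(keep_masks).reindex(trials.index, fill_value=False)
    return trials.loc[keep].copy(), report


def response_rates(trials: pd.DataFrame) -> pd.Series:
    """Proportion of presented trials with any response, per participant (runs pooled)."""
    responded = trials["response"] != "none"
    return responded.groupby(trials["participant_id"]).mean()


def exclude_participants(
    trials: pd.DataFrame, report: PreprocessReport | None = None
) -> tuple[pd.DataFrame, PreprocessReport]:
    """Drop participants whose overall response rate is strictly below 50%.

    ``trials`` must be the raw (pre-filter) table: the response rate is defined
    over all presented trials across both runs.  The returned report carries
    the excluded participant ids (merged into ``report`` if one is given).
    """
    if report is None:
        report = PreprocessReport()
    if len(trials) == 0:
        return trials.copy(), report
    rates = response_rates(trials)
    bad = rates.index[rates < MIN_RESPONSE_RATE].tolist()
    report.excluded_participants = sorted(set(report.excluded_participants) | set(bad),
                                          key=str)
    out = trials[~trials["participant_id"].isin(bad)].copy()
    return out, report


def load_trials_csv(path) -> pd.DataFrame:
    """Read a trial CSV (rt in milliseconds) into the internal schema (rt in seconds)."""
    df = pd.read_csv(path)
    df = df.rename(columns={"run": "condition", "rt_ms": "rt"})
    df["rt"] = df["rt"] / 1000.0
    df.loc[df["response"] == "none", "rt"] = np.nan
    return df[TRIAL_COLUMNS]


def write_trials_csv(trials: pd.DataFrame, path) -> None:
    """Write trials to CSV with rt in milliseconds (column ``rt_ms``)."""
    out = trials.rename(columns={"condition": "run", "rt": "rt_ms"}).copy()
    out["rt_ms"] = (out["rt_ms"] * 1000.0).round(4)
    out.to_csv(path, index=False)
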