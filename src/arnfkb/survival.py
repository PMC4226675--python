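"""Kaplan-Meier curves and two-group log-rank tests on signature-defined groups.

Survival records are a DataFrame with columns ``sample_id``, ``time``
(months, > 0), ``event`` (1 = death/progression, 0 = censored) and
``group``.  Estimation and testing are delegated to lifelines; this
module adds the grouping rules, the follow-up-horizon truncation
(records beyond the horizon are administratively censored at it) and the
degenerate-input checks.  Censored subjects at a tied time remain at risk
for events at that time (the standard convention lifelines implements).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank

from .containers import SignatureScores

REQUIRED_COLS = ("sample_id", "time", "event", "group")


@dataclass
class LogRankResult:
    chi_square: float
    df: int
    p_value: float
    horizon_months: float | None
    group_sizes: dict[str, int]


@dataclass
class KMCurve:
    """Right-continuous product-limit step function with S(0) = 1."""

    times: np.ndarray
    survival: np.ndarray

    def __call__(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.times, t, side="right") - 1
        return self.survival[np.clip(idx, 0, len(self.survival) - 1)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time": self.times, "survival": self.survival})


def _check_records(records: pd.DataFrame) -> pd.DataFrame:
    missing = set(REQUIRED_COLS) - set(records.columns)
    if missing:
        raise ValueError(f"survival records missing columns: {sorted(missing)}")
    rec = records.copy()
    rec["time"] = rec["time"].astype(float)
    rec["event"] = rec["event"].astype(int)
    if not np.isfinite(rec["time"]).all() or (rec["time"] <= 0).any():
        raise ValueError("survival times must be finite and positive")
    return rec


def group_by_signature(scores: SignatureScores, rule: str = "median", threshold: float | None = None) -> pd.Series:
    """Two-group labels ("high"/"low") from per-tumor signature scores.

    ``rule="median"`` splits at the median (scores strictly above ->
    "high"); ``rule="threshold"`` splits at ``threshold``.  Each group
    must receive at least 2 tumors.
    """
    s = scores.per_sample_score
    if rule == "median":
        cut = float(s.median())
        if s.nunique() == 1:
            raise ValueError("degenerate split: all scores equal")
    elif rule == "threshold":
        if threshold is None:
            raise ValueError("threshold rule needs a threshold value")
        cut = float(threshold)
    else:
        raise ValueError(f"unknown grouping rule {rule!r}")
    labels = pd.Series(np.where(s > cut, "high", "low"), index=s.index, name="group")
    sizes = labels.value_counts()
    if sizes.min() < 2 or len(sizes) < 2:
        raise ValueError(f"grouping leaves a group with < 2 tumors: {sizes.to_dict()}")
    return labels


def truncate_at_horizon(records: pd.DataFrame, horizon_months: float) -> pd.DataFrame:
    """Administratively censor every record beyond the follow-up horizon."""
    rec = _check_records(records)
    over = rec["time"] > horizon_months
    rec.loc[over, "time"] = horizon_months
    rec.loc[over, "event"] = 0
    return rec


def km_estimate(records: pd.DataFrame) -> KMCurve:
    """Product-limit survival estimate for one group of records."""
    rec = _check_records(records)
    if len(rec) < 1:
        raise ValueError("no records")
    kmf = KaplanMeierFitter()
    kmf.fit(rec["time"], event_observed=rec["event"])
    sf = kmf.survival_function_
    times = sf.index.to_numpy(dtype=float)
    surv = sf.iloc[:, 0].to_numpy(dtype=float)
    if times[0] != 0.0:
        times = np.concatenate([[0.0], times])
        surv = np.concatenate([[1.0], surv])
    return KMCurve(times=times, survival=surv)


def logrank_test(records: pd.DataFrame, horizon_months: float | None = None) -> LogRankResult:
    """Standard two-group log-rank chi-square (1 df), optionally truncated."""
    rec = _check_records(records)
    if horizon_months is not None:
        rec = truncate_at_horizon(rec, horizon_months)
    groups = rec["group"].unique().tolist()
    if len(groups) != 2:
        raise ValueError(f"log-rank needs exactly 2 groups, got {groups}")
    sizes = rec["group"].value_counts()
    if sizes.min() < 1:
        raise ValueError("a group has zero at-risk subjects")
    if rec["event"].sum() == 0:
        raise ValueError("no events after truncation; log-rank undefined")
    a = rec[rec["group"] == groups[0]]
    b = rec[rec["group"] == groups[1]]
    res = _ll_logrank(a["time"], b["time"], event_observed_A=a["event"], event_observed_B=b["event"])
    return LogRankResult(
        chi_square=float(res.test_statistic),
        df=1,
        p_value=float(res.p_value),
        horizon_months=horizon_months,
        group_sizes={str(g): int(sizes[g]) for g in groups},
    )
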