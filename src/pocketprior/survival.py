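"""Kaplan-Meier validation machinery.

A cohort is dichotomised on the median expression of a candidate gene
(ties at the median go to the low group), optionally administratively
censored at a follow-up horizon (e.g. 2,000 days), summarised with the
product-limit estimator, and compared with the Mantel-Cox log-rank test
(hypergeometric variance, no continuity correction).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from lifelines.statistics import logrank_test as _lifelines_logrank

logger = logging.getLogger(__name__)

COHORT_COLUMNS = ["patient_id", "time_days", "event", "expression"]


@dataclass(frozen=True)
class KmCurve:
    """Product-limit curve evaluated at the distinct event times."""

    event_times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray

    def survival_at(self, t: float) -> float:
        """S(t): step function, right-continuous, S = 1 before the first event."""
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def read_cohort(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"patient_id": str})
    missing = set(COHORT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"cohort table missing columns {sorted(missing)}")
    df = df[COHORT_COLUMNS].copy()
    df["time_days"] = df["time_days"].astype(float)
    if (df["time_days"] < 0).any():
        raise ValueError("survival times must be non-negative")
    df["event"] = df["event"].astype(bool)
    if not np.isfinite(df["expression"]).all():
        raise ValueError("expression values must be finite")
    return df


def dichotomize_by_median(records: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """(low, high) split on median expression; ties at the median go low."""
    if len(records) < 2:
        raise ValueError("need >= 2 records to dichotomize")
    median = records["expression"].median()
    high = records[records["expression"] > median]
    low = records[records["expression"] <= median]
    if high.empty:
        raise ValueError("all expression values equal the median; no split possible")
    return low.reset_index(drop=True), high.reset_index(drop=True)


def truncate(records: pd.DataFrame, horizon: float) -> pd.DataFrame:
    """Administrative censoring: times beyond the horizon become censored there."""
    if horizon <= 0:
        raise ValueError("horizon must be positive")
    out = records.copy()
    over = out["time_days"] > horizon
    out.loc[over, "time_days"] = float(horizon)
    out.loc[over, "event"] = False
    return out


def km_estimate(times: Sequence[float], events: Sequence[bool]) -> KmCurve:
    """Product-limit estimator S(t) = prod_{t_i <= t} (1 - d_i / n_i)."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    if times.size == 0:
        raise ValueError("need >= 1 record")
    event_times = np.unique(times[events])
    d = np.array([int(((times == t) & events).sum()) for t in event_times])
    n = np.array([int((times >= t).sum()) for t in event_times])
    survival = np.cumprod(1.0 - d / n) if event_times.size else np.array([])
    return KmCurve(event_times, survival, n)


def logrank_test(
    times_a: Sequence[float],
    events_a: Sequence[bool],
    times_b: Sequence[float],
    events_b: Sequence[bool],
) -> tuple[float, float]:
    """Mantel-Cox log-rank statistic and 1-df chi-square p-value."""
    times_a = np.asarray(times_a, dtype=float)
    times_b = np.asarray(times_b, dtype=float)
    events_a = np.asarray(events_a, dtype=bool)
    events_b = np.asarray(events_b, dtype=bool)
    if times_a.size == 0 or times_b.size == 0:
        raise ValueError("both groups need >= 1 record")
    if events_a.sum() + events_b.sum() == 0:
        logger.warning("zero observed events in both groups; log-rank is uninformative")
        return 0.0, 1.0
    res = _lifelines_logrank(times_a, times_b, event_observed_A=events_a, event_observed_B=events_b)
    return float(res.test_statistic), float(res.p_value)


def km_curve_table(curve: KmCurve) -> pd.DataFrame:
    return pd.DataFrame(
        {"event_time": curve.event_times, "survival": curve.survival, "at_risk": curve.at_risk}
    )
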