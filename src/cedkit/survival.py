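"""Kaplan–Meier overall-survival endpoints for a small CED trial cohort.

Overall survival (OS) is measured from radiographic diagnosis to death;
patients without a recorded death contribute follow-up time to their
off-study date. Because one patient in the cohort was lost to follow-up,
two analysis policies are supported: treating the loss as an event at the
time it occurred (conservative) or censoring the lost patient at that time.

Confidence intervals use the Greenwood variance on the log-survival scale
(the ``conf.type = "log"`` convention of the R ``survival`` package):

    CI(t) = exp( log S(t) ± z * se(log S(t)) ),
    se(log S(t))^2 = sum_{t_i <= t} d_i / (n_i (n_i - d_i)),

truncated to [0, 1]. This asymmetric interval is the standard output of
``survfit`` and behaves sensibly at the small sample sizes typical of
phase-1 trials.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

Z_95 = 1.959963984540054  # two-sided 95% normal quantile


class Status(str, enum.Enum):
    DEATH = "death"
    ALIVE = "alive"
    LOST = "lost"


class LostPolicy(str, enum.Enum):
    LOST_AS_EVENT = "lost_as_event"
    LOST_CENSORED = "lost_censored"


@dataclass(frozen=True)
class SurvivalRecord:
    """One patient: follow-up time in months and vital status at last contact."""

    subject_id: str
    time_months: float
    status: Status

    def __post_init__(self) -> None:
        if self.time_months <= 0:
            raise ValueError(
                f"{self.subject_id}: time_months must be positive, got {self.time_months}"
            )
        object.__setattr__(self, "status", Status(self.status))


@dataclass
class KMCurve:
    """Product-limit estimate evaluated at the distinct event times.

    Arrays are aligned: at ``event_times[i]``, ``at_risk[i]`` subjects were
    at risk, ``events[i]`` died, and the curve steps down to ``survival[i]``
    with pointwise 95% CI (``ci_lower[i]``, ``ci_upper[i]``).
    """

    event_times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    events: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    max_followup: float = field(default=math.inf)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.event_times,
                "at_risk": self.at_risk,
                "events": self.events,
                "survival": self.survival,
                "ci_lower": self.ci_lower,
                "ci_upper": self.ci_upper,
            }
        )


def read_survival_table(path_or_df) -> list[SurvivalRecord]:
    """Build records from a cohort table CSV (subject, followup_months, status)."""
    df = path_or_df if isinstance(path_or_df, pd.DataFrame) else pd.read_csv(path_or_df)
    return [
        SurvivalRecord(str(r.subject), float(r.followup_months), Status(str(r.status).lower()))
        for r in df.itertuples()
    ]


def apply_lost_policy(
    records: Iterable[SurvivalRecord], policy: LostPolicy | str
) -> list[tuple[float, bool]]:
    """Convert records into (time, event_flag) pairs under a lost-to-follow-up policy.

    Deaths are always events, alive patients always censored; a patient lost
    to follow-up becomes an event or a censoring at the recorded time
    depending on ``policy``.
    """
    policy = LostPolicy(policy)
    out: list[tuple[float, bool]] = []
    for rec in records:
        if rec.status is Status.DEATH:
            flag = True
        elif rec.status is Status.ALIVE:
            flag = False
        else:
            flag = policy is LostPolicy.LOST_AS_EVENT
        out.append((rec.time_months, flag))
    return out


def km_fit(data: Sequence[tuple[float, bool]]) -> KMCurve:
    """Product-limit estimator with log-transformed Greenwood 95% CI.

    Ties between deaths and censorings at the same time are resolved with
    deaths first (the standard convention: a subject censored at t is still
    at risk for an event at t).
    """
    if len(data) == 0:
        raise ValueError("km_fit requires at least one record")
    times = np.asarray([t for t, _ in data], dtype=float)
    flags = np.asarray([bool(e) for _, e in data], dtype=bool)

    event_times = np.unique(times[flags])
    n = len(times)
    surv = 1.0
    cumvar = 0.0  # sum d / (n (n - d)) over past event times
    s_list, nrisk_list, d_list, lo_list, hi_list = [], [], [], [], []
    for t in event_times:
        n_risk = int(np.sum(times >= t))  # deaths at t precede censorings at t
        d = int(np.sum(times[flags] == t))
        surv *= 1.0 - d / n_risk
        if n_risk > d:
            cumvar += d / (n_risk * (n_risk - d))
            se_log = math.sqrt(cumvar)
            lo = math.exp(math.log(surv) - Z_95 * se_log) if surv > 0 else 0.0
            hi = min(1.0, math.exp(math.log(surv) + Z_95 * se_log)) if surv > 0 else 0.0
        else:  # curve hits zero; log-scale CI undefined below
            lo, hi = 0.0, hi_list[-1] if hi_list else 1.0
        s_list.append(surv)
        nrisk_list.append(n_risk)
        d_list.append(d)
        lo_list.append(max(0.0, lo))
        hi_list.append(hi)

    return KMCurve(
        event_times=event_times,
        survival=np.asarray(s_list),
        at_risk=np.asarray(nrisk_list, dtype=int),
        events=np.asarray(d_list, dtype=int),
        ci_lower=np.asarray(lo_list),
        ci_upper=np.asarray(hi_list),
        max_followup=float(times.max()),
    )


def os_at(curve: KMCurve, t: float) -> tuple[float, float, float, bool]:
    """Survival estimate and CI at time ``t`` (right-continuous step function).

    Returns ``(estimate, ci_lower, ci_upper, truncated)`` where ``truncated``
    flags a query beyond the last observed follow-up (the last defined value
    is carried forward).
    """
    if t < 0:
        raise ValueError("time must be nonnegative")
    truncated = t > curve.max_followup
    idx = np.searchsorted(curve.event_times, t, side="right") - 1
    if idx < 0:
        return 1.0, 1.0, 1.0, truncated
    return (
        float(curve.survival[idx]),
        float(curve.ci_lower[idx]),
        float(curve.ci_upper[idx]),
        truncated,
    )


def median_survival(curve: KMCurve) -> float | None:
    """Smallest event time at which S(t) drops to 0.5 or below; None if never."""
    below = np.nonzero(curve.survival <= 0.5)[0]
    if len(below) == 0:
        return None
    return float(curve.event_times[below[0]])


def summarize(
    records: Iterable[SurvivalRecord],
    policy: LostPolicy | str,
    at_months: float = 12.0,
) -> dict:
    """Fit one policy and report the endpoints as a JSON-ready dict."""
    policy = LostPolicy(policy)
    curve = km_fit(apply_lost_policy(records, policy))
    est, lo, hi, truncated = os_at(curve, at_months)
    med = median_survival(curve)
    return {
        "policy": policy.value,
        "at_months": at_months,
        "os_estimate": est,
        "ci_lower": lo,
        "ci_upper": hi,
        "truncated": truncated,
        "median_months": med,
    }
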