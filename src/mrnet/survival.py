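"""Kaplan-Meier estimation, log-rank testing and dES-based stratification.

Patients are stratified by regulon state: active (dES > 0, ES_A > 0,
ES_B < 0), repressed (dES < 0, ES_A < 0, ES_B > 0), otherwise inconclusive;
the two large groups are further split in half at their median dES (ties to
the low half). KM curves use the product-limit estimator and group
comparisons the standard log-rank chi-square with k - 1 df.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test

log = logging.getLogger("mrnet")

STRATA = ("active_high", "active_low", "repressed_high", "repressed_low", "inconclusive")


@dataclasses.dataclass
class KMCurve:
    """Product-limit survival curve: step function over the event times."""

    timeline: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray

    def validate(self) -> None:
        if self.survival[0] > 1 + 1e-12:
            raise ValueError("S(0) must be 1")
        if (np.diff(self.survival) > 1e-12).any():
            raise ValueError("survival must be non-increasing")


@dataclasses.dataclass
class LogrankResult:
    statistic: float
    df: int
    p: float


def km_estimate(times, events) -> KMCurve:
    """Kaplan-Meier product-limit estimate of the survival function."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.size == 0:
        raise ValueError("empty survival input")
    if (times < 0).any():
        raise ValueError("negative times")
    if not np.isin(events, (0, 1)).all():
        raise ValueError("events must be 0/1")
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    timeline = kmf.survival_function_.index.to_numpy(dtype=float)
    surv = kmf.survival_function_.iloc[:, 0].to_numpy(dtype=float)
    at_risk = kmf.event_table["at_risk"].to_numpy(dtype=float)
    curve = KMCurve(timeline=timeline, survival=surv, at_risk=at_risk)
    curve.validate()
    return curve


def logrank_test(groups) -> LogrankResult:
    """Log-rank comparison of k survival groups.

    ``groups`` is a sequence of ``(times, events)`` pairs. The statistic is
    the standard observed-minus-expected chi-square with k - 1 degrees of
    freedom (hypergeometric variance at each event time, censored-after-
    events tie convention, no continuity correction).
    """
    groups = list(groups)
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    times, events, labels = [], [], []
    for i, (t, e) in enumerate(groups):
        t = np.asarray(t, dtype=float)
        e = np.asarray(e, dtype=int)
        if t.size == 0:
            raise ValueError(f"group {i} is empty")
        times.append(t)
        events.append(e)
        labels.append(np.full(t.size, i))
    times = np.concatenate(times)
    events = np.concatenate(events)
    labels = np.concatenate(labels)
    if events.sum() == 0:
        raise ValueError("no events in any group")
    res = multivariate_logrank_test(times, labels, events)
    return LogrankResult(
        statistic=float(res.test_statistic), df=len(groups) - 1, p=float(res.p_value)
    )


def three_way_state(activity_rows: pd.DataFrame) -> pd.Series:
    """Per-sample regulon state: active / repressed / inconclusive.

    ``activity_rows`` must carry one row per sample with columns
    ``unit, es_a, es_b, des`` (one MR's per-sample activity).
    """
    des = activity_rows["des"].to_numpy(dtype=float)
    es_a = activity_rows["es_a"].to_numpy(dtype=float)
    es_b = activity_rows["es_b"].to_numpy(dtype=float)
    state = np.where(
        (des > 0) & (es_a > 0) & (es_b < 0),
        "active",
        np.where((des < 0) & (es_a < 0) & (es_b > 0), "repressed", "inconclusive"),
    )
    return pd.Series(state, index=activity_rows["unit"].to_numpy(), name="state")


def stratify_by_activity(activity_rows: pd.DataFrame) -> pd.Series:
    """Five-way survival strata from one MR's per-sample activity.

    Samples are first classified active/repressed/inconclusive, then the
    active and repressed groups are each split at their median dES into
    high/low halves (dES equal to the median goes to the low half);
    inconclusive samples are left whole. Strata are exhaustive and mutually
    exclusive by construction.
    """
    if activity_rows["unit"].duplicated().any():
        raise ValueError("more than one activity row per sample")
    state = three_way_state(activity_rows)
    des = pd.Series(
        activity_rows["des"].to_numpy(dtype=float), index=state.index
    )
    strata = pd.Series("inconclusive", index=state.index, name="stratum")
    for grp in ("active", "repressed"):
        members = state.index[state == grp]
        if len(members) == 0:
            continue
        med = des.loc[members].median()
        high = des.loc[members] > med
        strata.loc[members[high.to_numpy()]] = f"{grp}_high"
        strata.loc[members[~high.to_numpy()]] = f"{grp}_low"
    counts = strata.value_counts().to_dict()
    log.info("stratify_by_activity: %s", counts)
    return strata


def strata_survival(
    strata: pd.Series, annot: pd.DataFrame, groups=None
) -> tuple[dict[str, KMCurve], LogrankResult]:
    """KM curve per stratum plus a joint log-rank test.

    ``groups`` selects which strata to compare (default: all non-empty ones
    with survival data); a group may also be a tuple of strata to pool
    (e.g. ``("repressed_high", "repressed_low")``).
    """
    ann = annot.set_index("sample_id")
    if groups is None:
        groups = [s for s in STRATA if (strata == s).any()]
    curves: dict[str, KMCurve] = {}
    samples_per_group = []
    names = []
    for grp in groups:
        members = (
            strata.index[strata.isin(grp)]
            if isinstance(grp, tuple)
            else strata.index[strata == grp]
        )
        name = "+".join(grp) if isinstance(grp, tuple) else grp
        sub = ann.loc[ann.index.intersection(members)].dropna(subset=["survival_time"])
        if len(sub) == 0:
            continue
        names.append(name)
        samples_per_group.append((sub["survival_time"].to_numpy(), sub["event"].to_numpy()))
        curves[name] = km_estimate(sub["survival_time"], sub["event"])
    if len(samples_per_group) < 2:
        raise ValueError("fewer than 2 strata with survival data")
    lr = logrank_test(samples_per_group)
    log.info("strata_survival: groups=%s chi2=%.3f p=%.3g", names, lr.statistic, lr.p)
    return curves, lr
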