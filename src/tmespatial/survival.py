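"""Endpoint construction (OS, MFS), Kaplan-Meier estimation, log-rank
testing, and one- or two-marker median-stratified survival analysis.

The product-limit estimator and the k-group Mantel-Cox statistic are
implemented directly (they are small, and the tie conventions — events
before censorings at equal times — are part of the contract); tests verify
them against hand computations and an independent library implementation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from tmespatial.errors import ValidationError
from tmespatial.scoring import MarkerScore, stratify_by_median

ENDPOINTS = ("OS", "MFS")


@dataclass(frozen=True)
class SurvivalRecord:
    patient_id: str
    endpoint: str
    time: float
    event: bool
    strata: Optional[str] = None

    def __post_init__(self) -> None:
        if self.endpoint not in ENDPOINTS:
            raise ValidationError(f"unknown endpoint {self.endpoint!r}")
        if self.time < 0:
            raise ValidationError(
                f"patient {self.patient_id}: negative {self.endpoint} time {self.time}"
            )


@dataclass
class KMCurve:
    """Product-limit estimate: S(t) stepping down at event times only."""

    times: np.ndarray  # distinct event times, ascending
    at_risk: np.ndarray
    events: np.ndarray
    survival: np.ndarray  # S(t) just after each event time
    censor_times: np.ndarray = field(default_factory=lambda: np.array([]))
    n: int = 0

    def survival_at(self, t: float) -> float:
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])

    def median_time(self) -> float:
        """Smallest event time with S(t) <= 0.5, or nan if never reached."""
        below = np.nonzero(self.survival <= 0.5)[0]
        return float(self.times[below[0]]) if len(below) else float("nan")

    def restricted_mean(self, horizon: float) -> float:
        """Area under S(t) from 0 to ``horizon``."""
        grid = np.concatenate(([0.0], self.times[self.times < horizon], [horizon]))
        s = np.concatenate(([1.0], self.survival[self.times < horizon]))
        return float(np.sum(s * np.diff(grid)))


def build_endpoints(
    clinical: pd.DataFrame, mfs_death_as_event: bool = False
) -> list[SurvivalRecord]:
    """Derive OS and MFS records from a clinical table.

    OS runs from diagnosis to death (event) or last follow-up (censored).
    MFS runs from surgery to metastasis (event); death without metastasis
    censors by default (``mfs_death_as_event`` toggles treating it as an
    event).  Negative derived times are a hard error.
    """
    records: list[SurvivalRecord] = []
    for row in clinical.itertuples(index=False):
        pid = str(row.patient_id)
        diagnosis = float(getattr(row, "diagnosis_time", 0.0) or 0.0)
        surgery = float(getattr(row, "surgery_time", diagnosis))
        lfu = float(row.last_followup_time)
        death = getattr(row, "death_time", None)
        death = None if death is None or pd.isna(death) else float(death)
        met = getattr(row, "metastasis_time", None)
        met = None if met is None or pd.isna(met) else float(met)

        if death is not None:
            os_time, os_event = death - diagnosis, True
        else:
            os_time, os_event = lfu - diagnosis, False
        records.append(SurvivalRecord(pid, "OS", os_time, os_event))

        if met is not None:
            mfs_time, mfs_event = met - surgery, True
        else:
            end = min(x for x in (death, lfu) if x is not None)
            mfs_time = end - surgery
            mfs_event = mfs_death_as_event and death is not None and death <= lfu
        records.append(SurvivalRecord(pid, "MFS", mfs_time, bool(mfs_event)))
    return records


def kaplan_meier(records: Sequence[SurvivalRecord]) -> KMCurve:
    """Product-limit estimator; at tied times events precede censorings."""
    if len(records) == 0:
        raise ValidationError("kaplan_meier needs at least one record")
    times = np.array([r.time for r in records], dtype=float)
    events = np.array([r.event for r in records], dtype=bool)
    order = np.argsort(times, kind="stable")
    times, events = times[order], events[order]

    event_times = np.unique(times[events])
    at_risk = np.empty(len(event_times), dtype=int)
    d = np.empty(len(event_times), dtype=int)
    for i, t in enumerate(event_times):
        at_risk[i] = int(np.sum(times >= t))  # events-first tie rule
        d[i] = int(np.sum(events & (times == t)))
    with np.errstate(invalid="ignore"):
        survival = np.cumprod(1.0 - d / at_risk)
    return KMCurve(
        times=event_times,
        at_risk=at_risk,
        events=d,
        survival=survival,
        censor_times=np.sort(times[~events]),
        n=len(records),
    )


def km_table(curve: KMCurve) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "time": curve.times,
            "at_risk": curve.at_risk,
            "events": curve.events,
            "survival": curve.survival,
        }
    )


@dataclass(frozen=True)
class LogRankResult:
    statistic: float
    df: int
    p: float
    n_per_group: tuple[int, ...]


def log_rank(groups: Sequence[Sequence[SurvivalRecord]]) -> LogRankResult:
    """k-group Mantel-Cox test via the observed-minus-expected chi-square."""
    if len(groups) < 2:
        raise ValidationError("log_rank requires >= 2 groups")
    for i, g in enumerate(groups):
        if len(g) == 0:
            raise ValidationError(f"log_rank group {i} is empty")
    k = len(groups)
    times = [np.array([r.time for r in g], dtype=float) for g in groups]
    events = [np.array([r.event for r in g], dtype=bool) for g in groups]
    all_event_times = np.unique(np.concatenate([t[e] for t, e in zip(times, events)]))

    o_minus_e = np.zeros(k)
    cov = np.zeros((k, k))
    for t in all_event_times:
        n_j = np.array([np.sum(tt >= t) for tt in times], dtype=float)
        d_j = np.array([np.sum(ee & (tt == t)) for tt, ee in zip(times, events)], dtype=float)
        n, d = n_j.sum(), d_j.sum()
        if n <= 1:
            continue
        expected = d * n_j / n
        o_minus_e += d_j - expected
        scale = d * (n - d) / (n - 1)
        for a in range(k):
            for b in range(k):
                delta = 1.0 if a == b else 0.0
                cov[a, b] += scale * (n_j[a] / n) * (delta - n_j[b] / n)

    v = cov[: k - 1, : k - 1]
    u = o_minus_e[: k - 1]
    if not np.any(v):
        chi2 = 0.0
    else:
        chi2 = float(u @ np.linalg.pinv(v) @ u)
        chi2 = max(chi2, 0.0)
    df = k - 1
    p = float(sps.chi2.sf(chi2, df)) if chi2 > 0 else 1.0
    return LogRankResult(statistic=chi2, df=df, p=p, n_per_group=tuple(len(g) for g in groups))


@dataclass
class StratifiedKMResult:
    groups: dict[str, list[SurvivalRecord]]
    curves: dict[str, KMCurve]
    log_rank: Optional[LogRankResult]
    thresholds: dict[str, float]
    absent_groups: tuple[str, ...] = ()


def stratified_km(
    scores: Mapping[str, Sequence[MarkerScore]],
    records: Sequence[SurvivalRecord],
    markers: Sequence[str],
) -> StratifiedKMResult:
    """Median-stratified KM analysis for 1 marker (high/low) or 2 markers
    (four groups); groups with zero patients are reported absent, and the
    log-rank test is skipped with a warning when fewer than two groups
    remain."""
    if len(markers) not in (1, 2):
        raise ValidationError("stratified_km supports 1 or 2 markers")
    endpoint = {r.endpoint for r in records}
    if len(endpoint) != 1:
        raise ValidationError(f"records mix endpoints {sorted(endpoint)}")

    label_of: dict[str, dict[str, str]] = {}
    thresholds: dict[str, float] = {}
    for m in markers:
        labels = stratify_by_median(list(scores[m]))
        label_of[m] = {lab.patient_id: lab.label for lab in labels}
        thresholds[m] = labels[0].threshold

    def group_name(pid: str) -> Optional[str]:
        parts = []
        for m in markers:
            if pid not in label_of[m]:
                return None
            parts.append(f"{m}_{label_of[m][pid]}")
        return "/".join(parts)

    if len(markers) == 1:
        m = markers[0]
        expected = [f"{m}_high", f"{m}_low"]
    else:
        expected = [
            f"{markers[0]}_{a}/{markers[1]}_{b}"
            for a in ("high", "low")
            for b in ("high", "low")
        ]
    groups: dict[str, list[SurvivalRecord]] = {name: [] for name in expected}
    for r in records:
        name = group_name(r.patient_id)
        if name is not None:
            groups[name].append(r)

    absent = tuple(name for name, recs in groups.items() if not recs)
    present = {name: recs for name, recs in groups.items() if recs}
    curves = {name: kaplan_meier(recs) for name, recs in present.items()}
    lr = None
    if len(present) >= 2:
        lr = log_rank(list(present.values()))
    else:
        warnings.warn("all patients fall in one stratification group; log-rank skipped", stacklevel=2)
    return StratifiedKMResult(
        groups=present, curves=curves, log_rank=lr, thresholds=thresholds, absent_groups=absent
    )
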