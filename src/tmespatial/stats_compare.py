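"""Group comparisons: Student's t-tests, one-way ANOVA with Tukey/Dunnett
post-hoc procedures, and Pearson correlation.

All p-values are two-sided.  The unpaired test is the pooled-variance
Student form, not Welch.  Degenerate inputs (zero variance everywhere with
equal means) are reported as no-difference (statistic 0, p = 1) with a
``degenerate`` flag rather than raising, so pipelines survive flat
synthetic inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from tmespatial.errors import ValidationError


@dataclass(frozen=True)
class ComparisonResult:
    kind: str
    statistic: float
    df: tuple[float, ...]
    p: float
    group_means: tuple[float, ...]
    group_sems: tuple[float, ...]
    degenerate: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.p <= 1.0):
            raise ValidationError(f"p-value out of [0,1]: {self.p}")


def _sem(a: np.ndarray) -> float:
    return float(np.std(a, ddof=1) / np.sqrt(len(a))) if len(a) > 1 else 0.0


def t_test(a: Sequence[float], b: Sequence[float], paired: bool = False) -> ComparisonResult:
    """Two-sided Student's t-test (pooled variance when unpaired)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if paired:
        if len(a) != len(b):
            raise ValidationError("paired test requires equal-length samples")
        if len(a) < 2:
            raise ValidationError("paired test requires n >= 2")
        diffs = a - b
        if np.all(diffs == diffs[0]) and diffs[0] == 0:
            return ComparisonResult(
                kind="t_paired", statistic=0.0, df=(len(a) - 1,), p=1.0,
                group_means=(float(a.mean()), float(b.mean())),
                group_sems=(_sem(a), _sem(b)), degenerate=True,
            )
        res = stats.ttest_rel(a, b)
        kind = "t_paired"
        df = (len(a) - 1,)
    else:
        if len(a) < 2 or len(b) < 2:
            raise ValidationError("unpaired test requires n >= 2 per group")
        if np.var(a) == 0 and np.var(b) == 0:
            equal = a.mean() == b.mean()
            return ComparisonResult(
                kind="t_unpaired", statistic=0.0 if equal else float("inf"),
                df=(len(a) + len(b) - 2,), p=1.0 if equal else 0.0,
                group_means=(float(a.mean()), float(b.mean())),
                group_sems=(0.0, 0.0), degenerate=True,
            )
        res = stats.ttest_ind(a, b, equal_var=True)
        kind = "t_unpaired"
        df = (len(a) + len(b) - 2,)
    return ComparisonResult(
        kind=kind, statistic=float(res.statistic), df=df, p=float(res.pvalue),
        group_means=(float(a.mean()), float(b.mean())),
        group_sems=(_sem(a), _sem(b)),
    )


@dataclass
class AnovaResult:
    anova: ComparisonResult
    pairwise: Optional[pd.DataFrame] = None  # columns: group_a, group_b, p_adj
    posthoc: str = "none"
    group_labels: tuple = field(default_factory=tuple)


def one_way_anova(
    groups: Sequence[Sequence[float]],
    posthoc: str = "none",
    labels: Optional[Sequence[str]] = None,
    control_index: int = 0,
) -> AnovaResult:
    """One-way fixed-effects ANOVA; F with (k-1, N-k) degrees of freedom.

    Two groups delegate to the unpaired t-test (reported as such).
    ``posthoc`` is ``tukey``, ``dunnett`` (vs ``groups[control_index]``) or
    ``none``.
    """
    if posthoc not in ("tukey", "dunnett", "none"):
        raise ValidationError(f"unknown posthoc {posthoc!r}")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    labels = tuple(labels) if labels is not None else tuple(f"g{i}" for i in range(len(arrays)))
    for lbl, g in zip(labels, arrays):
        if len(g) < 2:
            raise ValidationError(f"group {lbl!r} has n={len(g)} < 2")
    if len(arrays) < 2:
        raise ValidationError("ANOVA requires at least 2 groups")
    if len(arrays) == 2:
        return AnovaResult(anova=t_test(arrays[0], arrays[1]), group_labels=labels)

    pooled = np.concatenate(arrays)
    if np.var(pooled) == 0:
        k, n_total = len(arrays), len(pooled)
        result = ComparisonResult(
            kind="anova", statistic=0.0, df=(k - 1, n_total - k), p=1.0,
            group_means=tuple(float(g.mean()) for g in arrays),
            group_sems=tuple(_sem(g) for g in arrays), degenerate=True,
        )
        return AnovaResult(anova=result, group_labels=labels)

    f_res = stats.f_oneway(*arrays)
    k, n_total = len(arrays), len(pooled)
    result = ComparisonResult(
        kind="anova", statistic=float(f_res.statistic), df=(k - 1, n_total - k),
        p=float(f_res.pvalue),
        group_means=tuple(float(g.mean()) for g in arrays),
        group_sems=tuple(_sem(g) for g in arrays),
    )
    pairwise = None
    if posthoc == "tukey":
        t_res = stats.tukey_hsd(*arrays)
        rows = [
            {"group_a": labels[i], "group_b": labels[j], "p_adj": float(t_res.pvalue[i, j])}
            for i in range(k)
            for j in range(i + 1, k)
        ]
        pairwise = pd.DataFrame(rows)
    elif posthoc == "dunnett":
        control = arrays[control_index]
        others = [g for i, g in enumerate(arrays) if i != control_index]
        other_labels = [lbl for i, lbl in enumerate(labels) if i != control_index]
        d_res = stats.dunnett(*others, control=control)
        pairwise = pd.DataFrame(
            {
                "group_a": other_labels,
                "group_b": [labels[control_index]] * len(other_labels),
                "p_adj": [float(p) for p in np.atleast_1d(d_res.pvalue)],
            }
        )
    return AnovaResult(anova=result, pairwise=pairwise, posthoc=posthoc, group_labels=labels)


def pearson(x: Sequence[float], y: Sequence[float]) -> tuple[float, float, int]:
    """Sample Pearson correlation with two-sided p from the t-transform."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValidationError("pearson requires equal-length vectors")
    if len(x) < 3:
        raise ValidationError(f"pearson requires n >= 3, got {len(x)}")
    if np.var(x) == 0 or np.var(y) == 0:
        raise ValidationError("pearson undefined for zero-variance input")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue), len(x)


def comparisons_table(results: dict[str, ComparisonResult]) -> pd.DataFrame:
    """Serialize named comparison results to a flat table."""
    rows = []
    for name, r in results.items():
        rows.append(
            {
                "comparison": name,
                "test": r.kind,
                "statistic": r.statistic,
                "df": "/".join(f"{d:g}" for d in r.df),
                "p": r.p,
                "degenerate": r.degenerate,
            }
        )
    return pd.DataFrame(rows)
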