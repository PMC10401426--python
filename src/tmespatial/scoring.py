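"""Marker quantification: H-score, TIL score, replicate aggregation,
per-core positive fraction / density, and median stratification."""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from tmespatial.cell_io import CoreCellTable
from tmespatial.errors import ValidationError

SCORE_KINDS = ("h_score", "til_score", "positive_fraction", "density_per_mm2", "flow_frequency")


@dataclass(frozen=True)
class IntensityBinFractions:
    """Fractions of cells with stain intensity 0 / weak / moderate / strong."""

    f0: float
    f1: float
    f2: float
    f3: float

    def __post_init__(self) -> None:
        fracs = (self.f0, self.f1, self.f2, self.f3)
        if any(f < 0 or f > 1 for f in fracs):
            raise ValidationError(f"bin fractions must lie in [0,1], got {fracs}")
        if abs(sum(fracs) - 1.0) > 1e-9:
            raise ValidationError(f"bin fractions must sum to 1, got {sum(fracs)!r}")


@dataclass(frozen=True)
class MarkerScore:
    """One scalar expression score for one patient and marker."""

    patient_id: str
    marker: str
    value: float
    kind: str
    n_replicates: int = 1

    def __post_init__(self) -> None:
        if self.kind not in SCORE_KINDS:
            raise ValidationError(f"unknown score kind {self.kind!r}")
        if self.kind == "h_score" and not (0 <= self.value <= 300):
            raise ValidationError(f"h_score out of [0,300]: {self.value}")
        if self.kind == "til_score" and not (0 <= self.value <= 3):
            raise ValidationError(f"til_score out of [0,3]: {self.value}")
        if self.kind == "positive_fraction" and not (0 <= self.value <= 1):
            raise ValidationError(f"fraction out of [0,1]: {self.value}")
        if self.value < 0:
            raise ValidationError(f"score must be nonnegative: {self.value}")


@dataclass(frozen=True)
class StratificationLabel:
    patient_id: str
    marker: str
    label: str  # "high" | "low"
    threshold: float  # cohort median used for the split


def h_score(bins: IntensityBinFractions) -> float:
    """Weighted intensity score on the 0-300 scale: 100*(f1 + 2*f2 + 3*f3)."""
    return 100.0 * (bins.f1 + 2.0 * bins.f2 + 3.0 * bins.f3)


def til_score(tils_per_hpf: float) -> int:
    """Ordinal 0-3 infiltrate bin from a TIL-per-high-power-field count.

    Bins: <1 -> 0; 1-10 -> 1; 11-20 -> 2; >20 -> 3.  Averaged replicate
    inputs falling in the open gap (10, 11) are snapped half-up to the
    nearest bin boundary before binning.
    """
    x = float(tils_per_hpf)
    if x < 0:
        raise ValidationError(f"TIL count must be nonnegative, got {x}")
    if 10 < x < 11:
        x = 10.0 if x < 10.5 else 11.0
    if x < 1:
        return 0
    if x <= 10:
        return 1
    if x <= 20:
        return 2
    return 3


def aggregate_replicates(scores: Sequence[float]) -> float:
    """Arithmetic mean over replicate cores of one patient."""
    if len(scores) == 0:
        raise ValidationError("no replicate scores to aggregate")
    return float(np.mean(scores))


def positive_fraction_and_density(core: CoreCellTable, marker: str) -> tuple[float, float]:
    """(positive fraction of all cells, positive cells per mm^2) for a core."""
    positives = int(core.mask(marker).sum())
    n = len(core)
    fraction = positives / n if n else 0.0
    density = positives / (core.area_um2 / 1e6)
    return fraction, density


def stratify_by_median(scores: Sequence[MarkerScore]) -> list[StratificationLabel]:
    """Split one marker's per-patient scores at the cohort median.

    ``high`` means strictly above the median (even-n median is the mean of
    the middle two values); with a median of 0 every zero-score patient is
    labelled ``low``.  A degenerate all-equal cohort is labelled all-low
    with a warning.
    """
    if len(scores) < 2:
        raise ValidationError("median stratification needs at least 2 patients")
    markers = {s.marker for s in scores}
    if len(markers) != 1:
        raise ValidationError(f"stratify one marker at a time, got {sorted(markers)}")
    values = np.array([s.value for s in scores], dtype=float)
    median = float(np.median(values))
    if np.all(values == values[0]):
        warnings.warn(
            f"all {scores[0].marker} scores equal ({values[0]}); degenerate split, all 'low'",
            stacklevel=2,
        )
    return [
        StratificationLabel(
            patient_id=s.patient_id,
            marker=s.marker,
            label="high" if s.value > median else "low",
            threshold=median,
        )
        for s in scores
    ]


def patient_marker_scores(
    cores: Iterable[CoreCellTable], marker: str, kind: str = "density_per_mm2"
) -> list[MarkerScore]:
    """Per-patient scores of ``kind`` for ``marker``, averaging replicate cores."""
    if kind not in ("positive_fraction", "density_per_mm2"):
        raise ValidationError(f"cannot derive kind {kind!r} from cell tables")
    per_patient: dict[str, list[float]] = {}
    for core in cores:
        fraction, density = positive_fraction_and_density(core, marker)
        value = fraction if kind == "positive_fraction" else density
        per_patient.setdefault(core.patient_id, []).append(value)
    return [
        MarkerScore(
            patient_id=pid,
            marker=marker,
            value=aggregate_replicates(vals),
            kind=kind,
            n_replicates=len(vals),
        )
        for pid, vals in sorted(per_patient.items())
    ]
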