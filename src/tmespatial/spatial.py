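"""Radius-based cell neighborhood enumeration.

For chosen center and target phenotypes, count target cells whose centroid
lies within a fixed radius (default 30 μm, Euclidean, boundary inclusive)
of each center cell.  Centers never count themselves (exclusion is by cell
identity, so coincident distinct cells are mutual neighbors).  No edge
correction is applied by default; an optional guard margin excludes
centers within one radius of the core boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from tmespatial.cell_io import CoreCellTable, flag_column
from tmespatial.errors import ValidationError
from tmespatial.scoring import MarkerScore, positive_fraction_and_density
from tmespatial import stats_compare

DEFAULT_RADIUS_UM = 30.0


@dataclass
class SpatialIndex:
    """KD-tree over one core's centroids supporting inclusive radius queries."""

    core: CoreCellTable
    _tree: Optional[cKDTree] = None

    def __post_init__(self) -> None:
        if len(self.core):
            self._tree = cKDTree(self.core.positions())

    def query(self, point: Sequence[float], radius: float) -> np.ndarray:
        """Row indices of cells with Euclidean distance <= radius of ``point``."""
        if self._tree is None:
            return np.array([], dtype=int)
        idx = self._tree.query_ball_point(np.asarray(point, float), r=radius)
        return np.sort(np.asarray(idx, dtype=int))

    def query_many(self, points: np.ndarray, radius: float) -> list[np.ndarray]:
        if self._tree is None:
            return [np.array([], dtype=int) for _ in range(len(points))]
        balls = self._tree.query_ball_point(points, r=radius)
        return [np.sort(np.asarray(b, dtype=int)) for b in balls]


def build_index(core: CoreCellTable) -> SpatialIndex:
    return SpatialIndex(core)


@dataclass
class NeighborhoodResult:
    core_id: str
    center_phenotype: str
    radius: float
    per_center: pd.DataFrame  # cell_id + one count_<target> column per target
    n_centers: int
    summary: dict  # target -> {"mean", "min", "max"}


def _guard_mask(core: CoreCellTable, radius: float) -> np.ndarray:
    if core.geometry is None:
        raise ValidationError(
            f"core {core.core_id}: guard margin requires a known disc geometry"
        )
    cx, cy, r_core = core.geometry
    pos = core.positions()
    dist = np.hypot(pos[:, 0] - cx, pos[:, 1] - cy)
    return dist <= r_core - radius


def neighbor_counts(
    core: CoreCellTable,
    center_phenotype: str,
    target_phenotypes: Sequence[str],
    radius: float = DEFAULT_RADIUS_UM,
    inclusive: bool = True,
    guard_margin: bool = False,
    index: Optional[SpatialIndex] = None,
) -> NeighborhoodResult:
    """Per-center in-range counts of each target phenotype."""
    if radius <= 0:
        raise ValidationError(f"radius must be positive, got {radius}")
    for p in (center_phenotype, *target_phenotypes):
        flag_column(p)  # raises on unknown phenotype

    center_mask = core.mask(center_phenotype)
    if guard_margin:
        center_mask = center_mask & _guard_mask(core, radius)
    center_idx = np.nonzero(center_mask)[0]
    target_masks = {t: core.mask(t) for t in target_phenotypes}

    counts = {t: np.zeros(len(center_idx), dtype=int) for t in target_phenotypes}
    if len(center_idx) and len(core):
        idx = index or build_index(core)
        pos = core.positions()
        balls = idx.query_many(pos[center_idx], radius)
        if not inclusive:
            balls = [
                b[np.hypot(*(pos[b] - pos[c]).T) < radius]
                for c, b in zip(center_idx, balls)
            ]
        for i, (c, ball) in enumerate(zip(center_idx, balls)):
            ball = ball[ball != c]  # self-exclusion by identity
            for t in target_phenotypes:
                counts[t][i] = int(target_masks[t][ball].sum())

    per_center = pd.DataFrame({"cell_id": core.cells["cell_id"].iloc[center_idx].to_numpy()})
    for t in target_phenotypes:
        per_center[f"count_{t}"] = counts[t]
    summary = {}
    for t in target_phenotypes:
        c = counts[t]
        summary[t] = {
            "mean": float(c.mean()) if len(c) else float("nan"),
            "min": int(c.min()) if len(c) else None,
            "max": int(c.max()) if len(c) else None,
        }
    return NeighborhoodResult(
        core_id=core.core_id,
        center_phenotype=center_phenotype,
        radius=radius,
        per_center=per_center,
        n_centers=len(center_idx),
        summary=summary,
    )


@dataclass
class ClusteringResult:
    """Center x target mean in-range counts at several aggregation levels.

    ``per_core`` / ``per_patient`` map ids to matrices (rows = centers,
    columns = targets, NaN where a unit has no centers of that phenotype —
    absence is not zero clustering).  ``pooled`` averages over all centers
    pooled across cores; ``long`` keeps every (center cell, target) count.
    """

    phenotypes: tuple[str, ...]
    radius: float
    per_core: dict[str, pd.DataFrame]
    per_patient: dict[str, pd.DataFrame]
    pooled: pd.DataFrame
    long: pd.DataFrame
    excluded: list = field(default_factory=list)  # (core_id, phenotype) with 0 centers


def clustering_matrix(
    cores: Sequence[CoreCellTable],
    phenotypes: Sequence[str],
    radius: float = DEFAULT_RADIUS_UM,
    guard_margin: bool = False,
) -> ClusteringResult:
    if not cores:
        raise ValidationError("clustering_matrix needs at least one core")
    phenotypes = tuple(phenotypes)
    per_core: dict[str, pd.DataFrame] = {}
    excluded: list = []
    long_rows: list[pd.DataFrame] = []
    pooled_sum = pd.DataFrame(0.0, index=phenotypes, columns=phenotypes)
    pooled_n = pd.DataFrame(0, index=phenotypes, columns=phenotypes)

    for core in cores:
        idx = build_index(core)
        mat = pd.DataFrame(np.nan, index=phenotypes, columns=phenotypes)
        for center in phenotypes:
            res = neighbor_counts(
                core, center, phenotypes, radius=radius, guard_margin=guard_margin, index=idx
            )
            if res.n_centers == 0:
                excluded.append((core.core_id, center))
                continue
            for target in phenotypes:
                counts = res.per_center[f"count_{target}"].to_numpy()
                mat.loc[center, target] = counts.mean()
                pooled_sum.loc[center, target] += counts.sum()
                pooled_n.loc[center, target] += len(counts)
            melted = res.per_center.melt(
                id_vars="cell_id", var_name="target_type", value_name="count"
            )
            melted["target_type"] = melted["target_type"].str.removeprefix("count_")
            melted.insert(0, "patient_id", core.patient_id)
            melted.insert(0, "core_id", core.core_id)
            melted["center_type"] = center
            melted["radius"] = radius
            long_rows.append(melted)
        per_core[core.core_id] = mat

    patients: dict[str, list[pd.DataFrame]] = {}
    for core in cores:
        patients.setdefault(core.patient_id, []).append(per_core[core.core_id])
    per_patient = {
        pid: pd.concat(mats).groupby(level=0, sort=False).mean().reindex(phenotypes)
        for pid, mats in sorted(patients.items())
    }
    with np.errstate(invalid="ignore"):
        pooled = pooled_sum / pooled_n.where(pooled_n > 0)
    long = (
        pd.concat(long_rows, ignore_index=True)
        if long_rows
        else pd.DataFrame(
            columns=["core_id", "patient_id", "cell_id", "target_type", "count", "center_type", "radius"]
        )
    )
    long = long[
        ["core_id", "patient_id", "cell_id", "center_type", "target_type", "radius", "count"]
    ]
    return ClusteringResult(
        phenotypes=phenotypes,
        radius=radius,
        per_core=per_core,
        per_patient=per_patient,
        pooled=pooled,
        long=long,
        excluded=excluded,
    )


def paired_in_range(
    cores: Sequence[CoreCellTable],
    center_phenotype: str,
    target_a: str,
    target_b: str,
    radius: float = DEFAULT_RADIUS_UM,
) -> pd.DataFrame:
    """Per-center paired counts (count_a, count_b); feeds the paired t-test."""
    frames = []
    for core in cores:
        res = neighbor_counts(core, center_phenotype, [target_a, target_b], radius=radius)
        df = res.per_center.rename(
            columns={f"count_{target_a}": "count_a", f"count_{target_b}": "count_b"}
        )
        if target_a == target_b:
            df = res.per_center.rename(columns={f"count_{target_a}": "count_a"})
            df["count_b"] = df["count_a"]
        df.insert(0, "core_id", core.core_id)
        frames.append(df[["core_id", "cell_id", "count_a", "count_b"]])
    return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["core_id", "cell_id", "count_a", "count_b"]
    )


@dataclass
class FlagPartitionResult:
    flag: str
    positive: pd.DataFrame  # long per-center counts for flag-positive centers
    negative: pd.DataFrame
    summary: pd.DataFrame  # rows: (partition, target) mean/min/max/n_centers
    n_excluded: int  # centers with undefined flag


def partition_centers_by_flag(
    cores: Sequence[CoreCellTable],
    target_phenotypes: Sequence[str],
    radius: float = DEFAULT_RADIUS_UM,
    flag: str = "MHC1",
    restrict_to: Optional[str] = None,
) -> FlagPartitionResult:
    """Split centers by a boolean flag (default MHC-I) and count targets.

    Every cell with a defined flag is a center exactly once, in the
    partition matching its flag; cells with an undefined (NA) flag are
    excluded and counted.  ``restrict_to`` optionally limits centers to one
    phenotype (e.g. ``"tumor"``).
    """
    col = flag_column(flag)
    rows = {True: [], False: []}
    n_excluded = 0
    for core in cores:
        flags = core.cells[col]
        defined = flags.notna().to_numpy()
        n_excluded += int((~defined).sum())
        eligible = defined
        if restrict_to is not None:
            eligible = eligible & core.mask(restrict_to)
        flag_vals = flags.fillna(False).to_numpy(dtype=bool)
        idx = build_index(core)
        pos = core.positions()
        balls = idx.query_many(pos[eligible], radius) if eligible.any() else []
        target_masks = {t: core.mask(t) for t in target_phenotypes}
        for c, ball in zip(np.nonzero(eligible)[0], balls):
            ball = ball[ball != c]
            row = {
                "core_id": core.core_id,
                "patient_id": core.patient_id,
                "cell_id": core.cells["cell_id"].iloc[c],
            }
            for t in target_phenotypes:
                row[f"count_{t}"] = int(target_masks[t][ball].sum())
            rows[bool(flag_vals[c])].append(row)

    cols = ["core_id", "patient_id", "cell_id"] + [f"count_{t}" for t in target_phenotypes]
    positive = pd.DataFrame(rows[True], columns=cols)
    negative = pd.DataFrame(rows[False], columns=cols)
    summary_rows = []
    for name, df in ((f"{flag}+", positive), (f"{flag}-", negative)):
        for t in target_phenotypes:
            c = df[f"count_{t}"]
            summary_rows.append(
                {
                    "partition": name,
                    "target": t,
                    "n_centers": len(df),
                    "mean": float(c.mean()) if len(df) else float("nan"),
                    "min": int(c.min()) if len(df) else None,
                    "max": int(c.max()) if len(df) else None,
                }
            )
    return FlagPartitionResult(
        flag=flag,
        positive=positive,
        negative=negative,
        summary=pd.DataFrame(summary_rows),
        n_excluded=n_excluded,
    )


def density_expression_correlation(
    cores: Sequence[CoreCellTable],
    phenotype: str,
    expression_scores: Sequence[MarkerScore],
) -> tuple[float, float, int]:
    """Pearson correlation between a per-patient expression score and the
    per-patient mean density (cells/mm^2) of ``phenotype``."""
    densities: dict[str, list[float]] = {}
    for core in cores:
        _, dens = positive_fraction_and_density(core, phenotype)
        densities.setdefault(core.patient_id, []).append(dens)
    pairs = [
        (s.value, float(np.mean(densities[s.patient_id])))
        for s in expression_scores
        if s.patient_id in densities
    ]
    if len(pairs) < 3:
        raise ValidationError(f"correlation needs >= 3 paired units, got {len(pairs)}")
    x, y = zip(*pairs)
    return stats_compare.pearson(x, y)


def brute_force_counts(
    core: CoreCellTable,
    center_phenotype: str,
    target_phenotype: str,
    radius: float = DEFAULT_RADIUS_UM,
) -> np.ndarray:
    """O(n^2) reference: in-range target counts per center, by full distance
    matrix.  Exists for validation against the indexed path."""
    pos = core.positions()
    centers = np.nonzero(core.mask(center_phenotype))[0]
    targets = core.mask(target_phenotype)
    out = np.zeros(len(centers), dtype=int)
    for i, c in enumerate(centers):
        d = np.hypot(pos[:, 0] - pos[c, 0], pos[:, 1] - pos[c, 1])
        in_range = (d <= radius) & targets
        in_range[c] = False
        out[i] = int(in_range.sum())
    return out
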