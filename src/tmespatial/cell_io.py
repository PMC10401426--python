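"""Read, validate and write per-cell segmentation tables and clinical tables.

The on-disk cell format is plain delimited text (UTF-8, comma or tab), one
row per nucleated cell.  Mandatory columns: ``cell_id``, ``core_id``,
``patient_id``, ``x``, ``y`` (centroids in μm once parsed).  Optional
columns: per-marker intensities (``intensity_<marker>``), 0/1 phenotype
flags (``cd3``, ``cd8``, ``nkp46``, ``cd56``, ``tumor``), a nullable
``mhc1`` flag (empty = undefined, e.g. for cells whose MHC-I status was not
called), a ``core_area_um2`` column and, when the core geometry is a known
disc, ``core_cx``/``core_cy``/``core_radius_um``.  Comment lines start with
``#`` and carry provenance such as the generator seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from tmespatial.errors import ConfigError, ValidationError

#: canonical phenotype name -> boolean flag column
FLAG_OF = {
    "CD3": "cd3",
    "CD8": "cd8",
    "NKp46": "nkp46",
    "NK": "nkp46",  # alias: NK cells are identified by NKp46 in tissue
    "CD56": "cd56",
    "MHC1": "mhc1",
    "tumor": "tumor",
}

MANDATORY_COLUMNS = ("cell_id", "core_id", "patient_id", "x", "y")
BOOL_FLAGS = ("cd3", "cd8", "nkp46", "cd56", "tumor")
NULLABLE_FLAGS = ("mhc1",)

TREATMENT_GROUPS = (
    "upfront_surgery",
    "neoadjuvant_rt",
    "neoadjuvant_chemo",
    "chemoradiation",
)


def flag_column(phenotype: str) -> str:
    """Map a panel phenotype name to its flag column, or raise."""
    try:
        return FLAG_OF[phenotype]
    except KeyError:
        raise ValidationError(
            f"unknown phenotype {phenotype!r}; panel is {sorted(FLAG_OF)}"
        ) from None


@dataclass
class CoreCellTable:
    """All cells of one TMA core plus its geometry.

    ``cells`` holds one row per cell with at least ``cell_id``, ``x``, ``y``
    and the boolean flag columns.  ``geometry`` is ``(cx, cy, radius_um)``
    when the core is a known disc, else ``None``.
    """

    core_id: str
    patient_id: str
    cells: pd.DataFrame
    area_um2: float
    geometry: Optional[tuple[float, float, float]] = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (self.area_um2 > 0):
            raise ValidationError(
                f"core {self.core_id}: area must be positive, got {self.area_um2}"
            )
        cells = self.cells
        if len(cells):
            if cells["cell_id"].duplicated().any():
                dupes = cells.loc[cells["cell_id"].duplicated(), "cell_id"]
                raise ValidationError(
                    f"core {self.core_id}: duplicate cell_id {dupes.iloc[0]!r}"
                )
            xy = cells[["x", "y"]].to_numpy(dtype=float)
            if not np.isfinite(xy).all():
                raise ValidationError(f"core {self.core_id}: non-finite coordinates")
        for col in BOOL_FLAGS:
            if col not in cells.columns:
                cells[col] = np.zeros(len(cells), dtype=bool)
            else:
                # NaN (row absent from a mixed source) means negative, not True
                cells[col] = cells[col].astype("boolean").fillna(False).astype(bool)
        for col in NULLABLE_FLAGS:
            if col not in cells.columns:
                cells[col] = pd.array([pd.NA] * len(cells), dtype="boolean")
            else:
                cells[col] = cells[col].astype("boolean")

    def __len__(self) -> int:
        return len(self.cells)

    def positions(self) -> np.ndarray:
        return self.cells[["x", "y"]].to_numpy(dtype=float)

    def mask(self, phenotype: str) -> np.ndarray:
        """Boolean mask of cells positive for ``phenotype`` (NA counts as False)."""
        col = flag_column(phenotype)
        return self.cells[col].fillna(False).to_numpy(dtype=bool)

    def equals(self, other: "CoreCellTable") -> bool:
        if (self.core_id, self.patient_id) != (other.core_id, other.patient_id):
            return False
        if not math.isclose(self.area_um2, other.area_um2, rel_tol=1e-12):
            return False
        a = self.cells.reset_index(drop=True)
        b = other.cells.reset_index(drop=True)
        cols = sorted(set(a.columns) & set(b.columns))
        if set(a.columns) != set(b.columns) or len(a) != len(b):
            return False
        return a[cols].equals(b[cols])


@dataclass(frozen=True)
class DialectConfig:
    """How to interpret one segmentation export dialect.

    ``columns`` maps canonical names (``cell_id``, ``core_id``,
    ``patient_id``, ``x``, ``y``) to the column labels used in the file.
    ``units`` is ``"um"`` or ``"px"`` (the latter requires ``px_size_um``).
    ``intensity_columns`` maps marker names to intensity column labels;
    ``label_columns`` maps flag columns to pre-existing 0/1 label columns.
    """

    delimiter: Optional[str] = None
    columns: Mapping[str, str] = field(default_factory=dict)
    units: str = "um"
    px_size_um: Optional[float] = None
    intensity_columns: Mapping[str, str] = field(default_factory=dict)
    label_columns: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.units not in ("um", "px"):
            raise ConfigError(f"unknown coordinate units {self.units!r} (um or px)")
        if self.units == "px" and not (self.px_size_um and self.px_size_um > 0):
            raise ConfigError("px units require a positive px_size_um")


@dataclass
class ParseReport:
    source: str
    n_rows_read: int = 0
    n_rows_dropped: int = 0
    dropped_reasons: dict = field(default_factory=dict)


def _sniff_delimiter(path: Path) -> str:
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            return "\t" if line.count("\t") >= line.count(",") else ","
    return ","


def read_cell_table(
    path, dialect: DialectConfig = DialectConfig()
) -> tuple[list[CoreCellTable], ParseReport]:
    """Parse a delimited cell table into per-core tables.

    Rows with missing/non-finite coordinates are dropped and counted in the
    returned :class:`ParseReport`; missing mandatory columns are a hard
    error naming them.
    """
    path = Path(path)
    sep = dialect.delimiter or _sniff_delimiter(path)
    raw = pd.read_csv(path, sep=sep, comment="#", dtype={0: str}, float_precision="round_trip")
    colmap = {dialect.columns.get(k, k): k for k in MANDATORY_COLUMNS}
    missing = [src for src in colmap if src not in raw.columns]
    if missing:
        raise ValidationError(
            f"{path}: missing mandatory column(s): {', '.join(sorted(missing))}"
        )
    df = raw.rename(columns=colmap)
    for marker, src in dialect.intensity_columns.items():
        if src not in raw.columns:
            raise ValidationError(f"{path}: intensity column {src!r} not found")
        df[f"intensity_{marker}"] = pd.to_numeric(raw[src])
    for flag, src in dialect.label_columns.items():
        if src not in raw.columns:
            raise ValidationError(f"{path}: label column {src!r} not found")
        df[flag] = raw[src]

    report = ParseReport(source=str(path), n_rows_read=len(df))
    df["x"] = pd.to_numeric(df["x"], errors="coerce")
    df["y"] = pd.to_numeric(df["y"], errors="coerce")
    bad = ~(np.isfinite(df["x"].to_numpy(float)) & np.isfinite(df["y"].to_numpy(float)))
    if bad.any():
        report.n_rows_dropped = int(bad.sum())
        report.dropped_reasons["missing_coordinates"] = int(bad.sum())
        df = df.loc[~bad].reset_index(drop=True)
    if dialect.units == "px":
        df["x"] = df["x"] * dialect.px_size_um
        df["y"] = df["y"] * dialect.px_size_um

    for col in BOOL_FLAGS:
        if col in df.columns:
            df[col] = pd.to_numeric(df[col]).fillna(0).astype(bool)
    for col in NULLABLE_FLAGS:
        if col in df.columns:
            num = pd.to_numeric(df[col], errors="coerce")
            df[col] = pd.array(
                [pd.NA if pd.isna(v) else bool(v) for v in num], dtype="boolean"
            )

    tables = []
    for core_id, sub in df.groupby("core_id", sort=True):
        sub = sub.reset_index(drop=True)
        patient_id = str(sub["patient_id"].iloc[0])
        geometry = None
        if {"core_cx", "core_cy", "core_radius_um"} <= set(sub.columns):
            geometry = (
                float(sub["core_cx"].iloc[0]),
                float(sub["core_cy"].iloc[0]),
                float(sub["core_radius_um"].iloc[0]),
            )
        if "core_area_um2" in sub.columns:
            area = float(sub["core_area_um2"].iloc[0])
        elif geometry is not None:
            area = math.pi * geometry[2] ** 2
        else:
            area = _estimate_area(sub)
        cells = sub.drop(
            columns=[
                c
                for c in ("core_id", "patient_id", "core_area_um2", "core_cx", "core_cy", "core_radius_um")
                if c in sub.columns
            ]
        )
        cells["cell_id"] = cells["cell_id"].astype(str)
        tables.append(
            CoreCellTable(
                core_id=str(core_id),
                patient_id=patient_id,
                cells=cells,
                area_um2=area,
                geometry=geometry,
                provenance={"source": str(path), "dialect_units": dialect.units},
            )
        )
    return tables, report


def _estimate_area(df: pd.DataFrame) -> float:
    """Convex-hull area fallback when no geometry is recorded; degenerate
    point sets fall back to the bounding box, then to 1 μm²."""
    from scipy.spatial import ConvexHull, QhullError

    pts = df[["x", "y"]].to_numpy(float)
    area = 0.0
    if len(pts) >= 3:
        try:
            area = float(ConvexHull(pts).volume)  # 2-D hull: volume == area
        except QhullError:
            area = 0.0
    if area <= 0 and len(pts):
        area = float(np.ptp(pts[:, 0]) * np.ptp(pts[:, 1]))
    return area if area > 0 else 1.0


def write_cell_table(tables: Sequence[CoreCellTable], path, header_meta: dict | None = None) -> None:
    """Write cores to one delimited file; inverse of :func:`read_cell_table`."""
    path = Path(path)
    frames = []
    for t in tables:
        df = t.cells.copy()
        df.insert(1, "core_id", t.core_id)
        df.insert(2, "patient_id", t.patient_id)
        df["core_area_um2"] = t.area_um2
        if t.geometry is not None:
            df["core_cx"], df["core_cy"], df["core_radius_um"] = t.geometry
        frames.append(df)
    if frames:
        out = pd.concat(frames, ignore_index=True)
    else:
        out = pd.DataFrame(columns=list(MANDATORY_COLUMNS))
    for col in BOOL_FLAGS:
        if col in out.columns:
            out[col] = out[col].astype(int)
    for col in NULLABLE_FLAGS:
        if col in out.columns:
            out[col] = out[col].astype("boolean").astype("Int64")
    with open(path, "w", encoding="utf-8") as fh:
        for key, val in (header_meta or {}).items():
            fh.write(f"# {key}={val}\n")
        out.to_csv(fh, index=False)


@dataclass(frozen=True)
class GatingConfig:
    """Intensity thresholds per marker, or trust pre-existing label columns.

    Positivity is strict: flag set iff intensity > threshold.  The
    containment rule CD8+ => CD3+ is applied when ``cd8_implies_cd3``.
    """

    thresholds: Mapping[str, float] = field(default_factory=dict)
    use_labels: bool = False
    cd8_implies_cd3: bool = True


def classify_cells(table: CoreCellTable, gating: GatingConfig) -> CoreCellTable:
    """Set phenotype flags from marker intensities (strict ``>`` gating)."""
    cells = table.cells.copy()
    if not gating.use_labels:
        for marker, thr in gating.thresholds.items():
            col = f"intensity_{marker}"
            if col not in cells.columns:
                raise ValidationError(
                    f"core {table.core_id}: marker {marker!r} has no column {col!r}"
                )
            flag = flag_column(marker)
            positive = cells[col].to_numpy(float) > thr
            if flag in NULLABLE_FLAGS:
                cells[flag] = pd.array(positive, dtype="boolean")
            else:
                cells[flag] = positive
    if gating.cd8_implies_cd3:
        cells["cd3"] = cells["cd3"].astype(bool) | cells["cd8"].astype(bool)
    return CoreCellTable(
        core_id=table.core_id,
        patient_id=table.patient_id,
        cells=cells,
        area_um2=table.area_um2,
        geometry=table.geometry,
        provenance={**table.provenance, "gating": "labels" if gating.use_labels else "thresholds"},
    )


CLINICAL_COLUMNS = (
    "patient_id",
    "diagnosis_time",
    "surgery_time",
    "last_followup_time",
    "death_time",
    "metastasis_time",
    "treatment_group",
    "histology",
)


def read_clinical_table(path, delimiter: Optional[str] = None) -> pd.DataFrame:
    path = Path(path)
    sep = delimiter or _sniff_delimiter(path)
    df = pd.read_csv(
        path, sep=sep, comment="#", dtype={"patient_id": str}, float_precision="round_trip"
    )
    missing = [c for c in ("patient_id",) if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing clinical column(s): {missing}")
    if "treatment_group" in df.columns:
        bad = set(df["treatment_group"].dropna()) - set(TREATMENT_GROUPS)
        if bad:
            raise ValidationError(f"{path}: unknown treatment group(s) {sorted(bad)}")
    return df


def write_clinical_table(df: pd.DataFrame, path, header_meta: dict | None = None) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for key, val in (header_meta or {}).items():
            fh.write(f"# {key}={val}\n")
        df.to_csv(fh, index=False)
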