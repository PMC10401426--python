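"""Synthetic spatial cohorts: marked cluster point processes on circular
cores, IHC intensity-bin tables, and exponential proportional-hazards
survival, so every downstream stage is testable without external data.

Clustered phenotypes follow a Neyman-Scott (Thomas) construction: Poisson
parents on the core disc, Poisson-distributed offspring counts, isotropic
Gaussian displacements, offspring outside the disc discarded.  Cross-type
attraction is modeled by letting one phenotype borrow a fraction of another
phenotype's parents; affinity to MHC-I+ disc regions constrains a fraction
of parents inside (or, negative affinity, outside) those regions.  Tumor
cells carry a defined MHC-I flag (positive inside the discs); immune cells
leave it undefined.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from tmespatial.cell_io import CLINICAL_COLUMNS, CoreCellTable, TREATMENT_GROUPS
from tmespatial.errors import ConfigError
from tmespatial.scoring import aggregate_replicates

#: primary phenotype -> boolean flag columns it sets (CD8+ implies CD3+)
PHENOTYPE_FLAGS = {
    "NK": ("nkp46", "cd56"),
    "CD3": ("cd3",),
    "CD8": ("cd8", "cd3"),
    "tumor": ("tumor",),
}

HISTOLOGIES = ("UPS", "liposarcoma", "leiomyosarcoma", "myxofibrosarcoma")


@dataclass(frozen=True)
class ClusterSpec:
    """One Thomas-process component."""

    parent_rate: float  # parents per μm^2
    mean_offspring: float  # Poisson mean per parent
    offspring_sd: float  # μm, isotropic Gaussian displacement
    mhc1_affinity: float = 0.0  # in [-1, 1]: fraction of parents forced
    # inside (>0) or outside (<0) the MHC-I+ disc regions

    def __post_init__(self) -> None:
        if self.parent_rate < 0:
            raise ConfigError(f"parent_rate must be >= 0, got {self.parent_rate}")
        if self.mean_offspring < 0:
            raise ConfigError(f"mean_offspring must be >= 0, got {self.mean_offspring}")
        if not self.offspring_sd > 0:
            raise ConfigError(f"offspring_sd must be > 0, got {self.offspring_sd}")
        if not -1.0 <= self.mhc1_affinity <= 1.0:
            raise ConfigError(f"mhc1_affinity must lie in [-1,1], got {self.mhc1_affinity}")


@dataclass(frozen=True)
class PointProcessConfig:
    """Marked point-process configuration for one circular core.

    The core is the disc of radius ``core_radius`` centered at
    ``(core_radius, core_radius)`` (all coordinates positive, image
    convention).  ``cross_attraction[(A, B)]`` is the fraction of B's
    parents drawn from A's parent set (1 = fully co-clustered, 0 =
    independent/disjoint parents).
    """

    core_radius: float = 400.0
    background_rate: Mapping[str, float] = field(default_factory=dict)
    clusters: Mapping[str, ClusterSpec] = field(default_factory=dict)
    cross_attraction: Mapping[tuple[str, str], float] = field(default_factory=dict)
    mhc1_discs: tuple[tuple[float, float, float], ...] = ()
    tumor_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.core_radius > 0:
            raise ConfigError(f"core_radius must be > 0, got {self.core_radius}")
        for name, rate in self.background_rate.items():
            if rate < 0:
                raise ConfigError(f"background_rate[{name!r}] must be >= 0, got {rate}")
        if self.tumor_rate < 0:
            raise ConfigError(f"tumor_rate must be >= 0, got {self.tumor_rate}")
        for pair, frac in self.cross_attraction.items():
            if not 0.0 <= frac <= 1.0:
                raise ConfigError(f"cross_attraction[{pair!r}] must lie in [0,1], got {frac}")

    @property
    def center(self) -> tuple[float, float]:
        return (self.core_radius, self.core_radius)

    @property
    def area_um2(self) -> float:
        return float(np.pi * self.core_radius**2)


def _uniform_disc(rng: np.random.Generator, n: int, center, radius: float) -> np.ndarray:
    r = radius * np.sqrt(rng.random(n))
    theta = rng.random(n) * 2 * np.pi
    return np.column_stack([center[0] + r * np.cos(theta), center[1] + r * np.sin(theta)])


def _in_discs(points: np.ndarray, discs) -> np.ndarray:
    inside = np.zeros(len(points), dtype=bool)
    for cx, cy, r in discs:
        inside |= np.hypot(points[:, 0] - cx, points[:, 1] - cy) <= r
    return inside


def _constrained_points(
    rng: np.random.Generator, n: int, config: PointProcessConfig, want_inside: bool
) -> np.ndarray:
    """Uniform points on the core disc conditioned on MHC-I disc membership
    (rejection sampling with a fixed retry cap)."""
    out = np.empty((0, 2))
    for _ in range(200):
        if len(out) >= n:
            break
        cand = _uniform_disc(rng, max(4 * (n - len(out)), 16), config.center, config.core_radius)
        keep = _in_discs(cand, config.mhc1_discs) == want_inside
        out = np.vstack([out, cand[keep]])
    return out[:n]


def _parents(rng: np.random.Generator, name: str, spec: ClusterSpec, config: PointProcessConfig) -> np.ndarray:
    n = rng.poisson(spec.parent_rate * config.area_um2)
    pts = _uniform_disc(rng, n, config.center, config.core_radius)
    if spec.mhc1_affinity != 0.0 and config.mhc1_discs:
        n_constrained = rng.binomial(n, abs(spec.mhc1_affinity)) if n else 0
        if n_constrained:
            pts[:n_constrained] = _constrained_points(
                rng, n_constrained, config, want_inside=spec.mhc1_affinity > 0
            )
    return pts


def simulate_core(
    config: PointProcessConfig,
    seed: Optional[int] = None,
    core_id: str = "core-0",
    patient_id: str = "pt-0",
) -> CoreCellTable:
    """Draw one core's cells; deterministic for fixed (config, seed)."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    cx, cy = config.center
    records: list[tuple[str, float, float]] = []  # (phenotype, x, y)

    n_tumor = rng.poisson(config.tumor_rate * config.area_um2)
    tumor_pts = _uniform_disc(rng, n_tumor, config.center, config.core_radius)
    for x, y in tumor_pts:
        records.append(("tumor", x, y))

    for name in sorted(config.background_rate):
        n = rng.poisson(config.background_rate[name] * config.area_um2)
        for x, y in _uniform_disc(rng, n, config.center, config.core_radius):
            records.append((name, x, y))

    cluster_names = list(config.clusters)
    parent_sets = {
        name: _parents(rng, name, config.clusters[name], config) for name in cluster_names
    }
    for (src, dst), frac in sorted(config.cross_attraction.items()):
        if dst not in parent_sets or frac == 0.0:
            continue
        n_dst = len(parent_sets[dst])
        n_src = len(parent_sets.get(src, ()))
        if n_dst == 0 or n_src == 0:
            continue
        n_shared = rng.binomial(n_dst, frac)
        if n_shared:
            take = rng.integers(0, n_src, size=n_shared)
            parent_sets[dst] = parent_sets[dst].copy()
            parent_sets[dst][:n_shared] = parent_sets[src][take]

    for name in cluster_names:
        spec = config.clusters[name]
        for px, py in parent_sets[name]:
            n_off = rng.poisson(spec.mean_offspring)
            if not n_off:
                continue
            offsets = rng.normal(0.0, spec.offspring_sd, size=(n_off, 2))
            pts = np.array([px, py]) + offsets
            keep = np.hypot(pts[:, 0] - cx, pts[:, 1] - cy) <= config.core_radius
            for x, y in pts[keep]:
                records.append((name, x, y))

    df = pd.DataFrame(records, columns=["phenotype", "x", "y"])
    df.insert(0, "cell_id", [f"{core_id}-c{i:06d}" for i in range(len(df))])
    for flag in ("cd3", "cd8", "nkp46", "cd56", "tumor"):
        df[flag] = False
    for phenotype, flags in PHENOTYPE_FLAGS.items():
        mask = df["phenotype"] == phenotype
        for flag in flags:
            df.loc[mask, flag] = True
    mhc1 = pd.array([pd.NA] * len(df), dtype="boolean")
    tumor_mask = (df["phenotype"] == "tumor").to_numpy()
    if tumor_mask.any():
        pts = df.loc[tumor_mask, ["x", "y"]].to_numpy(float)
        mhc1[np.nonzero(tumor_mask)[0]] = _in_discs(pts, config.mhc1_discs)
    df["mhc1"] = mhc1
    df = df.drop(columns="phenotype")
    return CoreCellTable(
        core_id=core_id,
        patient_id=patient_id,
        cells=df,
        area_um2=config.area_um2,
        geometry=(cx, cy, config.core_radius),
        provenance={"generator": "thomas", "seed": int(config.seed if seed is None else seed)},
    )


def default_point_process_config(seed: int = 0) -> PointProcessConfig:
    """Default core emulating the assumed structure: NK micro-aggregates
    kept out of MHC-I+ regions, larger co-clustered CD3/CD8 aggregates on
    MHC-I+ regions, low uniform immune background, tumor cells throughout."""
    r = 400.0
    return PointProcessConfig(
        core_radius=r,
        tumor_rate=3.0e-3,
        mhc1_discs=((250.0, 250.0, 120.0), (550.0, 350.0, 120.0), (350.0, 600.0, 120.0)),
        background_rate={"NK": 1.0e-5, "CD3": 2.0e-5, "CD8": 1.5e-5},
        clusters={
            "NK": ClusterSpec(6.0e-5, 8.0, 8.0, mhc1_affinity=-0.95),
            "CD3": ClusterSpec(1.2e-5, 25.0, 35.0, mhc1_affinity=0.95),
            "CD8": ClusterSpec(1.2e-5, 50.0, 10.0, mhc1_affinity=0.95),
        },
        cross_attraction={("CD3", "CD8"): 0.5},
        seed=seed,
    )


@dataclass(frozen=True)
class CohortConfig:
    """Cohort-level simulation: replicate cores per patient and an
    exponential proportional-hazards model on per-patient marker scores
    (standardized within the cohort)."""

    n_patients: int = 20
    cores_per_patient: int = 3
    baseline_hazard: float = 0.02  # events per month
    log_hazard: Mapping[str, float] = field(default_factory=lambda: {"NK": -0.8})
    censoring_rate: float = 0.01  # per month
    horizon: float = 120.0  # months
    frailty_sd: float = 0.5  # per-patient log-normal rate multiplier SD
    metastasis_hazard_ratio: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 2:
            raise ConfigError(f"n_patients must be >= 2, got {self.n_patients}")
        if self.cores_per_patient < 1:
            raise ConfigError("cores_per_patient must be >= 1")
        if not self.baseline_hazard > 0:
            raise ConfigError("baseline_hazard must be > 0")
        if not self.censoring_rate > 0:
            raise ConfigError("censoring_rate must be > 0")
        if not self.horizon > 0:
            raise ConfigError(f"horizon must be > 0, got {self.horizon}")
        if self.frailty_sd < 0:
            raise ConfigError("frailty_sd must be >= 0")


def _scaled_config(
    config: PointProcessConfig, multipliers: Mapping[str, float]
) -> PointProcessConfig:
    background = {
        name: rate * multipliers.get(name, 1.0)
        for name, rate in config.background_rate.items()
    }
    clusters = {
        name: ClusterSpec(
            spec.parent_rate * multipliers.get(name, 1.0),
            spec.mean_offspring,
            spec.offspring_sd,
            spec.mhc1_affinity,
        )
        for name, spec in config.clusters.items()
    }
    return PointProcessConfig(
        core_radius=config.core_radius,
        background_rate=background,
        clusters=clusters,
        cross_attraction=config.cross_attraction,
        mhc1_discs=config.mhc1_discs,
        tumor_rate=config.tumor_rate,
        seed=config.seed,
    )


def simulate_cohort(
    config: CohortConfig,
    spatial_config: PointProcessConfig,
    seed: Optional[int] = None,
) -> tuple[list[CoreCellTable], pd.DataFrame, dict]:
    """Simulate cores, per-patient marker scores, and survival outcomes.

    Returns (cores, clinical table, truth) where truth holds the hazard
    coefficients, per-patient raw and standardized scores, and per-patient
    hazards for recovery assertions.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    markers = sorted(config.log_hazard)

    cores: list[CoreCellTable] = []
    raw_scores: dict[str, dict[str, float]] = {m: {} for m in markers}
    patient_ids = [f"pt-{i:03d}" for i in range(config.n_patients)]
    for pid in patient_ids:
        multipliers = {
            name: float(np.exp(rng.normal(0.0, config.frailty_sd)))
            for name in sorted(set(spatial_config.clusters) | set(spatial_config.background_rate))
        }
        patient_config = _scaled_config(spatial_config, multipliers)
        patient_cores = []
        for c in range(config.cores_per_patient):
            core_seed = int(rng.integers(0, 2**63 - 1))
            patient_cores.append(
                simulate_core(
                    patient_config, seed=core_seed, core_id=f"{pid}-core{c}", patient_id=pid
                )
            )
        cores.extend(patient_cores)
        for m in markers:
            densities = [
                core.mask(m).sum() / (core.area_um2 / 1e6) for core in patient_cores
            ]
            raw_scores[m][pid] = aggregate_replicates(densities)

    z_scores: dict[str, dict[str, float]] = {}
    for m in markers:
        vals = np.array([raw_scores[m][pid] for pid in patient_ids])
        sd = vals.std()
        z = (vals - vals.mean()) / sd if sd > 0 else np.zeros_like(vals)
        z_scores[m] = dict(zip(patient_ids, z))

    rows = []
    hazards = {}
    for pid in patient_ids:
        lp = sum(config.log_hazard[m] * z_scores[m][pid] for m in markers)
        lam = config.baseline_hazard * float(np.exp(lp))
        hazards[pid] = lam
        death_raw = rng.exponential(1.0 / lam)
        censor = min(rng.exponential(1.0 / config.censoring_rate), config.horizon)
        met_raw = rng.exponential(1.0 / (lam * config.metastasis_hazard_ratio))
        death_observed = death_raw <= censor
        death_time = death_raw if death_observed else np.nan
        lfu = death_raw if death_observed else censor
        met_time = met_raw if met_raw < min(death_raw, censor) else np.nan
        rows.append(
            {
                "patient_id": pid,
                "diagnosis_time": 0.0,
                "surgery_time": 0.0,
                "last_followup_time": lfu,
                "death_time": death_time,
                "metastasis_time": met_time,
                "treatment_group": TREATMENT_GROUPS[rng.integers(0, len(TREATMENT_GROUPS))],
                "histology": HISTOLOGIES[rng.integers(0, len(HISTOLOGIES))],
            }
        )
    clinical = pd.DataFrame(rows, columns=CLINICAL_COLUMNS)
    truth = {
        "log_hazard": dict(config.log_hazard),
        "baseline_hazard": config.baseline_hazard,
        "raw_scores": raw_scores,
        "z_scores": z_scores,
        "hazards": hazards,
    }
    return cores, clinical, truth


def simulate_ihc_bins(
    n_cores: int, dirichlet_weights: Sequence[float], seed: Optional[int] = None
) -> pd.DataFrame:
    """Per-core intensity-bin fractions (f0, f1, f2, f3), each row summing
    to 1, drawn from a Dirichlet; zero weights pin their bin to exactly 0."""
    weights = np.asarray(dirichlet_weights, dtype=float)
    if weights.shape != (4,) or (weights < 0).any():
        raise ConfigError("dirichlet_weights must be 4 nonnegative reals")
    if not weights.sum() > 0:
        raise ConfigError("dirichlet_weights must not be all zero")
    if n_cores < 0:
        raise ConfigError("n_cores must be >= 0")
    rng = np.random.default_rng(seed)
    out = np.zeros((n_cores, 4))
    positive = weights > 0
    if positive.sum() == 1:
        out[:, positive] = 1.0
    else:
        out[:, positive] = rng.dirichlet(weights[positive], size=n_cores)
    return pd.DataFrame(out, columns=["f0", "f1", "f2", "f3"])
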