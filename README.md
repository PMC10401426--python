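# tmespatial

Radius-based cell-neighborhood analysis of multiplexed tumor-microenvironment
data, built around the question of how NK cells, T cells and MHC-I⁺ cells
co-localize in tissue microarray (TMA) cores, plus the quantification and
survival machinery such an analysis rests on:

- **`synthetic_data`** — marked cluster point-process simulator (Thomas /
  Neyman–Scott components with cross-type attraction and MHC-I-region
  affinity), Dirichlet IHC intensity-bin tables, and exponential
  proportional-hazards cohorts with ground truth for recovery tests.
- **`cell_io`** — delimited-text segmentation-table parsing (configurable
  column dialects, μm/px units), validation with an explicit parse report,
  round-trip writing, and threshold gating of marker intensities into
  phenotype flags (strict `>`, optional CD8⁺⇒CD3⁺ containment).
- **`scoring`** — H-score (0–300), TIL score (0–3), replicate-core
  averaging, per-core positive fraction / density, and median
  stratification (high = strictly above the cohort median).
- **`spatial`** — the core computation: for chosen center/target
  phenotypes, count targets within a fixed radius (default 30 μm,
  Euclidean, inclusive boundary, self excluded by identity) of every
  center cell; clustering matrices at per-core / per-patient / pooled
  levels; MHC-I⁺/⁻ center partitions; paired in-range counts; a
  brute-force O(n²) reference implementation kept for verification.
- **`stats_compare`** — pooled-variance Student's t (paired/unpaired),
  one-way ANOVA with Tukey/Dunnett post-hoc, Pearson correlation; explicit
  degenerate-input conventions.
- **`survival`** — OS/MFS endpoint construction, a direct product-limit
  Kaplan–Meier estimator, the k-group Mantel–Cox log-rank test, and one-
  or two-marker (four-group) median-stratified analyses.
- **`pipeline_cli`** — `run_paper_battery` orchestration with a run
  manifest that reproduces reports byte-for-byte, Table-1-style cohort
  summaries (half-up percentages), figures, and a `click` CLI.

## CLI

```bash
tmespatial simulate --seed 1 --n-patients 20 --out runs/sim      # cells.csv + clinical.csv
tmespatial score    --cells runs/sim/cells.csv --out runs/scores.csv
tmespatial spatial  --cells runs/sim/cells.csv --radius 30 --out runs/spat
tmespatial survival --clinical runs/sim/clinical.csv --scores runs/scores.csv \
                    --marker NKp46 --endpoint OS --out runs/surv
tmespatial battery  --seed 1 --out runs/battery                  # full analysis battery
tmespatial report   --clinical runs/sim/clinical.csv             # cohort summary
```

`battery` accepts a YAML config (`--config`) or a previously written
manifest (`--manifest runs/battery/manifest.json`), which reproduces the
run exactly.

## Data formats

Cell tables are plain delimited text (comma or tab), one row per nucleated
cell, with mandatory columns `cell_id, core_id, patient_id, x, y`
(centroids in μm), optional `intensity_<marker>` columns, 0/1 flags
(`cd3, cd8, nkp46, cd56, tumor`), a nullable `mhc1` flag (empty =
undefined status), and per-core geometry columns. Lines starting with `#`
carry provenance (e.g. the generator seed). Clinical tables carry
`patient_id`, time columns in months (`diagnosis_time`, `surgery_time`,
`last_followup_time`, `death_time`, `metastasis_time`), a treatment group
from {upfront_surgery, neoadjuvant_rt, neoadjuvant_chemo, chemoradiation},
and histology.
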