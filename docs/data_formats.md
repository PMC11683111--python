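# Dataset and table formats

All files are plain text. Units are fixed (positions mm, times ms, voltages
mV, speeds m/s) and declared in each dataset's `meta.json`; the reader
validates the declaration and refuses unit-less or mismatched files.

## Map dataset directory

| file | contents |
|---|---|
| `meta.json` | `patient_id`, `fs_hz` (required, Hz), `rhythm`, `units` (must equal `{"position": "mm", "time": "ms", "voltage": "mV", "speed": "m/s"}`), provenance (`tool`, `seed`, `config_hash`), `n_points` |
| `mesh.ply` | triangulated surface, ASCII PLY, vertex coordinates in mm |
| `vertex_data.csv` | one row per mesh vertex, in vertex order |
| `points.csv` | one row per mapping point |
| `traces_bipolar.csv` | one row of comma-separated samples (mV) per point, no header |
| `traces_unipolar.csv` | same layout, optional |

Maps with fewer than 1,000 points load with a `low_density` warning flag
(the clinical inclusion rule), never a hard error.

### `vertex_data.csv` columns

| column | meaning |
|---|---|
| `region` | `body`, `pv` (pulmonary-vein ostium) or `laa` (appendage) |
| any other column | named per-vertex scalar field (e.g. `bip_voltage`, `cv`, `true_lat_ms`); NaN marks unmapped vertices |

### `points.csv` columns

| column | meaning |
|---|---|
| `point_id` | 0-based index, matches the trace-file row |
| `x_mm`, `y_mm`, `z_mm` | electrode position |
| `t0_ms` | time of the first trace sample on the map clock |
| `lat_ms` | annotated local activation time (NaN before processing) |
| `bip_mV`, `uni_mV` | peak-to-peak amplitudes (NaN before processing) |
| `quality` | `accepted`, `rejected_noise` or `rejected_amplitude` |
| `true_lat_ms`, `true_bip_mV` | simulator ground truth (NaN for imported data) |

## Cohort table

CSV with one row per patient and the `PatientSummary` field names:
`patient_id`, `group` (`AF_paroxysmal` / `AF_persistent` / `control`),
`mean_bip_mV`, `mean_uni_mV`, `mean_cv_m_per_s`, `area_bip_05_rel`,
`area_bip_03_rel`, `area_cv_06_rel`, `area_cv_04_rel`, `n_points`,
`age_years`, `n_comorbidities`, `lavi_ml_per_m2`, `event` (0/1),
`time_months`, `cluster_label`, `true_cluster`. Report CSVs written by the
pipeline start with a comment line `# eamap <version> seed=<s>
config_hash=<h>`; read them with `comment="#"`.

## Kaplan-Meier curve export

`km_curves.csv`: `stratum`, `t_months`, `survival`, `greenwood_var`,
`n_at_risk`, `n_events` — the product-limit step function per stratum.

## Configuration

A flat YAML mapping of the `PipelineConfig` fields (see
`eamap.io.PipelineConfig`); unknown keys are rejected. `config_hash` is the
first 16 hex digits of the SHA-256 of the canonical JSON dump and is
embedded in every output file.
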