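"""Dataset layout, readers/writers, and run configuration.

A map dataset is a directory:

    meta.json            patient id, sampling rate, rhythm, declared units,
                         provenance (tool version, seed, config hash)
    mesh.ply             triangulated surface, ASCII PLY, positions in mm
    vertex_data.csv      per-vertex region label and any named scalar fields
    points.csv           one row per mapping point: position, trace start
                         time, annotations and simulator truth where known
    traces_bipolar.csv   one row of samples (mV) per point, no header
    traces_unipolar.csv  likewise (optional)

Units are declared in ``meta.json`` and validated on read — never inferred —
because every conduction-velocity threshold is unit-critical.  Cohort and
survival tables are plain CSV with the column names of ``PatientSummary``.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import trimesh
import yaml

from . import __version__
from .egm import ElectrogramTrace
from .mapping import AtrialMesh, MappingPoint

__all__ = [
    "PipelineConfig",
    "DatasetError",
    "write_dataset",
    "read_dataset",
    "write_cohort_table",
    "read_cohort_table",
]

EXPECTED_UNITS = {"position": "mm", "time": "ms", "voltage": "mV", "speed": "m/s"}
MIN_POINTS_RECOMMENDED = 1000  # inclusion rule: maps want >1,000 reading points


class DatasetError(ValueError):
    """A dataset violates the documented schema."""


@dataclass
class PipelineConfig:
    """Every tunable of the simulate -> process -> cohort -> survival pipeline.

    Stored as a flat human-readable YAML mapping; ``config_hash`` (first 16
    hex digits of the SHA-256 of the canonical JSON dump) is embedded in every
    output so runs are attributable.
    """

    seed: int = 0
    # mesh / simulation
    mesh_shape: str = "disc"
    mesh_resolution_mm: float = 2.5
    disc_radius_mm: float = 40.0
    n_points_per_map: int = 1100
    fs_hz: float = 2000.0
    egm_noise_rms_mV: float = 0.01
    jitter_mm: float = 0.2
    full_maps: bool = True
    # signal processing
    bandpass_low_hz: float = 30.0
    bandpass_high_hz: float = 250.0
    noise_max_out_of_band_ratio: float = 1.0
    min_peak_to_peak_mV: float = 0.03
    min_slope_mV_per_ms: float = 0.02
    # interpolation
    idw_power: float = 2.0
    idw_k_nearest: int = 8
    idw_snap_eps_mm: float = 0.1
    idw_max_dist_mm: float = 10.0
    # CV constraints (relaxed edge band suits simulated point spacings)
    cv_d_min_mm: float = 1.5
    cv_d_max_mm: float = 10.0
    cv_min_delta_t_ms: float = 2.0
    cv_min_cv_m_per_s: float = 0.2
    cv_min_angle_deg: float = 30.0
    # cohort / survival
    cohort_sd_scale: float = 1.0
    kmeans_k: int = 3
    kmeans_n_init: int = 20
    cv_cut_m_per_s: float = 0.60
    voltage_cut_mV: float = 0.82

    @property
    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def to_file(self, path):
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise DatasetError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


# ------------------------------------------------------------------- datasets


def write_dataset(path, mesh: AtrialMesh, points, meta: dict) -> None:
    """Write a map dataset directory (see module docstring for the layout)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    meta = dict(meta)
    meta.setdefault("units", dict(EXPECTED_UNITS))
    meta.setdefault("tool", f"eamap {__version__}")
    meta["n_points"] = len(points)
    if "fs_hz" not in meta:
        raise DatasetError("meta must declare fs_hz")
    (path / "meta.json").write_text(json.dumps(meta, sort_keys=True, indent=2))

    tm = trimesh.Trimesh(mesh.vertices, mesh.triangles, process=False)
    (path / "mesh.ply").write_bytes(tm.export(file_type="ply", encoding="ascii"))
    vdf = pd.DataFrame({"region": mesh.region})
    for name, vals in mesh.fields.items():
        vdf[name] = vals
    vdf.to_csv(path / "vertex_data.csv", index=False, float_format="%.10g")

    rows = []
    bip, uni = [], []
    for i, p in enumerate(points):
        rows.append(
            {
                "point_id": i,
                "x_mm": p.position[0],
                "y_mm": p.position[1],
                "z_mm": p.position[2],
                "t0_ms": p.bipolar.t0_ms if p.bipolar is not None else np.nan,
                "lat_ms": p.lat_ms,
                "bip_mV": p.bip_mV,
                "uni_mV": p.uni_mV,
                "quality": p.quality,
                "true_lat_ms": np.nan if p.true_lat_ms is None else p.true_lat_ms,
                "true_bip_mV": np.nan if p.true_bip_mV is None else p.true_bip_mV,
            }
        )
        if p.bipolar is not None:
            bip.append(p.bipolar.samples)
        if p.unipolar is not None:
            uni.append(p.unipolar.samples)
    pd.DataFrame(rows).to_csv(path / "points.csv", index=False, float_format="%.10g")
    if bip:
        np.savetxt(path / "traces_bipolar.csv", np.vstack(bip), fmt="%.9g",
                   delimiter=",")
    if uni:
        np.savetxt(path / "traces_unipolar.csv", np.vstack(uni), fmt="%.9g",
                   delimiter=",")


def read_dataset(path):
    """Read and validate a map dataset directory.

    Returns ``(mesh, points, meta)``.  Unit declarations must match the
    package's fixed units exactly; a missing sampling rate is an error; a map
    with fewer than 1,000 points loads with ``meta['low_density'] = True``
    and a warning (small synthetic fixtures are legitimate).
    """
    path = Path(path)
    meta_file = path / "meta.json"
    if not meta_file.exists():
        raise DatasetError(f"{path}: missing meta.json")
    meta = json.loads(meta_file.read_text())
    if "fs_hz" not in meta or not meta["fs_hz"] or meta["fs_hz"] <= 0:
        raise DatasetError(f"{path}: meta.json must declare a positive fs_hz")
    units = meta.get("units")
    if units != EXPECTED_UNITS:
        raise DatasetError(
            f"{path}: unit declaration {units!r} does not match required "
            f"{EXPECTED_UNITS!r} (units are validated, never coerced)"
        )
    tm = trimesh.load(path / "mesh.ply", process=False)
    vdf = pd.read_csv(path / "vertex_data.csv")
    if len(vdf) != len(tm.vertices):
        raise DatasetError(
            f"{path}: vertex_data.csv has {len(vdf)} rows for "
            f"{len(tm.vertices)} mesh vertices"
        )
    fields = {
        c: vdf[c].to_numpy(dtype=float) for c in vdf.columns if c != "region"
    }
    mesh = AtrialMesh(
        np.asarray(tm.vertices), np.asarray(tm.faces), vdf["region"].to_numpy(),
        fields,
    )

    pdf = pd.read_csv(path / "points.csv")
    required = {"point_id", "x_mm", "y_mm", "z_mm"}
    missing = required - set(pdf.columns)
    if missing:
        raise DatasetError(f"{path}: points.csv missing columns {sorted(missing)}")
    fs = float(meta["fs_hz"])
    bip_path = path / "traces_bipolar.csv"
    uni_path = path / "traces_unipolar.csv"
    bip = np.loadtxt(bip_path, delimiter=",", ndmin=2) if bip_path.exists() else None
    uni = np.loadtxt(uni_path, delimiter=",", ndmin=2) if uni_path.exists() else None
    if bip is not None and len(bip) != len(pdf):
        raise DatasetError(f"{path}: trace row count does not match points.csv")
    points = []
    for i, row in pdf.iterrows():
        t0 = float(row.get("t0_ms", np.nan))
        points.append(
            MappingPoint(
                np.array([row["x_mm"], row["y_mm"], row["z_mm"]]),
                bipolar=(
                    ElectrogramTrace(bip[i], fs, "bipolar", t0)
                    if bip is not None else None
                ),
                unipolar=(
                    ElectrogramTrace(uni[i], fs, "unipolar", t0)
                    if uni is not None else None
                ),
                lat_ms=float(row.get("lat_ms", np.nan)),
                bip_mV=float(row.get("bip_mV", np.nan)),
                uni_mV=float(row.get("uni_mV", np.nan)),
                quality=str(row.get("quality", "accepted")),
                true_lat_ms=(
                    None if pd.isna(row.get("true_lat_ms")) else float(row["true_lat_ms"])
                ),
                true_bip_mV=(
                    None if pd.isna(row.get("true_bip_mV")) else float(row["true_bip_mV"])
                ),
            )
        )
    if len(points) < MIN_POINTS_RECOMMENDED:
        meta["low_density"] = True
        warnings.warn(
            f"{path}: {len(points)} mapping points is below the recommended "
            f"minimum of {MIN_POINTS_RECOMMENDED}",
            stacklevel=2,
        )
    return mesh, points, meta


# --------------------------------------------------------------- cohort tables


def write_cohort_table(path, df: pd.DataFrame, seed: int, config_hash: str):
    """CSV with a provenance comment header; byte-stable across reruns."""
    with open(path, "w") as fh:
        fh.write(f"# eamap {__version__} seed={seed} config_hash={config_hash}\n")
        df.to_csv(fh, index=False, float_format="%.10g")


def read_cohort_table(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")
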