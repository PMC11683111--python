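"""Mesh and mapping-point containers, field interpolation, and map summaries.

The atrial surface is a triangulated mesh in millimetres whose vertices carry
a region label (``body``, ``pv`` for pulmonary-vein ostia, ``laa`` for the
appendage) and named scalar fields (bipolar voltage in mV, conduction velocity
in m/s).  Mapping points are catheter measurements on that surface.  Scalar
values measured at points are spread onto the mesh by inverse-distance
weighting (IDW); map-level summaries (mean voltage, mean CV, low-value area
fractions) are computed area-weighted over the mapped surface.

Units are fixed throughout the package: positions mm, times ms, voltage mV,
speed m/s.  Because 1 mm/ms = 1 m/s, no conversion factors appear anywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "AtrialMesh",
    "MappingPoint",
    "MapSummary",
    "clip_regions",
    "interpolate_field",
    "area_fraction_below",
    "map_summary",
]

REGIONS = ("body", "pv", "laa")

#: Thresholds (value, field) behind the four relative-area substrate metrics:
#: bipolar voltage below 0.5 / 0.3 mV, conduction velocity below 0.6 / 0.4 m/s.
AREA_THRESHOLDS = {
    "area_bip_05_rel": ("bip_voltage", 0.5),
    "area_bip_03_rel": ("bip_voltage", 0.3),
    "area_cv_06_rel": ("cv", 0.6),
    "area_cv_04_rel": ("cv", 0.4),
}


@dataclass
class AtrialMesh:
    """Triangulated atrial surface with per-vertex labels and scalar fields.

    Parameters
    ----------
    vertices : (n, 3) float array, positions in mm.
    triangles : (m, 3) int array of vertex indices.
    region : (n,) array of region labels, one of ``body``/``pv``/``laa``.
    fields : mapping from field name to (n,) float array; NaN marks vertices
        outside the mapped region (no point close enough to interpolate from).
    """

    vertices: np.ndarray
    triangles: np.ndarray
    region: np.ndarray = None
    fields: dict = field(default_factory=dict)

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.triangles = np.asarray(self.triangles, dtype=int)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise ValueError("vertices must be (n, 3)")
        if self.triangles.size and (
            self.triangles.min() < 0 or self.triangles.max() >= len(self.vertices)
        ):
            raise ValueError("triangle indices out of range")
        if self.region is None:
            self.region = np.full(len(self.vertices), "body", dtype="<U4")
        else:
            self.region = np.asarray(self.region, dtype="<U4")
            if len(self.region) != len(self.vertices):
                raise ValueError("region labels must match vertex count")
            unknown = set(np.unique(self.region)) - set(REGIONS)
            if unknown:
                raise ValueError(f"unknown region labels: {sorted(unknown)}")
        areas = self.triangle_areas()
        if areas.size and areas.min() <= 0:
            raise ValueError("mesh contains zero-area triangles")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_triangles(self) -> int:
        return len(self.triangles)

    def triangle_areas(self) -> np.ndarray:
        """Per-triangle areas in mm^2."""
        p = self.vertices[self.triangles]
        cross = np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0])
        return 0.5 * np.linalg.norm(cross, axis=1)

    def total_area(self) -> float:
        return float(self.triangle_areas().sum())

    def triangle_centroids(self) -> np.ndarray:
        return self.vertices[self.triangles].mean(axis=1)

    def edges(self) -> np.ndarray:
        """Unique undirected edges as a (k, 2) index array."""
        e = np.vstack(
            [self.triangles[:, [0, 1]], self.triangles[:, [1, 2]], self.triangles[:, [2, 0]]]
        )
        e.sort(axis=1)
        return np.unique(e, axis=0)

    def copy(self) -> "AtrialMesh":
        return AtrialMesh(
            self.vertices.copy(),
            self.triangles.copy(),
            self.region.copy(),
            {k: v.copy() for k, v in self.fields.items()},
        )


@dataclass
class MappingPoint:
    """One catheter measurement: position plus electrogram-derived values.

    ``quality`` is ``accepted``, ``rejected_noise`` or ``rejected_amplitude``.
    ``true_lat_ms`` / ``true_bip_mV`` hold simulator ground truth when the
    point comes from the synthetic generator (None for imported data).
    """

    position: np.ndarray
    bipolar: object = None  # ElectrogramTrace
    unipolar: object = None
    lat_ms: float = np.nan
    bip_mV: float = np.nan
    uni_mV: float = np.nan
    quality: str = "accepted"
    true_lat_ms: float = None
    true_bip_mV: float = None

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,):
            raise ValueError("position must be a 3-vector (mm)")


def accepted_points(points: Iterable[MappingPoint]) -> list:
    return [p for p in points if p.quality == "accepted"]


def clip_regions(mesh: AtrialMesh) -> AtrialMesh:
    """Remove pulmonary-vein and appendage regions, returning the body submesh.

    Emulates the semi-automatic clipping of PV ostia and the LA appendage from
    the mapped geometry: any triangle touching a non-body vertex is dropped and
    vertices are re-indexed.  Fields and labels are carried over.

    Raises
    ------
    ValueError
        If no body-region triangle remains.
    """
    body = mesh.region == "body"
    keep_tri = body[mesh.triangles].all(axis=1)
    if not keep_tri.any():
        raise ValueError("clip_regions: body region is empty")
    tris = mesh.triangles[keep_tri]
    used = np.unique(tris)
    remap = np.full(mesh.n_vertices, -1, dtype=int)
    remap[used] = np.arange(len(used))
    return AtrialMesh(
        mesh.vertices[used],
        remap[tris],
        mesh.region[used],
        {k: v[used] for k, v in mesh.fields.items()},
    )


def interpolate_field(
    positions: np.ndarray,
    values: np.ndarray,
    mesh: AtrialMesh,
    power: float = 2.0,
    k_nearest: int = 8,
    snap_eps_mm: float = 0.1,
    max_dist_mm: float = 10.0,
) -> np.ndarray:
    """Inverse-distance-weighted interpolation of point values onto mesh vertices.

    Each vertex receives a weighted mean of its ``k_nearest`` data points with
    weights 1/d^power.  A vertex within ``snap_eps_mm`` of a data point takes
    that point's value exactly; a vertex farther than ``max_dist_mm`` from every
    data point is left unmapped (NaN) and excluded from all summaries.

    Returns the (n_vertices,) field array; the caller attaches it to
    ``mesh.fields`` under a name of its choosing.
    """
    positions = np.atleast_2d(np.asarray(positions, dtype=float))
    values = np.asarray(values, dtype=float)
    if len(positions) == 0:
        raise ValueError("interpolate_field: no accepted points")
    if len(positions) != len(values):
        raise ValueError("positions/values length mismatch")
    tree = cKDTree(positions)
    k = min(k_nearest, len(positions))
    dist, idx = tree.query(mesh.vertices, k=k)
    dist = np.atleast_2d(dist.T).T  # (n, k) even when k == 1
    idx = np.atleast_2d(idx.T).T
    out = np.full(mesh.n_vertices, np.nan)

    snapped = dist[:, 0] < snap_eps_mm
    out[snapped] = values[idx[snapped, 0]]

    todo = ~snapped & (dist[:, 0] <= max_dist_mm)
    if todo.any():
        d = dist[todo]
        v = values[idx[todo]]
        w = 1.0 / d**power
        w[d > max_dist_mm] = 0.0  # neighbours beyond the cut-off do not vote
        out[todo] = (w * v).sum(axis=1) / w.sum(axis=1)
    return out


def _triangle_values(mesh: AtrialMesh, field_values: np.ndarray):
    """Per-triangle mean field value and a mapped mask (all 3 vertices mapped)."""
    vals = np.asarray(field_values, dtype=float)[mesh.triangles]
    mapped = np.isfinite(vals).all(axis=1)
    return vals.mean(axis=1), mapped


def area_fraction_below(
    mesh: AtrialMesh, field_name: str, threshold: float
) -> float:
    """Fraction of the mapped surface area with field value below ``threshold``.

    A triangle's value is the mean of its three vertices; triangles with any
    unmapped vertex are excluded from both numerator and denominator, so the
    result is relative to the mapped area (the denominator Table-style
    ``_rel`` metrics use).
    """
    if field_name not in mesh.fields:
        raise KeyError(f"mesh has no field {field_name!r}")
    tri_val, mapped = _triangle_values(mesh, mesh.fields[field_name])
    areas = mesh.triangle_areas()
    mapped_area = areas[mapped].sum()
    if mapped_area == 0:
        raise ValueError("area_fraction_below: all vertices unmapped")
    low = mapped & (tri_val < threshold)
    return float(areas[low].sum() / mapped_area)


def _area_weighted_mean(mesh: AtrialMesh, field_name: str) -> float:
    tri_val, mapped = _triangle_values(mesh, mesh.fields[field_name])
    areas = mesh.triangle_areas()
    if not mapped.any():
        return float("nan")
    return float((tri_val[mapped] * areas[mapped]).sum() / areas[mapped].sum())


@dataclass
class MapSummary:
    """Per-map aggregates feeding a patient's cohort row.

    ``mean_bip_mV`` / ``mean_cv_m_per_s`` are area-weighted surface means
    (density-invariant); ``point_mean_bip_mV`` is the plain mean over accepted
    points, exposed because map-level "average voltage" is reported both ways
    in the field.
    """

    mean_bip_mV: float
    mean_uni_mV: float
    mean_cv_m_per_s: float
    point_mean_bip_mV: float
    area_bip_05_rel: float
    area_bip_03_rel: float
    area_cv_06_rel: float
    area_cv_04_rel: float
    n_points: int
    unmapped_area_frac: float


def map_summary(mesh: AtrialMesh, points: Sequence[MappingPoint] = ()) -> MapSummary:
    """Summarise a mapped mesh: surface-mean voltage/CV and low-value areas.

    Requires ``bip_voltage`` and ``cv`` fields on the mesh; ``uni_voltage`` is
    optional.  ``points`` (if given) supplies the accepted-point count and the
    point-averaged voltage.
    """
    for name in ("bip_voltage", "cv"):
        if name not in mesh.fields:
            raise KeyError(f"map_summary requires mesh field {name!r}")
    acc = accepted_points(points)
    areas = mesh.triangle_areas()
    _, mapped = _triangle_values(mesh, mesh.fields["bip_voltage"])
    fractions = {}
    for key, (fname, thr) in AREA_THRESHOLDS.items():
        fractions[key] = area_fraction_below(mesh, fname, thr)
    return MapSummary(
        mean_bip_mV=_area_weighted_mean(mesh, "bip_voltage"),
        mean_uni_mV=(
            _area_weighted_mean(mesh, "uni_voltage")
            if "uni_voltage" in mesh.fields
            else float("nan")
        ),
        mean_cv_m_per_s=_area_weighted_mean(mesh, "cv"),
        point_mean_bip_mV=(
            float(np.mean([p.bip_mV for p in acc])) if acc else float("nan")
        ),
        n_points=len(acc),
        unmapped_area_frac=float(areas[~mapped].sum() / areas.sum()),
        **fractions,
    )
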