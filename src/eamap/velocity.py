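"""Conduction-velocity estimation from LAT-annotated mapping points.

Triplets of points are selected by Delaunay triangulation (computed in local
tangent planes so curved atrial surfaces do not suffer 3-D tetrahedralisation
artefacts).  Each triple is fitted with a locally planar wavefront: writing
the slowness vector s (ms/mm) in the triangle plane, the activation-time
differences satisfy

    (p2 - p1) . s = t2 - t1,   (p3 - p1) . s = t3 - t1,

a 2x2 linear system; the conduction velocity is CV = 1/|s| (mm/ms = m/s) and
the propagation direction is s/|s|.  Four constraints then screen the
triples: edge length within [d_min, d_max]; maximum pairwise LAT difference
above 2 ms; fitted CV at or above the 0.2 m/s line-of-block floor (slower
triples mark conduction block and are excluded from the CV field); smallest
internal angle at least 30 degrees.  Accepted CVs are interpolated from the
triple centroids onto the mesh exactly as voltages are.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial import Delaunay, cKDTree
from scipy.spatial import QhullError

from .mapping import AtrialMesh, MappingPoint, accepted_points, interpolate_field

__all__ = [
    "CvConstraints",
    "CvTriple",
    "build_triples",
    "fit_triple_velocity",
    "apply_constraints",
    "cv_field",
    "triples_frame",
]

CONSTRAINT_NAMES = ("edge_distance", "delta_t", "min_cv", "min_angle")


@dataclass(frozen=True)
class CvConstraints:
    """The four triple-acceptance constraints with their clinical defaults.

    d_min_mm/d_max_mm : allowed edge-length band (1.5-2.0 mm by default,
        matched to closely spaced electrode pairs of a high-density catheter).
    min_delta_t_ms : the largest pairwise LAT difference must exceed this, so
        the triple genuinely spans a wavefront passage.
    min_cv_m_per_s : line-of-block floor; slower fits flag conduction block.
    min_angle_deg : smallest internal angle, rejecting needle triangles whose
        fits are ill-conditioned.
    """

    d_min_mm: float = 1.5
    d_max_mm: float = 2.0
    min_delta_t_ms: float = 2.0
    min_cv_m_per_s: float = 0.2
    min_angle_deg: float = 30.0

    @classmethod
    def relaxed(cls) -> "CvConstraints":
        """Wider edge band (1.5-10 mm) for sparser, e.g. simulated, samplings."""
        return cls(d_max_mm=10.0)


@dataclass
class CvTriple:
    """One Delaunay triple with its fitted wavefront and constraint flags.

    ``flags`` maps each constraint name to pass(True)/fail(False); ``accepted``
    requires all four.  ``cv_m_per_s`` is NaN when the fit is undefined (all
    three LATs equal: zero slowness, treated as above any finite speed).
    """

    point_ids: tuple
    positions: np.ndarray  # (3, 3) mm
    lats_ms: np.ndarray = None
    centroid: np.ndarray = None
    edge_lengths_mm: np.ndarray = None
    min_angle_deg: float = None
    cv_m_per_s: float = None
    direction: np.ndarray = None
    flags: dict = field(default_factory=dict)

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        if self.centroid is None:
            self.centroid = self.positions.mean(axis=0)
        if self.edge_lengths_mm is None or self.min_angle_deg is None:
            L, ang = _edge_geometry(self.positions[None])
            self.edge_lengths_mm = L[0]
            self.min_angle_deg = float(ang[0])

    @property
    def accepted(self) -> bool:
        return bool(self.flags) and all(self.flags.values())


def _edge_geometry(P: np.ndarray):
    """Edge lengths and minimum internal angle for (m, 3, 3) triangle stacks."""
    a = np.linalg.norm(P[:, 1] - P[:, 2], axis=1)
    b = np.linalg.norm(P[:, 0] - P[:, 2], axis=1)
    c = np.linalg.norm(P[:, 0] - P[:, 1], axis=1)
    L = np.stack([a, b, c], axis=1)
    # law of cosines, clipped for numerical safety
    with np.errstate(invalid="ignore", divide="ignore"):
        cosA = (b**2 + c**2 - a**2) / (2 * b * c)
        cosB = (a**2 + c**2 - b**2) / (2 * a * c)
        cosC = (a**2 + b**2 - c**2) / (2 * a * b)
    ang = np.degrees(np.arccos(np.clip(np.stack([cosA, cosB, cosC], 1), -1, 1)))
    return L, ang.min(axis=1)


def build_triples(points: Sequence, k_neighbors: int = 12) -> list:
    """Select point triplets by Delaunay triangulation in local tangent planes.

    ``points`` is a sequence of MappingPoint or an (n, 3) position array.  For
    every point, its ``k_neighbors`` nearest neighbours are projected onto the
    local PCA tangent plane and triangulated; triangles incident to the centre
    point are collected and de-duplicated globally.  On flat point sets this
    reproduces the global Delaunay triangulation.

    Raises ``ValueError`` for fewer than 3 points or a collinear set.
    """
    if len(points) and isinstance(points[0], MappingPoint):
        pos = np.array([p.position for p in points])
    else:
        pos = np.atleast_2d(np.asarray(points, dtype=float))
    n = len(pos)
    if n < 3:
        raise ValueError("build_triples needs at least 3 points")
    k = min(k_neighbors + 1, n)
    if n <= k:
        # whole cloud fits in one neighbourhood: a single global triangulation
        # (per-point unions could mix diagonals of co-circular quadrilaterals)
        centred = pos - pos.mean(axis=0)
        _, _, vt = np.linalg.svd(centred, full_matrices=False)
        try:
            tri = Delaunay(centred @ vt[:2].T)
        except QhullError as exc:
            raise ValueError("points are collinear; no triangulation") from exc
        triples = {tuple(sorted(int(i) for i in s)) for s in tri.simplices}
        return [CvTriple(point_ids=t, positions=pos[list(t)])
                for t in sorted(triples)]
    tree = cKDTree(pos)
    _, nbrs = tree.query(pos, k=k)
    nbrs = np.atleast_2d(nbrs)
    seen = set()
    for i in range(n):
        ids = nbrs[i]
        local = pos[ids]
        centred = local - local.mean(axis=0)
        # tangent plane = top-2 principal axes of the neighbourhood
        _, _, vt = np.linalg.svd(centred, full_matrices=False)
        uv = centred @ vt[:2].T
        try:
            tri = Delaunay(uv)
        except QhullError as exc:
            if n <= k:  # whole cloud degenerate, not just one neighbourhood
                raise ValueError("points are collinear; no triangulation") from exc
            continue
        centre_local = int(np.nonzero(ids == i)[0][0])
        for simplex in tri.simplices:
            if centre_local in simplex:
                seen.add(tuple(sorted(int(ids[j]) for j in simplex)))
    return [CvTriple(point_ids=t, positions=pos[list(t)]) for t in sorted(seen)]


def _fit_batch(P: np.ndarray, T: np.ndarray):
    """Vectorised planar-wavefront fit for (m, 3, 3) positions, (m, 3) LATs.

    Returns (cv, direction) where cv is in m/s (NaN when slowness is zero)
    and direction is the (m, 3) unit propagation direction in each triangle
    plane (NaN rows when undefined).
    """
    u = P[:, 1] - P[:, 0]
    w = P[:, 2] - P[:, 0]
    normal = np.cross(u, w)
    area2 = np.linalg.norm(normal, axis=1)
    if np.any(area2 <= 1e-12):
        raise ValueError("degenerate (zero-area) triangle in CV fit")
    e1 = u / np.linalg.norm(u, axis=1, keepdims=True)
    w_perp = w - (w * e1).sum(axis=1, keepdims=True) * e1
    e2 = w_perp / np.linalg.norm(w_perp, axis=1, keepdims=True)
    # 2x2 systems A s = dt in the (e1, e2) plane
    A = np.empty((len(P), 2, 2))
    A[:, 0, 0] = (u * e1).sum(axis=1)
    A[:, 0, 1] = (u * e2).sum(axis=1)
    A[:, 1, 0] = (w * e1).sum(axis=1)
    A[:, 1, 1] = (w * e2).sum(axis=1)
    dt = np.stack([T[:, 1] - T[:, 0], T[:, 2] - T[:, 0]], axis=1)
    s = np.linalg.solve(A, dt[..., None])[..., 0]  # slowness, ms/mm
    smag = np.linalg.norm(s, axis=1)
    with np.errstate(divide="ignore"):
        cv = np.where(smag > 1e-12, 1.0 / smag, np.nan)
    with np.errstate(invalid="ignore"):
        d3 = (s[:, :1] * e1 + s[:, 1:] * e2) / smag[:, None]
    d3[smag <= 1e-12] = np.nan
    return cv, d3


def fit_triple_velocity(triple: CvTriple, lats_ms) -> CvTriple:
    """Fit a planar wavefront to one triple, filling cv and direction.

    All-equal LATs give zero slowness: cv is NaN (undefined, effectively above
    any finite speed) and the triple cannot pass the delta-t constraint.
    """
    T = np.asarray(lats_ms, dtype=float).reshape(1, 3)
    if not np.all(np.isfinite(T)):
        raise ValueError("fit_triple_velocity needs three finite LATs")
    cv, d3 = _fit_batch(triple.positions[None], T)
    return replace(triple, lats_ms=T[0], cv_m_per_s=float(cv[0]),
                   direction=d3[0])


def apply_constraints(triple: CvTriple,
                      cfg: CvConstraints = CvConstraints()) -> CvTriple:
    """Evaluate the four acceptance constraints, filling ``triple.flags``.

    Flags never alter the fitted values; they only decide inclusion in the
    CV field.  An undefined cv (NaN, zero slowness) passes the line-of-block
    floor (it is not slow) but such triples always fail delta_t.
    """
    if triple.lats_ms is None:
        raise ValueError("apply_constraints requires a fitted triple")
    L = triple.edge_lengths_mm
    dts = np.abs(triple.lats_ms[:, None] - triple.lats_ms[None, :])
    cv = triple.cv_m_per_s
    flags = {
        "edge_distance": bool((L >= cfg.d_min_mm).all() and (L <= cfg.d_max_mm).all()),
        "delta_t": bool(dts.max() > cfg.min_delta_t_ms),
        "min_cv": bool(np.isnan(cv) or cv >= cfg.min_cv_m_per_s),
        "min_angle": bool(triple.min_angle_deg >= cfg.min_angle_deg),
    }
    return replace(triple, flags=flags)


def fit_and_screen(points: Sequence[MappingPoint],
                   cfg: CvConstraints = CvConstraints(),
                   k_neighbors: int = 12) -> list:
    """Convenience: build, fit and screen all triples from accepted points."""
    acc = accepted_points(points)
    triples = build_triples(acc)
    if not triples:
        return []
    P = np.stack([t.positions for t in triples])
    T = np.array([[acc[i].lat_ms for i in t.point_ids] for t in triples])
    cv, d3 = _fit_batch(P, T)
    out = []
    for j, t in enumerate(triples):
        t = replace(t, lats_ms=T[j], cv_m_per_s=float(cv[j]), direction=d3[j])
        out.append(apply_constraints(t, cfg))
    return out


def cv_field(triples: Sequence[CvTriple], mesh: AtrialMesh,
             **idw_kwargs) -> np.ndarray:
    """Interpolate accepted triples' CVs from their centroids onto the mesh.

    Raises ``ValueError`` naming the dominant failing constraint when no
    triple survives screening.
    """
    acc = [t for t in triples if t.accepted]
    if not acc:
        fails = {name: sum(1 for t in triples if t.flags and not t.flags[name])
                 for name in CONSTRAINT_NAMES}
        dominant = max(fails, key=fails.get) if any(fails.values()) else "none"
        raise ValueError(
            "cv_field: no accepted triples "
            f"(dominant failing constraint: {dominant}; counts {fails})"
        )
    centroids = np.stack([t.centroid for t in acc])
    values = np.array([t.cv_m_per_s for t in acc])
    return interpolate_field(centroids, values, mesh, **idw_kwargs)


def triples_frame(triples: Sequence[CvTriple]) -> pd.DataFrame:
    """Audit table: one row per triple with geometry, fit and per-flag columns."""
    rows = []
    for t in triples:
        row = {
            "id_a": t.point_ids[0], "id_b": t.point_ids[1], "id_c": t.point_ids[2],
            "cx_mm": t.centroid[0], "cy_mm": t.centroid[1], "cz_mm": t.centroid[2],
            "edge_min_mm": float(t.edge_lengths_mm.min()),
            "edge_max_mm": float(t.edge_lengths_mm.max()),
            "min_angle_deg": t.min_angle_deg,
            "cv_m_per_s": t.cv_m_per_s,
            "accepted": t.accepted,
        }
        for name in CONSTRAINT_NAMES:
            row[f"pass_{name}"] = bool(t.flags.get(name, False))
        rows.append(row)
    return pd.DataFrame(rows)
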