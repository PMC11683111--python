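"""Ground-truth simulator: meshes, wavefronts, electrograms, and cohorts.

Every downstream stage of the analysis (LAT annotation, voltage mapping, CV
triangulation, phenotype clustering, survival) is validated against data from
this module, where the truth is known by construction:

* left-atrium-like surfaces (a flat disc, or a scaled icosphere "ellipsoid")
  with labelled pulmonary-vein / appendage patches;
* activation fields — planar waves (LAT is an exact linear function of
  position) or focal spread over regionally varying speed, solved by a
  shortest-travel-time front propagation on the mesh edge graph;
* bipolar/unipolar electrograms whose steepest downslope falls exactly at the
  prescribed LAT and whose pre-noise peak-to-peak equals the prescribed
  amplitude (Gaussian-derivative bipolar wavelet, Ricker unipolar);
* a 52-patient cohort with three voltage/CV phenotype clusters and
  cluster-dependent 24-month recurrence.

Units: positions mm, times ms, voltage mV, speed m/s (1 mm/ms = 1 m/s).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field
from typing import Optional, Sequence

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import dijkstra
from scipy.spatial import Delaunay, cKDTree

from .cohort import PatientSummary
from .mapping import AtrialMesh, MappingPoint

__all__ = [
    "GroundTruthField",
    "RegionPatch",
    "EgmNoise",
    "CohortSpec",
    "make_mesh",
    "make_speed_field",
    "make_amplitude_field",
    "simulate_activation",
    "synthesize_egm",
    "sample_mapping_points",
    "generate_cohort",
]

SPEED_RANGE_M_PER_S = (0.05, 3.0)


@dataclass
class GroundTruthField:
    """Per-vertex ground truth: activation time, local speed, amplitude."""

    mesh: AtrialMesh
    lat_ms: np.ndarray
    speed_m_per_s: np.ndarray
    amplitude_mV: np.ndarray

    def __post_init__(self):
        n = self.mesh.n_vertices
        self.lat_ms = np.asarray(self.lat_ms, dtype=float)
        self.speed_m_per_s = np.broadcast_to(
            np.asarray(self.speed_m_per_s, dtype=float), (n,)
        ).copy()
        self.amplitude_mV = np.broadcast_to(
            np.asarray(self.amplitude_mV, dtype=float), (n,)
        ).copy()
        body = self.mesh.region == "body"
        if not np.all(np.isfinite(self.lat_ms[body])):
            raise ValueError("lat must be finite on all body vertices")
        if np.any(self.speed_m_per_s <= 0):
            raise ValueError("speed must be strictly positive")
        if np.any(self.amplitude_mV < 0):
            raise ValueError("amplitude must be non-negative")


@dataclass(frozen=True)
class RegionPatch:
    """A labelled patch: vertices within ``radius_mm`` of ``center`` (mm)."""

    label: str  # "pv" or "laa"
    center: tuple
    radius_mm: float


@dataclass(frozen=True)
class EgmNoise:
    """Additive contamination for synthetic electrograms.

    rms_mV : white-noise RMS added to both channels.
    artefact_hz / artefact_rms_mV : optional high-frequency sinusoidal
        artefact (for exercising the noise-exclusion screen).
    """

    rms_mV: float = 0.0
    artefact_hz: Optional[float] = None
    artefact_rms_mV: float = 0.0


# ----------------------------------------------------------------------- mesh


def _disc_mesh(radius_mm: float, resolution_mm: float) -> AtrialMesh:
    h = resolution_mm
    pts = [(0.0, 0.0)]
    j = 0
    y = 0.0
    row_h = h * math.sqrt(3) / 2
    jmax = int(radius_mm / row_h) + 2
    for j in range(-jmax, jmax + 1):
        y = j * row_h
        x_off = 0.5 * h if j % 2 else 0.0
        imax = int(radius_mm / h) + 2
        for i in range(-imax, imax + 1):
            x = i * h + x_off
            if (x, y) == (0.0, 0.0):
                continue
            if math.hypot(x, y) <= radius_mm - 0.6 * h:
                pts.append((x, y))
    n_b = max(8, int(round(2 * math.pi * radius_mm / h)))
    for kk in range(n_b):
        th = 2 * math.pi * kk / n_b
        pts.append((radius_mm * math.cos(th), radius_mm * math.sin(th)))
    xy = np.array(pts)
    tri = Delaunay(xy)
    verts = np.column_stack([xy, np.zeros(len(xy))])
    # drop numerically degenerate slivers along the rim
    p = verts[tri.simplices]
    areas = 0.5 * np.linalg.norm(
        np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0]), axis=1
    )
    return AtrialMesh(verts, tri.simplices[areas > 1e-9])


def _ellipsoid_mesh(axes_mm, resolution_mm: float) -> AtrialMesh:
    import trimesh

    r_mean = float(np.mean(axes_mm))
    subdiv = 1
    while 1.0514 * r_mean / (2**subdiv) > resolution_mm and subdiv < 7:
        subdiv += 1
    sphere = trimesh.creation.icosphere(subdivisions=subdiv, radius=1.0)
    verts = np.asarray(sphere.vertices) * np.asarray(axes_mm, dtype=float)
    return AtrialMesh(verts, np.asarray(sphere.faces))


def make_mesh(
    shape: str = "disc",
    resolution_mm: float = 2.0,
    radius_mm: float = 40.0,
    axes_mm: Sequence[float] = (35.0, 28.0, 22.0),
    region_spec: Optional[Sequence[RegionPatch]] = None,
) -> AtrialMesh:
    """Build a triangulated test surface with optional PV/LAA patches.

    ``disc``: a flat disc of the given radius, triangulated at target edge
    length ``resolution_mm`` (hex lattice interior + exact-radius rim, so the
    total area matches pi r^2 to well under 1%).  ``ellipsoid``: a scaled
    icosphere.  Vertices inside any ``RegionPatch`` sphere are labelled with
    the patch label; all others are ``body``.
    """
    if resolution_mm <= 0:
        raise ValueError("resolution must be positive")
    if shape == "disc":
        if radius_mm / resolution_mm < 1:
            raise ValueError("resolution too coarse for the requested disc")
        mesh = _disc_mesh(radius_mm, resolution_mm)
    elif shape == "ellipsoid":
        mesh = _ellipsoid_mesh(axes_mm, resolution_mm)
    else:
        raise ValueError(f"unknown shape {shape!r}")
    if mesh.n_vertices < 4:
        raise ValueError("degenerate resolution: fewer than 4 vertices")
    if region_spec:
        for patch in region_spec:
            if patch.label not in ("pv", "laa"):
                raise ValueError(f"region patch label must be pv/laa, got {patch.label}")
            d = np.linalg.norm(mesh.vertices - np.asarray(patch.center), axis=1)
            mesh.region[d <= patch.radius_mm] = patch.label
    return mesh


def make_speed_field(
    mesh: AtrialMesh,
    background_m_per_s: float = 0.8,
    patches: Sequence[tuple] = (),
) -> np.ndarray:
    """Per-vertex speed: a background value with slow/fast spherical patches.

    ``patches`` is a sequence of ``(center_xyz, radius_mm, speed_m_per_s)``.
    """
    speed = np.full(mesh.n_vertices, float(background_m_per_s))
    for center, radius, value in patches:
        d = np.linalg.norm(mesh.vertices - np.asarray(center, float), axis=1)
        speed[d <= radius] = float(value)
    _check_speeds(speed)
    return speed


def _vertex_weights(mesh: AtrialMesh) -> np.ndarray:
    """Barycentric vertex areas (1/3 of each incident triangle)."""
    areas = mesh.triangle_areas()
    w = np.zeros(mesh.n_vertices)
    np.add.at(w, mesh.triangles.ravel(), np.repeat(areas / 3.0, 3))
    return w


def make_amplitude_field(
    mesh: AtrialMesh,
    mean_mV: float = 1.2,
    n_low_patches: int = 3,
    patch_radius_mm: float = 8.0,
    low_scale: float = 0.2,
    smooth_scale_mm: float = 25.0,
    seed: Optional[int] = None,
) -> np.ndarray:
    """Spatially varying bipolar amplitude with low-voltage patches.

    A smooth long-wavelength field (sum of broad Gaussian bumps) multiplied
    down inside ``n_low_patches`` randomly placed fibrosis-like patches, then
    rescaled so the area-weighted surface mean equals ``mean_mV``.
    """
    rng = np.random.default_rng(seed)
    v = np.ones(mesh.n_vertices)
    for _ in range(4):  # gentle large-scale heterogeneity
        c = mesh.vertices[rng.integers(mesh.n_vertices)]
        d = np.linalg.norm(mesh.vertices - c, axis=1)
        v += 0.3 * rng.standard_normal() * np.exp(-(d**2) / (2 * smooth_scale_mm**2))
    for _ in range(n_low_patches):
        c = mesh.vertices[rng.integers(mesh.n_vertices)]
        d = np.linalg.norm(mesh.vertices - c, axis=1)
        v *= 1.0 - (1.0 - low_scale) * np.exp(-(d**2) / (2 * (patch_radius_mm / 2) ** 2))
    v = np.clip(v, 0.02, None)
    w = _vertex_weights(mesh)
    v *= mean_mV / float((v * w).sum() / w.sum())
    return v


# ----------------------------------------------------------- activation fields


def _check_speeds(speed):
    lo, hi = SPEED_RANGE_M_PER_S
    s = np.asarray(speed, dtype=float)
    if np.any(s < lo) or np.any(s > hi):
        raise ValueError(f"speeds must lie within [{lo}, {hi}] m/s")


def _travel_time_graph(mesh: AtrialMesh, slowness: np.ndarray) -> csr_matrix:
    """Edge graph for front propagation.

    Besides the triangle edges, each pair of vertices opposite a shared edge
    is connected ("crossing" links), which substantially reduces the metric
    anisotropy of shortest-path travel times on the lattice.
    """
    edges = mesh.edges()
    extra = {}
    tri = mesh.triangles
    for t in tri:
        for k in range(3):
            e = tuple(sorted((int(t[k]), int(t[(k + 1) % 3]))))
            extra.setdefault(e, []).append(int(t[(k + 2) % 3]))
    cross = [
        tuple(sorted((opp[0], opp[1])))
        for opp in extra.values()
        if len(opp) == 2 and opp[0] != opp[1]
    ]
    if cross:
        edges = np.vstack([edges, np.unique(np.array(cross), axis=0)])
    i, j = edges[:, 0], edges[:, 1]
    length = np.linalg.norm(mesh.vertices[i] - mesh.vertices[j], axis=1)
    w = length * 0.5 * (slowness[i] + slowness[j])  # ms
    n = mesh.n_vertices
    return csr_matrix((w, (i, j)), shape=(n, n))


def simulate_activation(
    mesh: AtrialMesh,
    mode: str = "planar",
    speed_m_per_s=0.7,
    origin=None,
    direction=(1.0, 0.0, 0.0),
    amplitude_mV=1.0,
) -> GroundTruthField:
    """Simulate sinus-rhythm-like activation of the surface.

    planar : a plane wave at constant speed along ``direction`` (auto
        normalised); LAT is the projected distance divided by the speed.
    focal : spread from ``origin`` (a 3-D point on or near the surface) with
        per-vertex ``speed_m_per_s``; LATs are shortest travel times over the
        augmented edge graph, so patchy speed fields are honoured.

    The earliest vertex is shifted to LAT = 0.
    """
    _check_speeds(speed_m_per_s)
    if mode == "planar":
        if np.ndim(speed_m_per_s) != 0:
            raise ValueError("planar mode needs a single scalar speed")
        d = np.asarray(direction, dtype=float)
        nrm = np.linalg.norm(d)
        if nrm == 0:
            raise ValueError("direction must be non-zero")
        d = d / nrm
        proj = mesh.vertices @ d
        lat = (proj - proj.min()) / float(speed_m_per_s)  # mm / (mm/ms) = ms
        speed = np.full(mesh.n_vertices, float(speed_m_per_s))
    elif mode == "focal":
        if origin is None:
            raise ValueError("focal mode needs an origin")
        origin = np.asarray(origin, dtype=float)
        d2 = np.linalg.norm(mesh.vertices - origin, axis=1)
        src = int(np.argmin(d2))
        edge_scale = np.median(
            np.linalg.norm(
                mesh.vertices[mesh.edges()[:, 0]] - mesh.vertices[mesh.edges()[:, 1]],
                axis=1,
            )
        )
        if d2[src] > 2.0 * edge_scale:
            raise ValueError("origin lies off the mesh surface")
        speed = np.broadcast_to(
            np.asarray(speed_m_per_s, dtype=float), (mesh.n_vertices,)
        ).copy()
        graph = _travel_time_graph(mesh, 1.0 / speed)
        lat = dijkstra(graph, directed=False, indices=src)
        lat -= lat[np.isfinite(lat)].min()
    else:
        raise ValueError(f"unknown activation mode {mode!r}")
    return GroundTruthField(mesh, lat, speed, amplitude_mV)


# ----------------------------------------------------------------- electrograms

#: bipolar wavelet: f(t) = -A x e^{-x^2/2}, x=(t-lat)/sigma.  Peak-to-peak is
#: 2 A e^{-1/2}; the first derivative attains its minimum exactly at t = lat.
_BIP_PP = 2.0 * math.exp(-0.5)
#: unipolar Ricker r(x) = (1-x^2) e^{-x^2/2}: max 1 at x=0, min -2e^{-3/2}.
_UNI_PP = 1.0 + 2.0 * math.exp(-1.5)


def _egm_templates(t_ms: np.ndarray, lat_ms: np.ndarray, amp_bip: np.ndarray,
                   amp_uni: np.ndarray, sigma_ms: float):
    x = (t_ms - lat_ms[:, None]) / sigma_ms
    env = np.exp(-0.5 * x**2)
    bip = (amp_bip[:, None] / _BIP_PP) * (-x) * env
    uni = (amp_uni[:, None] / _UNI_PP) * (1 - x**2) * env
    return bip, uni


def synth_egm_batch(
    lats_ms: np.ndarray,
    amps_mV: np.ndarray,
    fs_hz: float = 2000.0,
    duration_ms: float = 200.0,
    width_ms: float = 20.0,
    uni_ratio: float = 1.63,
    noise: EgmNoise = EgmNoise(),
    rng: Optional[np.random.Generator] = None,
):
    """Vectorised electrogram synthesis; one lat-centred trace pair per row.

    Returns (bip, uni, t0_ms): 2-D sample arrays plus each trace's start time.
    The window is centred on the activation so every LAT lies mid-trace.
    """
    if fs_hz < 500:
        raise ValueError("sampling rate must be at least 500 Hz")
    lats_ms = np.atleast_1d(np.asarray(lats_ms, dtype=float))
    amps_mV = np.atleast_1d(np.asarray(amps_mV, dtype=float))
    if np.any(amps_mV < 0):
        raise ValueError("amplitude must be non-negative")
    n_samp = int(round(duration_ms * fs_hz / 1000.0))
    t0 = lats_ms - duration_ms / 2.0
    rel_t = np.arange(n_samp) * 1000.0 / fs_hz
    t = t0[:, None] + rel_t[None, :]
    sigma = width_ms / 8.0  # lobes at +-sigma, support ~ +-width/2
    bip, uni = _egm_templates(t, lats_ms, amps_mV, uni_ratio * amps_mV, sigma)
    if noise.rms_mV > 0:
        if rng is None:
            rng = np.random.default_rng()
        bip = bip + rng.normal(0.0, noise.rms_mV, bip.shape)
        uni = uni + rng.normal(0.0, noise.rms_mV, uni.shape)
    if noise.artefact_hz and noise.artefact_rms_mV > 0:
        art = noise.artefact_rms_mV * math.sqrt(2) * np.sin(
            2 * math.pi * noise.artefact_hz * t / 1000.0
        )
        bip = bip + art
    return bip, uni, t0


def synthesize_egm(
    lat_ms: float,
    amplitude_mV: float,
    fs_hz: float = 2000.0,
    noise: EgmNoise = EgmNoise(),
    seed: Optional[int] = None,
    duration_ms: float = 200.0,
    width_ms: float = 20.0,
    uni_ratio: float = 1.63,
):
    """Synthesize one (bipolar, unipolar) electrogram trace pair.

    The bipolar wavelet is biphasic (positive then steep negative lobe, total
    width ~``width_ms``); its steepest downslope falls exactly at ``lat_ms``
    and its pre-noise peak-to-peak equals ``amplitude_mV``.  Deterministic for
    a fixed ``seed``.
    """
    from .egm import ElectrogramTrace

    rng = np.random.default_rng(seed)
    bip, uni, t0 = synth_egm_batch(
        [lat_ms], [amplitude_mV], fs_hz, duration_ms, width_ms, uni_ratio,
        noise, rng,
    )
    return (
        ElectrogramTrace(bip[0], fs_hz, "bipolar", float(t0[0])),
        ElectrogramTrace(uni[0], fs_hz, "unipolar", float(t0[0])),
    )


# --------------------------------------------------------------- point sampling


def sample_mapping_points(
    mesh: AtrialMesh,
    truth: GroundTruthField,
    n_points: int = 1200,
    jitter_mm: float = 0.0,
    fs_hz: float = 2000.0,
    noise: EgmNoise = EgmNoise(),
    seed: Optional[int] = None,
    synth_traces: bool = True,
    density_cap_per_mm2: float = 5.0,
) -> list:
    """Draw mapping points area-uniformly on the body region.

    Each point carries electrograms synthesized from the local ground-truth
    LAT/amplitude (barycentric interpolation within its triangle) plus the
    truth values themselves for recovery tests.  ``jitter_mm`` displaces the
    recorded position (catheter localisation error) without changing the
    truth the electrogram encodes.  With ``synth_traces=False`` the points
    carry the true LAT/amplitude directly as annotated values.
    """
    if n_points < 1:
        raise ValueError("n_points must be >= 1")
    body_tri = (mesh.region[mesh.triangles] == "body").all(axis=1)
    if not body_tri.any():
        raise ValueError("mesh has no body-region triangles to sample")
    areas = mesh.triangle_areas()
    body_area = areas[body_tri].sum()
    if n_points > density_cap_per_mm2 * body_area:
        raise ValueError(
            f"n_points={n_points} exceeds the density cap "
            f"({density_cap_per_mm2}/mm^2 over {body_area:.0f} mm^2)"
        )
    rng = np.random.default_rng(seed)
    tri_idx = np.nonzero(body_tri)[0]
    probs = areas[body_tri] / body_area
    chosen = rng.choice(tri_idx, size=n_points, p=probs)
    r1 = np.sqrt(rng.random(n_points))
    r2 = rng.random(n_points)
    bary = np.column_stack([1 - r1, r1 * (1 - r2), r1 * r2])
    corners = mesh.vertices[mesh.triangles[chosen]]
    pos = np.einsum("ij,ijk->ik", bary, corners)
    lat = np.einsum("ij,ij->i", bary, truth.lat_ms[mesh.triangles[chosen]])
    amp = np.einsum("ij,ij->i", bary, truth.amplitude_mV[mesh.triangles[chosen]])
    if jitter_mm > 0:
        pos = pos + rng.normal(0.0, jitter_mm, pos.shape)

    points = []
    if synth_traces:
        from .egm import ElectrogramTrace

        bip, uni, t0 = synth_egm_batch(lat, amp, fs_hz, noise=noise, rng=rng)
        for i in range(n_points):
            points.append(
                MappingPoint(
                    pos[i],
                    bipolar=ElectrogramTrace(bip[i], fs_hz, "bipolar", float(t0[i])),
                    unipolar=ElectrogramTrace(uni[i], fs_hz, "unipolar", float(t0[i])),
                    true_lat_ms=float(lat[i]),
                    true_bip_mV=float(amp[i]),
                )
            )
    else:
        for i in range(n_points):
            points.append(
                MappingPoint(
                    pos[i],
                    lat_ms=float(lat[i]),
                    bip_mV=float(amp[i]),
                    uni_mV=1.63 * float(amp[i]),
                    true_lat_ms=float(lat[i]),
                    true_bip_mV=float(amp[i]),
                )
            )
    return points


# --------------------------------------------------------------------- cohorts


@dataclass
class CohortSpec:
    """Statistical recipe for a synthetic AF phenotype cohort.

    Three clusters, ordered as in the clinical phenotype description:
    0 = normal CV / normal voltage, 1 = slow CV / normal voltage,
    2 = slow CV / low voltage.  Sizes default to 30/12/10 of a 52-patient
    cohort.  ``recurrence_24mo`` is each cluster's probability of arrhythmia
    recurrence within the 24-month follow-up; event times are exponential
    with the matching rate, and patients event-free at the horizon are
    censored uniformly over (0, 24] months.  Voltage/CV means and SDs are an
    emulation chosen from printed group statistics, not measured cluster
    parameters (none are published).
    """

    n_patients: int = 52
    cluster_sizes: tuple = (30, 12, 10)
    cluster_voltage_mV: tuple = ((1.6, 0.35), (1.35, 0.25), (0.55, 0.12))
    cluster_cv_m_per_s: tuple = ((0.75, 0.07), (0.52, 0.06), (0.45, 0.06))
    recurrence_24mo: tuple = (0.25, 1.0 / 3.0, 0.60)
    persistent_frac: tuple = (1.0 / 3.0, 0.417, 0.50)
    comorbidity_mean: tuple = (1.2, 1.8, 2.6)
    lavi_ml_per_m2: tuple = (33.15, 39.25, 40.40)
    lavi_sd: float = 8.0
    age_mean_sd: tuple = (56.9, 12.2)
    follow_up_months: float = 24.0
    censor_horizon_months: float = 36.0  # dropout ~ U(0, horizon), capped at follow-up
    sd_scale: float = 1.0  # multiplies every voltage/CV SD (0 -> degenerate)
    seed: int = 0

    def validate(self):
        if sum(self.cluster_sizes) != self.n_patients:
            raise ValueError("cluster_sizes must sum to n_patients")
        if any(s < 1 for s in self.cluster_sizes):
            raise ValueError("every cluster needs at least one patient")
        for mean, sd in (*self.cluster_voltage_mV, *self.cluster_cv_m_per_s):
            if sd < 0 or mean <= 0:
                raise ValueError("cluster means must be positive, SDs non-negative")
        for p in self.recurrence_24mo:
            if not (0 <= p < 1):
                raise ValueError("recurrence probabilities must lie in [0, 1)")
        if self.follow_up_months <= 0:
            raise ValueError("follow-up must be positive")


def generate_cohort(spec: CohortSpec = CohortSpec()) -> list:
    """Generate per-patient summaries with known cluster structure.

    Substrate area fractions are derived from each patient's mean voltage/CV
    through smooth decreasing maps (plus noise) calibrated to the printed
    cohort medians, so the summaries carry realistic covariation; the true
    cluster label is retained for adjusted-Rand-index scoring.
    Bit-reproducible for a fixed ``spec.seed``.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    fu = spec.follow_up_months
    out = []
    pid = 0
    for c, size in enumerate(spec.cluster_sizes):
        v_mu, v_sd = spec.cluster_voltage_mV[c]
        cv_mu, cv_sd = spec.cluster_cv_m_per_s[c]
        p_rec = spec.recurrence_24mo[c]
        rate = -math.log(1.0 - p_rec) / fu if p_rec > 0 else 0.0
        for _ in range(size):
            pid += 1
            v = max(0.05, rng.normal(v_mu, v_sd * spec.sd_scale))
            cv = max(0.1, rng.normal(cv_mu, cv_sd * spec.sd_scale))
            a05 = float(np.clip(0.95 * math.exp(-1.2 * v) + rng.normal(0, 0.03), 0, 1))
            a03 = float(np.clip(0.74 * a05 + rng.normal(0, 0.02), 0, 1))
            a06 = float(np.clip(2.31 * math.exp(-3.0 * cv) + rng.normal(0, 0.04), 0, 1))
            a04 = float(np.clip(0.47 * a06 + rng.normal(0, 0.02), 0, 1))
            if rate > 0:
                t_event = rng.exponential(1.0 / rate)
            else:
                t_event = math.inf
            if t_event <= fu:
                event, t_obs = 1, t_event
            else:
                # event-free at the horizon: censored at 24 months unless the
                # patient dropped out earlier (uniform dropout hazard chosen to
                # reproduce an ~19 +- 11 month observed follow-up mix)
                dropout = spec.censor_horizon_months * (1.0 - rng.random())
                event, t_obs = 0, min(fu, dropout)
            out.append(
                PatientSummary(
                    patient_id=f"P{pid:03d}",
                    group=(
                        "AF_persistent"
                        if rng.random() < spec.persistent_frac[c]
                        else "AF_paroxysmal"
                    ),
                    mean_bip_mV=float(v),
                    mean_uni_mV=float(v * 1.63 * (1 + rng.normal(0, 0.05))),
                    mean_cv_m_per_s=float(cv),
                    area_bip_05_rel=a05,
                    area_bip_03_rel=a03,
                    area_cv_06_rel=a06,
                    area_cv_04_rel=a04,
                    n_points=int(max(1000, round(rng.normal(1654.2, 874.5)))),
                    age_years=float(np.clip(rng.normal(*spec.age_mean_sd), 18, 95)),
                    n_comorbidities=int(min(rng.poisson(spec.comorbidity_mean[c]), 6)),
                    lavi_ml_per_m2=float(
                        max(15.0, rng.normal(spec.lavi_ml_per_m2[c], spec.lavi_sd))
                    ),
                    event=event,
                    time_months=float(t_obs),
                    true_cluster=c,
                )
            )
    return out
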