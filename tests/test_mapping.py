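"""Mesh containers, region clipping, IDW interpolation, and map summaries."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import eamap
from eamap.mapping import (
    AtrialMesh,
    area_fraction_below,
    clip_regions,
    interpolate_field,
    map_summary,
)


def square_mesh(n=11, size=20.0):
    """Regular triangulated square in the z=0 plane, side ``size`` mm."""
    xs = np.linspace(0, size, n)
    gx, gy = np.meshgrid(xs, xs)
    verts = np.column_stack([gx.ravel(), gy.ravel(), np.zeros(n * n)])
    tris = []
    for j in range(n - 1):
        for i in range(n - 1):
            a = j * n + i
            tris.append([a, a + 1, a + n])
            tris.append([a + 1, a + n + 1, a + n])
    return AtrialMesh(verts, np.array(tris))


class TestMeshInvariants:
    def test_rejects_bad_indices(self):
        with pytest.raises(ValueError):
            AtrialMesh(np.zeros((3, 3)), np.array([[0, 1, 5]]))

    def test_rejects_zero_area_triangle(self):
        v = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0.0]])
        with pytest.raises(ValueError):
            AtrialMesh(v, np.array([[0, 1, 2]]))

    def test_area_bookkeeping(self):
        m = square_mesh()
        assert m.total_area() == pytest.approx(400.0)


class TestClipRegions:
    def test_labelled_area_removed(self):
        m = eamap.make_mesh(
            "disc", 2.0, 40.0,
            region_spec=[eamap.RegionPatch("pv", (30.0, 0.0, 0.0), 10.0)],
        )
        total = m.total_area()
        clipped = clip_regions(m)
        # removed cap ~ patch disc area; allow one triangle ring of slack
        removed = total - clipped.total_area()
        assert removed > 0
        assert removed == pytest.approx(np.pi * 100.0, rel=0.35)
        assert (clipped.region == "body").all()

    def test_all_body_identity(self, coarse_disc):
        clipped = clip_regions(coarse_disc)
        assert clipped.total_area() == pytest.approx(coarse_disc.total_area())
        assert clipped.n_triangles == coarse_disc.n_triangles

    def test_all_pv_errors(self):
        m = eamap.make_mesh("disc", 4.0, 20.0)
        m.region[:] = "pv"
        with pytest.raises(ValueError):
            clip_regions(m)


class TestInterpolateField:
    def test_single_point_constant_field(self, coarse_disc):
        f = interpolate_field(
            np.array([[0.0, 0.0, 0.0]]), np.array([1.2]), coarse_disc,
            max_dist_mm=100.0,
        )
        assert np.allclose(f, 1.2)

    def test_exact_at_coincident_vertex(self, coarse_disc):
        target = coarse_disc.vertices[7]
        f = interpolate_field(
            np.array([target, [5.0, 5.0, 0.0]]), np.array([0.9, 0.1]),
            coarse_disc,
        )
        assert f[7] == pytest.approx(0.9, abs=1e-12)

    def test_equidistant_average(self):
        m = square_mesh(3, 2.0)  # vertices at 0,1,2 mm
        pts = np.array([[0.0, 1.0, 0.0], [2.0, 1.0, 0.0]])
        f = interpolate_field(pts, np.array([0.4, 0.8]), m)
        centre = np.where((m.vertices[:, 0] == 1.0) & (m.vertices[:, 1] == 1.0))[0][0]
        assert f[centre] == pytest.approx(0.6)

    def test_bounded_by_data(self, coarse_disc, rng):
        pts = rng.uniform(-15, 15, (40, 3))
        pts[:, 2] = 0
        vals = rng.uniform(0.2, 1.8, 40)
        f = interpolate_field(pts, vals, coarse_disc, max_dist_mm=100.0)
        mapped = np.isfinite(f)
        assert f[mapped].min() >= vals.min() - 1e-12
        assert f[mapped].max() <= vals.max() + 1e-12

    def test_far_vertices_unmapped(self, coarse_disc):
        f = interpolate_field(
            np.array([[0.0, 0.0, 0.0]]), np.array([1.0]), coarse_disc,
            max_dist_mm=5.0,
        )
        r = np.linalg.norm(coarse_disc.vertices, axis=1)
        assert np.isnan(f[r > 5.0]).all()
        assert np.isfinite(f[r < 4.9]).all()

    def test_no_points_errors(self, coarse_disc):
        with pytest.raises(ValueError):
            interpolate_field(np.empty((0, 3)), np.empty(0), coarse_disc)

    def test_scale_equivariance(self, coarse_disc, rng):
        pts = rng.uniform(-15, 15, (30, 3))
        pts[:, 2] = 0
        vals = rng.uniform(0.1, 1.0, 30)
        f1 = interpolate_field(pts, vals, coarse_disc)
        f3 = interpolate_field(pts, 3.0 * vals, coarse_disc)
        assert np.allclose(f3, 3.0 * f1, equal_nan=True)

    def test_smooth_field_recovery(self, disc_mesh, rng):
        """Dense sampling of a smooth field: RMS error < 5% of its range."""
        truth_fn = lambda p: 1.0 + 0.5 * np.sin(p[:, 0] / 12.0) + 0.3 * np.cos(p[:, 1] / 9.0)
        pts = disc_mesh.vertices[rng.choice(disc_mesh.n_vertices, 2000)]
        pts = pts + rng.normal(0, 0.3, pts.shape) * [1, 1, 0]
        f = interpolate_field(pts, truth_fn(pts), disc_mesh)
        truth = truth_fn(disc_mesh.vertices)
        ok = np.isfinite(f)
        rms = np.sqrt(np.mean((f[ok] - truth[ok]) ** 2))
        assert rms < 0.05 * np.ptp(truth)


class TestAreaFraction:
    def test_all_below(self, coarse_disc):
        m = coarse_disc.copy()
        m.fields["bip_voltage"] = np.full(m.n_vertices, 0.2)
        assert area_fraction_below(m, "bip_voltage", 0.5) == 1.0

    def test_none_below(self, coarse_disc):
        m = coarse_disc.copy()
        m.fields["bip_voltage"] = np.full(m.n_vertices, 0.2)
        assert area_fraction_below(m, "bip_voltage", 0.1) == 0.0

    def test_half_disc(self, disc_mesh):
        m = disc_mesh.copy()
        m.fields["cv"] = np.where(m.vertices[:, 0] < 0, 0.3, 0.9)
        frac = area_fraction_below(m, "cv", 0.6)
        assert frac == pytest.approx(0.5, abs=0.03)  # one boundary ring of slack

    @given(thr=st.floats(-1.0, 3.0))
    @settings(max_examples=30, derandomize=True, deadline=None)
    def test_monotone_in_threshold(self, thr):
        m = square_mesh(6, 10.0)
        rng = np.random.default_rng(0)
        m.fields["cv"] = rng.uniform(0, 2, m.n_vertices)
        lo = area_fraction_below(m, "cv", thr)
        hi = area_fraction_below(m, "cv", thr + 0.25)
        assert 0.0 <= lo <= hi <= 1.0

    def test_all_unmapped_errors(self, coarse_disc):
        m = coarse_disc.copy()
        m.fields["cv"] = np.full(m.n_vertices, np.nan)
        with pytest.raises(ValueError):
            area_fraction_below(m, "cv", 0.6)


class TestMapSummary:
    def _with_fields(self, mesh, volt, cv):
        m = mesh.copy()
        m.fields["bip_voltage"] = np.broadcast_to(volt, (m.n_vertices,)).copy()
        m.fields["cv"] = np.broadcast_to(cv, (m.n_vertices,)).copy()
        return m

    def test_uniform_fields(self, coarse_disc):
        m = self._with_fields(coarse_disc, 1.1, 0.7)
        s = map_summary(m)
        assert s.mean_bip_mV == pytest.approx(1.1)
        assert s.mean_cv_m_per_s == pytest.approx(0.7)
        assert s.area_bip_05_rel == 0.0 and s.area_cv_06_rel == 0.0

    def test_two_half_mean(self, disc_mesh):
        m = disc_mesh.copy()
        m.fields["bip_voltage"] = np.where(m.vertices[:, 0] < 0, 0.4, 0.8)
        m.fields["cv"] = np.full(m.n_vertices, 0.7)
        s = map_summary(m)
        assert s.mean_bip_mV == pytest.approx(0.6, abs=0.01)

    def test_recovers_truth_field_mean(self, disc_mesh, rng):
        """Measured surface mean within 3% of the truth field's surface mean."""
        truth = eamap.simulate_activation(disc_mesh, "planar", 0.7)
        truth.amplitude_mV = eamap.make_amplitude_field(disc_mesh, 1.2, seed=4)
        pts = eamap.sample_mapping_points(disc_mesh, truth, 2000, seed=4,
                                          synth_traces=False)
        m = disc_mesh.copy()
        pos = np.stack([p.position for p in pts])
        m.fields["bip_voltage"] = interpolate_field(
            pos, np.array([p.bip_mV for p in pts]), m
        )
        m.fields["cv"] = np.full(m.n_vertices, 0.7)
        from eamap.mapping import _area_weighted_mean

        w = disc_mesh.triangle_areas()
        truth_mean = float(
            (truth.amplitude_mV[disc_mesh.triangles].mean(1) * w).sum() / w.sum()
        )
        s = map_summary(m, pts)
        assert s.mean_bip_mV == pytest.approx(truth_mean, rel=0.03)
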