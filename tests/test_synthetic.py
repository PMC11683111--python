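"""Ground-truth generator: meshes, activation fields, electrograms, cohorts."""

import numpy as np
import pytest

import eamap
from eamap.synthetic import CohortSpec, EgmNoise, synth_egm_batch


class TestMakeMesh:
    def test_disc_area_matches_analytic(self):
        m = eamap.make_mesh("disc", 2.0, 40.0)
        assert m.total_area() == pytest.approx(np.pi * 40.0**2, rel=0.02)

    def test_ellipsoid_default_all_body(self):
        m = eamap.make_mesh("ellipsoid", 4.0)
        assert (m.region == "body").all()
        assert m.n_vertices >= 4

    def test_zero_resolution_rejected(self):
        with pytest.raises(ValueError):
            eamap.make_mesh("disc", 0.0)

    def test_region_patch_labelling(self):
        m = eamap.make_mesh(
            "disc", 3.0, 30.0,
            region_spec=[eamap.RegionPatch("laa", (20.0, 0.0, 0.0), 6.0)],
        )
        d = np.linalg.norm(m.vertices - [20.0, 0.0, 0.0], axis=1)
        assert (m.region[d <= 6.0] == "laa").all()
        assert (m.region[d > 6.0] == "body").all()


class TestSimulateActivation:
    def test_planar_lat_differences(self, disc_mesh):
        """7 mm apart along the wave direction at 0.7 m/s -> 10 ms."""
        truth = eamap.simulate_activation(disc_mesh, "planar", 0.7,
                                          direction=(1, 0, 0))
        x = disc_mesh.vertices[:, 0]
        i, j = np.argmin(np.abs(x + 3.5)), np.argmin(np.abs(x - 3.5))
        expect = (x[j] - x[i]) / 0.7
        assert truth.lat_ms[j] - truth.lat_ms[i] == pytest.approx(expect, abs=1e-9)
        assert truth.lat_ms.min() == 0.0

    def test_direction_auto_normalised(self, coarse_disc):
        a = eamap.simulate_activation(coarse_disc, "planar", 0.5, direction=(2, 0, 0))
        b = eamap.simulate_activation(coarse_disc, "planar", 0.5, direction=(1, 0, 0))
        assert np.allclose(a.lat_ms, b.lat_ms)

    def test_focal_concentric_isochrones(self, disc_mesh):
        truth = eamap.simulate_activation(disc_mesh, "focal", 0.5, origin=(0, 0, 0))
        r = np.linalg.norm(disc_mesh.vertices, axis=1)
        far = r > 10
        rel_err = np.abs(truth.lat_ms[far] - r[far] / 0.5) / (r[far] / 0.5)
        assert rel_err.max() < 0.05  # edge-graph metric error vanishes with resolution

    def test_patchy_gradient_matches_local_slowness(self):
        """|grad lat| ~ 1/speed per triangle, via a finite-difference oracle."""
        m = eamap.make_mesh("disc", 1.5, 40.0)
        sf = eamap.make_speed_field(m, 0.8, [((15.0, 0.0, 0.0), 10.0, 0.3)])
        truth = eamap.simulate_activation(m, "focal", sf, origin=(-35.0, 0.0, 0.0))
        tris = m.triangles
        p = m.vertices[tris]
        lat = truth.lat_ms[tris]
        # per-triangle gradient of the linear interpolant
        grads = []
        for k in range(len(tris)):
            e1, e2 = p[k, 1] - p[k, 0], p[k, 2] - p[k, 0]
            A = np.array([[e1 @ e1, e1 @ e2], [e1 @ e2, e2 @ e2]])
            b = np.array([lat[k, 1] - lat[k, 0], lat[k, 2] - lat[k, 0]])
            c = np.linalg.solve(A, b)
            grads.append(np.linalg.norm(c[0] * e1 + c[1] * e2))
        grads = np.array(grads)
        cen = p.mean(axis=1)
        d = np.linalg.norm(cen - [15.0, 0.0, 0.0], axis=1)
        interior, outside = d < 6.0, (d > 14.0) & (np.linalg.norm(cen, axis=1) < 30)
        # gradient magnitude = local slowness (ms/mm) within discretisation error
        assert np.median(grads[interior]) == pytest.approx(1 / 0.3, rel=0.10)
        assert np.median(grads[outside]) == pytest.approx(1 / 0.8, rel=0.10)

    def test_speed_out_of_range_rejected(self, coarse_disc):
        with pytest.raises(ValueError):
            eamap.simulate_activation(coarse_disc, "planar", 4.0)

    def test_origin_off_mesh_rejected(self, coarse_disc):
        with pytest.raises(ValueError):
            eamap.simulate_activation(coarse_disc, "focal", 0.5,
                                      origin=(500.0, 0.0, 0.0))


class TestSynthesizeEgm:
    def test_peak_to_peak_by_construction(self):
        b, u = eamap.synthesize_egm(50.0, 1.0)
        assert np.ptp(b.samples) == pytest.approx(1.0, rel=1e-9)
        # unipolar extrema sit between samples; exact only for the template
        assert np.ptp(u.samples) == pytest.approx(1.63, rel=5e-3)

    def test_deterministic_given_seed(self):
        n = EgmNoise(rms_mV=0.05)
        a, _ = eamap.synthesize_egm(50.0, 1.0, noise=n, seed=7)
        b, _ = eamap.synthesize_egm(50.0, 1.0, noise=n, seed=7)
        assert np.array_equal(a.samples, b.samples)

    def test_annotation_roundtrip(self):
        b, _ = eamap.synthesize_egm(50.0, 1.0)
        assert eamap.annotate_lat(b).lat_ms == pytest.approx(50.0, abs=0.5)

    def test_rejects_low_fs_and_negative_amplitude(self):
        with pytest.raises(ValueError):
            eamap.synthesize_egm(50.0, 1.0, fs_hz=300.0)
        with pytest.raises(ValueError):
            eamap.synthesize_egm(50.0, -0.5)


class TestSampleMappingPoints:
    def test_points_confined_to_body(self):
        m = eamap.make_mesh(
            "disc", 2.0, 40.0,
            region_spec=[eamap.RegionPatch("pv", (25.0, 0.0, 0.0), 8.0)],
        )
        truth = eamap.simulate_activation(m, "planar", 0.7)
        pts = eamap.sample_mapping_points(m, truth, 1000, seed=0,
                                          synth_traces=False)
        d = np.linalg.norm(np.stack([p.position for p in pts]) - [25.0, 0.0, 0.0],
                           axis=1)
        assert (d > 7.9).all()  # patch interior excluded (boundary ring tolerance)

    def test_zero_jitter_truth_passthrough(self, disc_mesh, planar_truth):
        pts = eamap.sample_mapping_points(disc_mesh, planar_truth, 100, seed=1,
                                          synth_traces=False)
        for p in pts[:10]:
            expect = (p.position[0] - disc_mesh.vertices[:, 0].min()) / 0.7
            assert p.true_lat_ms == pytest.approx(expect, abs=1e-9)

    def test_density_uniform_across_quadrants(self, disc_mesh, planar_truth):
        """Chi-square of quadrant counts against area-uniform sampling."""
        from scipy.stats import chisquare

        pts = eamap.sample_mapping_points(disc_mesh, planar_truth, 10000, seed=3,
                                          synth_traces=False)
        pos = np.stack([p.position for p in pts])
        quad = (pos[:, 0] > 0).astype(int) * 2 + (pos[:, 1] > 0).astype(int)
        counts = np.bincount(quad, minlength=4)
        assert chisquare(counts).pvalue > 0.01
        assert np.ptp(counts) / counts.mean() < 0.10

    def test_density_cap_enforced(self, coarse_disc):
        truth = eamap.simulate_activation(coarse_disc, "planar", 0.7)
        with pytest.raises(ValueError):
            eamap.sample_mapping_points(coarse_disc, truth, 10**7)


class TestGenerateCohort:
    def test_default_sizes(self):
        s = eamap.generate_cohort(CohortSpec(seed=0))
        assert len(s) == 52
        sizes = np.bincount([x.true_cluster for x in s])
        assert list(sizes) == [30, 12, 10]

    def test_bit_reproducible(self):
        a = eamap.generate_cohort(CohortSpec(seed=5))
        b = eamap.generate_cohort(CohortSpec(seed=5))
        assert all(x == y for x, y in zip(a, b))

    def test_event_fraction_matches_recurrence_param(self):
        """Monte-Carlo at n = 10,000: 24-month event fraction -> 0.60 +- 0.02."""
        spec = CohortSpec(
            n_patients=10000, cluster_sizes=(1, 1, 9998), seed=11
        )
        s = [x for x in eamap.generate_cohort(spec) if x.true_cluster == 2]
        assert np.mean([x.event for x in s]) == pytest.approx(0.60, abs=0.02)

    def test_degenerate_spread_identical_summaries(self):
        s = eamap.generate_cohort(CohortSpec(seed=2, sd_scale=0.0))
        c0 = [x for x in s if x.true_cluster == 0]
        assert len({x.mean_bip_mV for x in c0}) == 1
        assert len({x.mean_cv_m_per_s for x in c0}) == 1

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            CohortSpec(cluster_sizes=(30, 12, 9)).validate()
        with pytest.raises(ValueError):
            CohortSpec(recurrence_24mo=(0.2, 0.3, 1.5)).validate()


def test_lat_roundtrip_through_annotation(disc_mesh, planar_truth):
    """Simulator -> sampling -> annotation recovers true LATs within 1 sample."""
    from eamap.io import PipelineConfig
    from eamap.pipeline import process_points

    pts = eamap.sample_mapping_points(disc_mesh, planar_truth, 300, seed=8)
    process_points(pts, PipelineConfig())
    errs = [abs(p.lat_ms - p.true_lat_ms) for p in pts if p.quality == "accepted"]
    assert len(errs) > 280
    assert max(errs) <= 0.5  # one sample at 2 kHz
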