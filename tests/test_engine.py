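import numpy as np
import pytest
from scipy import ndimage

from unidose import BeamConfig, VolumeGrid, default_beam_model
from unidose.beams import FluenceMap
from unidose.engine import (
    BeamDoseOperator,
    CaseDoseOperator,
    _clip_segment_to_grid,
    conformal_aperture,
    convolve_fluence,
    fcbb_beam_dose,
    project_to_bev,
    radiological_depth,
    total_dose,
)
from unidose.fmo import _make_templates

from conftest import small_spec
from unidose import generate_phantom


def _sphere_case(n=32, radius=10.0):
    g = VolumeGrid(np.zeros((n, n, n)), 2.0)
    c = g.center_mm()
    pts = g.voxel_centers()
    body = np.sum(((pts - c) / (n - 4.0)) ** 2, axis=-1) <= 1.0
    ptv = np.sum((pts - c) ** 2, axis=-1) <= radius**2
    from unidose.structures import CaseBundle, StructureSet, Target

    st = StructureSet(g.like(body.astype(float)), [Target("ptv", g.like(ptv.astype(float)), 50.0)])
    beams = [BeamConfig(a, c, 1000.0) for a in (10.0, 100.0, 190.0, 280.0)]
    return CaseBundle(st, beams, default_beam_model())


class TestProjection:
    def test_isocenter_maps_to_origin(self):
        b = BeamConfig(73.0, [5.0, -3.0, 8.0], 1000.0)
        np.testing.assert_allclose(project_to_bev(b.isocenter_mm, b), [0, 0], atol=1e-9)

    def test_in_plane_point_is_identity(self):
        b = BeamConfig(0.0, [0.0, 0.0, 0.0], 1000.0)
        # gantry 0: u axis is +x, v axis is +z, both in the isocenter plane
        np.testing.assert_allclose(
            project_to_bev(np.array([10.0, 0.0, 0.0]), b), [10.0, 0.0], atol=1e-9
        )
        np.testing.assert_allclose(
            project_to_bev(np.array([0.0, 0.0, -4.0]), b), [0.0, -4.0], atol=1e-9
        )

    def test_upstream_point_magnified_by_similar_triangles(self):
        b = BeamConfig(0.0, [0.0, 0.0, 0.0], 1000.0)
        # 100 mm toward the source, 10 mm lateral offset: u = 10 * 1000 / 900
        uv = project_to_bev(np.array([10.0, 100.0, 0.0]), b)
        np.testing.assert_allclose(uv, [10.0 * 1000.0 / 900.0, 0.0], rtol=1e-12)

    def test_point_at_source_rejected(self):
        b = BeamConfig(0.0, [0.0, 0.0, 0.0], 1000.0)
        with pytest.raises(ValueError, match="source"):
            project_to_bev(np.array([0.0, 1000.0, 0.0]), b)


class TestAperture:
    @staticmethod
    def _radii(ap):
        iu = int(round(-ap.origin_uv_mm[0] / ap.pixel_mm))
        iv = int(round(-ap.origin_uv_mm[1] / ap.pixel_mm))
        return (
            ap.values[:, iv].sum() * ap.pixel_mm / 2,
            ap.values[iu, :].sum() * ap.pixel_mm / 2,
        )

    def test_sphere_aperture_radius_includes_margin(self):
        case = _sphere_case(radius=10.0)
        beam = case.beams[0]
        ptv = case.structures.targets[0].mask
        ap5 = conformal_aperture(ptv, beam, margin_mm=5.0, pixel_mm=1.0)
        ap0 = conformal_aperture(ptv, beam, margin_mm=0.0, pixel_mm=1.0)
        r5 = np.mean(self._radii(ap5))
        r0 = np.mean(self._radii(ap0))
        assert r5 - r0 == pytest.approx(5.0, abs=1.0)
        assert r0 == pytest.approx(10.0, abs=2.0)  # within a voxel of the sphere

    def test_aperture_is_binary_and_margin_grows_it(self):
        case = _sphere_case()
        ptv = case.structures.targets[0].mask
        ap0 = conformal_aperture(ptv, case.beams[1], margin_mm=0.0, pixel_mm=2.0)
        ap5 = conformal_aperture(ptv, case.beams[1], margin_mm=5.0, pixel_mm=2.0)
        assert set(np.unique(ap0.values)) <= {0.0, 1.0}
        assert ap5.values.sum() > ap0.values.sum()

    def test_disjoint_lobes_project_to_two_components(self):
        g = VolumeGrid(np.zeros((32, 32, 32)), 2.0)
        c = g.center_mm()
        pts = g.voxel_centers()
        lobe1 = np.sum((pts - (c + [0, 0, 14])) ** 2, -1) <= 6**2
        lobe2 = np.sum((pts - (c - [0, 0, 14])) ** 2, -1) <= 6**2
        ptv = g.like((lobe1 | lobe2).astype(float))
        beam = BeamConfig(35.0, c, 1000.0)
        ap = conformal_aperture(ptv, beam, margin_mm=0.0, pixel_mm=1.0)
        n_comp = ndimage.label(ap.values > 0)[1]
        assert n_comp == 2

    def test_empty_ptv_rejected(self):
        g = VolumeGrid(np.zeros((8, 8, 8)), 2.0)
        with pytest.raises(ValueError, match="empty PTV"):
            conformal_aperture(g, BeamConfig(0.0, g.center_mm(), 1000.0))


class TestConvolution:
    def test_delta_becomes_gaussian_with_central_max(self):
        f = np.zeros((41, 41))
        f[20, 20] = 1.0
        out = convolve_fluence(FluenceMap(f, 1.0), kernel_sigma_mm=3.0)
        assert np.unravel_index(out.values.argmax(), out.values.shape) == (20, 20)
        # matches the sampled, truncated, discretely normalized Gaussian
        ax = np.arange(-12.0, 13.0)
        g1 = np.exp(-0.5 * (ax / 3.0) ** 2)
        g2 = np.outer(g1, g1)
        g2 = g2 / g2.sum()
        np.testing.assert_allclose(out.values[20, 8:33], g2[12, :], atol=1e-9)

    def test_mass_preserved_for_padded_aperture(self):
        f = np.zeros((61, 61))
        f[25:36, 25:36] = 1.0
        out = convolve_fluence(FluenceMap(f, 1.0), kernel_sigma_mm=3.0)
        assert out.values.sum() == pytest.approx(f.sum(), rel=0.005)

    def test_constant_region_unchanged(self):
        f = np.ones((61, 61))
        out = convolve_fluence(FluenceMap(f, 1.0), kernel_sigma_mm=3.0)
        np.testing.assert_allclose(out.values[20:41, 20:41], 1.0, atol=1e-9)


class TestRadiologicalDepth:
    def test_uniform_density_returns_geometric_path(self):
        g = VolumeGrid(np.ones((16, 16, 16)), 2.0)
        src = np.array([15.0, 200.0, 15.0])
        pt = np.array([15.0, 1.0, 15.0])
        # body spans y in [-1, 31]; entry at y=31, so depth = 31 - 1 = 30
        d = radiological_depth(g, src, pt)
        assert d == pytest.approx(30.0, abs=0.2)

    def test_half_density_halves_depth(self):
        g = VolumeGrid(np.full((24, 24, 24), 0.5), 2.0)
        src = np.array([23.0, 300.0, 23.0])
        pt = np.array([23.0, 6.0, 23.0])  # box edge at y=47: geometric path 41
        d = radiological_depth(g, src, pt)
        geom = 47.0 - 6.0
        assert d == pytest.approx(0.5 * geom, abs=0.2)

    def test_oblique_ray_matches_fine_quadrature(self, rng):
        dens = VolumeGrid(rng.uniform(0, 1, (8, 8, 8)), 2.0)
        src = np.array([120.0, 60.0, 40.0])
        pts = np.array([[5.0, 3.0, 7.0], [2.0, 12.0, 4.0], [13.0, 9.0, 11.0]])
        d = radiological_depth(dens, src, pts, step_mm=0.5)
        t0, t1, dirs, _ = _clip_segment_to_grid(dens, src, pts)
        for i in range(len(pts)):
            ts = np.arange(t0[i], t1[i], 0.01)
            q = src + dirs[i] * ts[:, None]
            vals = ndimage.map_coordinates(
                dens.values, dens.index_coords(q).T, order=1, mode="nearest"
            )
            assert d[i] == pytest.approx(vals.sum() * 0.01, abs=0.5)

    def test_point_outside_grid_rejected(self):
        g = VolumeGrid(np.ones((8, 8, 8)), 2.0)
        with pytest.raises(ValueError, match="outside"):
            radiological_depth(g, np.array([0.0, 500.0, 0.0]), np.array([99.0, 0.0, 0.0]))


class TestDoseOperator:
    def test_zero_fluence_gives_zero_dose(self):
        case = _sphere_case()
        tmpl = _make_templates(case, 5.0, 5.0)[0]
        d = fcbb_beam_dose(case, case.beams[0], tmpl.like(np.zeros_like(tmpl.values)))
        assert np.all(d.values == 0)

    def test_linearity_in_fluence(self, rng):
        case = _sphere_case(n=16, radius=6.0)
        case.beams = case.beams[:1]
        tmpl = _make_templates(case, 5.0, 5.0)[0]
        f1 = rng.uniform(0, 1, tmpl.values.shape)
        f2 = rng.uniform(0, 1, tmpl.values.shape)
        op = BeamDoseOperator(
            case.structures.body, case.structures.body, case.beams[0], case.beam_model, tmpl
        )
        np.testing.assert_allclose(
            op.apply_values(f1 + f2),
            op.apply_values(f1) + op.apply_values(f2),
            rtol=1e-12,
            atol=1e-12,
        )

    def test_adjoint_identity(self, rng):
        case = generate_phantom(
            small_spec(seed=2, grid_shape=(16, 16, 16), n_beams_range=(3, 3),
                       body_semiaxes_range_mm=((10.0, 13.0),) * 3,
                       target_radius_range_mm=(4.0, 6.0))
        )
        tmpls = _make_templates(case, 5.0, 5.0)
        op = CaseDoseOperator(case, tmpls)
        f = [rng.uniform(0, 1, t.values.shape) for t in tmpls]
        d = rng.normal(size=op.n_voxels)
        lhs = float(op.apply_values(f) @ d)
        rhs = sum(float(np.sum(fi * gi)) for fi, gi in zip(f, op.adjoint_values(d)))
        assert lhs == pytest.approx(rhs, rel=1e-10)

    def test_beam_permutation_invariance(self, rng):
        case = _sphere_case(n=16, radius=6.0)
        tmpls = _make_templates(case, 5.0, 5.0)
        fls = [t.like(rng.uniform(0, 1, t.values.shape)) for t in tmpls]
        d1 = total_dose(case, fls)
        perm = [2, 0, 3, 1]
        case2 = _sphere_case(n=16, radius=6.0)
        case2.beams = [case.beams[i] for i in perm]
        d2 = total_dose(case2, [fls[i] for i in perm])
        np.testing.assert_allclose(d2.values, d1.values, rtol=1e-12, atol=1e-14)

    def test_single_beam_total_equals_beam_dose(self, rng):
        case = _sphere_case(n=16, radius=6.0)
        case.beams = case.beams[:1]
        tmpl = _make_templates(case, 5.0, 5.0)[0]
        fl = tmpl.like(rng.uniform(0, 1, tmpl.values.shape))
        np.testing.assert_allclose(
            total_dose(case, [fl]).values,
            fcbb_beam_dose(case, case.beams[0], fl).values,
        )

    def test_fluence_beam_count_mismatch_rejected(self, rng):
        case = _sphere_case(n=16, radius=6.0)
        tmpls = _make_templates(case, 5.0, 5.0)
        with pytest.raises(ValueError, match="fluence"):
            total_dose(case, [t.like(t.values) for t in tmpls[:2]])
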