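"""Surface extraction, template correspondence and thickness measurement."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from cardiatlas.core import SurfaceMesh, VolumeImage
from cardiatlas.phantom import PhantomSpec, generate_atlas_pool, generate_phantom
from cardiatlas.surfaces import (
    TemplateMapper,
    TemplateModel,
    _pair_epi_to_endo,
    build_template,
    extract_surfaces,
    measure_thickness,
    register_template,
)
from cardiatlas.transforms import SimilarityTransform


@pytest.fixture(scope="module")
def sphere_meshes(sphere_phantom):
    _, labels, _, _, _ = sphere_phantom
    return extract_surfaces(labels)


@pytest.fixture(scope="module")
def sphere_corresponded(sphere_meshes):
    endo, epi = sphere_meshes
    epi_pts = _pair_epi_to_endo(endo, epi)
    return endo, SurfaceMesh(epi_pts, endo.triangles, "epicardium")


class TestExtractSurfaces:
    def test_sphere_radii_within_half_voxel(self, sphere_meshes):
        endo, epi = sphere_meshes
        r_endo = np.linalg.norm(endo.points - endo.points.mean(0), axis=1)
        r_epi = np.linalg.norm(epi.points - epi.points.mean(0), axis=1)
        assert abs(r_endo.mean() - 20.0) < 0.5
        assert abs(r_epi.mean() - 30.0) < 0.5
        assert np.all(np.abs(r_endo - 20.0) < 0.5)
        assert np.all(np.abs(r_epi - 30.0) < 0.5)

    def test_sphere_areas_within_3_percent(self, sphere_meshes):
        endo, epi = sphere_meshes
        assert endo.to_trimesh().area == pytest.approx(4 * np.pi * 400, rel=0.03)
        assert epi.to_trimesh().area == pytest.approx(4 * np.pi * 900, rel=0.03)

    def test_meshes_live_in_physical_frame(self, sphere_phantom):
        _, labels, _, _, _ = sphere_phantom
        endo, _ = extract_surfaces(labels)
        center = endo.points.mean(0)
        np.testing.assert_allclose(center, [0, 0, 0], atol=0.5)

    def test_empty_label_map_rejected(self):
        empty = VolumeImage(np.zeros((8, 8, 8), dtype=np.int16), (1, 1, 1))
        with pytest.raises(ValueError, match="cavity"):
            extract_surfaces(empty)


class TestRegisterTemplate:
    def _template(self, sphere_corresponded):
        endo, epi = sphere_corresponded
        return TemplateModel(
            endo=endo,
            epi=epi,
            midwall=SurfaceMesh((endo.points + epi.points) / 2, endo.triangles, "midwall"),
        )

    def test_identity_on_self(self, sphere_corresponded, sphere_meshes):
        template = self._template(sphere_corresponded)
        t_endo, t_epi = sphere_meshes
        endo_c, epi_c, tf, rms = register_template(template, t_endo, t_epi)
        assert rms < 0.05
        # tangential ICP slack on a rotationally symmetric shape is a few
        # microns; anything near voxel scale would be a real failure
        np.testing.assert_allclose(endo_c.points, template.endo.points, atol=0.01)
        assert tf.scale == pytest.approx(1.0, abs=1e-3)

    def test_recovers_scale_1p1(self, sphere_corresponded, sphere_meshes):
        template = self._template(sphere_corresponded)
        t_endo, t_epi = sphere_meshes
        scaled = SimilarityTransform(scale=1.1)
        endo_s = t_endo.with_points(scaled.apply(t_endo.points))
        epi_s = t_epi.with_points(scaled.apply(t_epi.points))
        _, _, tf, _ = register_template(template, endo_s, epi_s)
        assert tf.scale == pytest.approx(1.1, abs=1e-3)

    def test_projection_lands_on_target_surface(self, sphere_corresponded, sphere_meshes):
        from cardiatlas._geometry import closest_point_on_mesh

        template = self._template(sphere_corresponded)
        t_endo, t_epi = sphere_meshes
        endo_c, _, _, _ = register_template(template, t_endo, t_epi)
        _, d, _ = closest_point_on_mesh(
            endo_c.points[::7], t_endo.points, t_endo.triangles
        )
        assert d.max() < 1e-6

    def test_idempotent_on_corresponded_mesh(self, sphere_corresponded):
        """Re-registering an already-corresponded mesh is a no-op."""
        template = self._template(sphere_corresponded)
        endo_c, epi_c, _, _ = register_template(
            template, template.endo, template.epi
        )
        assert np.abs(endo_c.points - template.endo.points).max() < 1e-6
        assert np.abs(epi_c.points - template.epi.points).max() < 1e-6


class TestMeasureThickness:
    def test_concentric_spheres_10mm_everywhere(self, sphere_corresponded):
        endo, epi = sphere_corresponded
        tm = measure_thickness(endo, epi)
        assert np.all(np.abs(tm.values - 10.0) < 0.2)

    def test_ellipsoid_shell_mean_within_5_percent(self):
        spec = PhantomSpec(
            endo_semiaxes=(18.0, 22.0, 40.0),
            wall_thickness=8.0,
            base_fraction=2.0,
            rng_seed=0,
        )
        _, labels, _, _ = generate_phantom(spec, (1.5, 1.5, 1.5))
        endo, epi = extract_surfaces(labels)
        epi_pts = _pair_epi_to_endo(endo, epi)
        tm = measure_thickness(endo, SurfaceMesh(epi_pts, endo.triangles, "epicardium"))
        assert tm.values.mean() == pytest.approx(8.0, rel=0.05)

    def test_rigid_motion_invariance(self, sphere_corresponded):
        endo, epi = sphere_corresponded
        sub = slice(None, None, 5)
        endo_s = SurfaceMesh(endo.points, endo.triangles, "endocardium")
        tm0 = measure_thickness(endo_s, epi)
        move = SimilarityTransform(
            Rotation.from_euler("xz", [17, -9], degrees=True).as_matrix(),
            np.array([12.0, -5.0, 40.0]),
        )
        tm1 = measure_thickness(
            endo.with_points(move.apply(endo.points)),
            epi.with_points(move.apply(epi.points)),
        )
        assert np.abs(tm1.values - tm0.values).max() < 1e-6

    def test_point_count_mismatch_rejected(self, sphere_corresponded):
        endo, epi = sphere_corresponded
        small = SurfaceMesh(endo.points[:3], np.array([[0, 1, 2]]), "endocardium")
        with pytest.raises(ValueError, match="point count"):
            measure_thickness(small, epi)


@pytest.fixture(scope="module")
def tiny_pool():
    return generate_atlas_pool(
        PhantomSpec(noise_sd=0.0),
        n_atlases=3,
        rng_seed=21,
        spacing=(2.0, 2.0, 2.0),
    )


class TestBuildTemplate:

    def test_identical_atlases_give_member_shape(self):
        from cardiatlas.phantom import ShapeVariation

        pool = generate_atlas_pool(
            PhantomSpec(noise_sd=0.0),
            n_atlases=2,
            variation=ShapeVariation(0, 0, 0, 0),
            rng_seed=0,
            spacing=(2.0, 2.0, 2.0),
        )
        template = build_template(pool)
        endo0, _ = extract_surfaces(pool[0].labels, step_size=2)
        from cardiatlas._geometry import closest_point_on_mesh

        _, d, _ = closest_point_on_mesh(
            template.endo.points[::5], endo0.points, endo0.triangles
        )
        assert d.max() < 0.1

    def test_two_spheres_average_radius(self):
        specs = [
            PhantomSpec(endo_semiaxes=(20.0,) * 3, wall_thickness=8.0, base_fraction=2.0),
            PhantomSpec(endo_semiaxes=(22.0,) * 3, wall_thickness=8.0, base_fraction=2.0),
        ]
        from cardiatlas.core import Atlas

        atlases = []
        for i, s in enumerate(specs):
            gray, labels, lms, _ = generate_phantom(s, (1.5, 1.5, 1.5))
            atlases.append(Atlas(gray, labels, lms, f"s{i}"))
        template = build_template(atlases)
        r = np.linalg.norm(template.endo.points - template.endo.points.mean(0), axis=1)
        assert r.mean() == pytest.approx(21.0, abs=0.3)

    def test_mapper_fixes_point_count(self, tiny_pool):
        mapper = TemplateMapper().fit(tiny_pool)
        tm1 = mapper.transform(tiny_pool[1].labels)
        tm2 = mapper.transform(tiny_pool[2].labels)
        assert tm1.n_points == tm2.n_points == mapper.n_points_
        assert np.all(tm1.values > 0)

    def test_single_atlas_rejected(self, tiny_pool):
        with pytest.raises(ValueError, match="at least 2"):
            build_template(tiny_pool[:1])
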