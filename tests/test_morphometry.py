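"""Geometry: hull volumes, areas, docked counts vs brute-force oracles, SEM."""

import numpy as np
import pytest
import trimesh

from synaptometry import (MeasurementReplicates, TaggedMesh, VesicleCloud,
                          count_docked, generate_spine_mesh, generate_vesicle_cloud,
                          measurement_error, neck_volume, psd_centroid_distance,
                          region_area, region_hull_volume)
from synaptometry.errors import (ConsistencyError, DomainError, GeometryError,
                                 InsufficientDataError, TaggingError, UnitError)
from synaptometry.morphometry import min_distance_to_region, points_in_mesh


# ---------------------------------------------------------------------------
# independent oracle: Ericson's closest-point-on-triangle, scalar, per point


def _closest_point_on_triangle(p, a, b, c):
    ab, ac, ap = b - a, c - a, p - a
    d1, d2 = ab @ ap, ac @ ap
    if d1 <= 0 and d2 <= 0:
        return a
    bp = p - b
    d3, d4 = ab @ bp, ac @ bp
    if d3 >= 0 and d4 <= d3:
        return b
    vc = d1 * d4 - d3 * d2
    if vc <= 0 and d1 >= 0 and d3 <= 0:
        return a + (d1 / (d1 - d3)) * ab
    cp = p - c
    d5, d6 = ab @ cp, ac @ cp
    if d6 >= 0 and d5 <= d6:
        return c
    vb = d5 * d2 - d1 * d6
    if vb <= 0 and d2 >= 0 and d6 <= 0:
        return a + (d2 / (d2 - d6)) * ac
    va = d3 * d6 - d5 * d4
    if va <= 0 and (d4 - d3) >= 0 and (d5 - d6) >= 0:
        return b + ((d4 - d3) / ((d4 - d3) + (d5 - d6))) * (c - b)
    denom = 1.0 / (va + vb + vc)
    return a + ab * (vb * denom) + ac * (vc * denom)


def brute_force_min_distances(points, triangles):
    out = np.empty(len(points))
    for i, p in enumerate(points):
        best = np.inf
        for tri in triangles:
            q = _closest_point_on_triangle(p, tri[0], tri[1], tri[2])
            best = min(best, float(np.linalg.norm(p - q)))
        out[i] = best
    return out


def cube_mesh():
    box = trimesh.creation.box(extents=(1.0, 1.0, 1.0))
    all_faces = np.arange(len(box.faces))
    return TaggedMesh(mesh=box, region_tags={"whole_spine": all_faces,
                                             "head": all_faces}, name="cube")


class TestRegionHullVolume:
    def test_unit_cube(self):
        assert region_hull_volume(cube_mesh(), "whole_spine") == pytest.approx(1.0)

    def test_icosphere_within_two_percent(self):
        sphere = trimesh.creation.icosphere(subdivisions=4, radius=0.5)
        tm = TaggedMesh(mesh=sphere,
                        region_tags={"whole_spine": np.arange(len(sphere.faces))})
        vol = region_hull_volume(tm, "whole_spine")
        assert vol == pytest.approx(4 / 3 * np.pi * 0.5 ** 3, rel=0.02)

    def test_single_triangle_region_degenerate(self):
        box = cube_mesh()
        box.region_tags["one"] = np.array([0])
        with pytest.raises(GeometryError):
            region_hull_volume(box, "one")

    def test_rigid_motion_invariance(self):
        tm = cube_mesh()
        v0 = region_hull_volume(tm, "whole_spine")
        rot = trimesh.transformations.rotation_matrix(0.7, [1, 2, 3], point=[0.2, 0, 0])
        moved = tm.mesh.copy()
        moved.apply_transform(rot)
        moved.apply_translation([3.0, -1.0, 2.5])
        tm2 = TaggedMesh(mesh=moved, region_tags=dict(tm.region_tags))
        assert region_hull_volume(tm2, "whole_spine") == pytest.approx(v0, rel=1e-9)

    def test_clip_is_noop_for_interior_convex_region(self):
        # a tetrahedral region strictly inside the cube: hull ⊂ mesh
        box = trimesh.creation.box(extents=(2.0, 2.0, 2.0))
        tet = trimesh.creation.icosphere(subdivisions=1, radius=0.4)
        combined = trimesh.util.concatenate([box, tet])
        inner = np.arange(len(box.faces), len(combined.faces))
        tm = TaggedMesh(mesh=combined, region_tags={"inner": inner})
        unclipped = region_hull_volume(tm, "inner", clip=False)
        clipped = region_hull_volume(tm, "inner", clip=True, grid_resolution=16)
        assert clipped == pytest.approx(unclipped, rel=0.05)

    def test_spine_head_matches_analytic_volume_across_subdivisions(self):
        v_target = 0.524  # r = 0.5 µm sphere
        for sub in (3, 4, 5):
            tm = generate_spine_mesh(v_target, neck_length=0.4, neck_diameter=0.16,
                                     subdivisions=sub)
            vol = region_hull_volume(tm, "head")
            assert vol == pytest.approx(v_target, rel=0.02)


class TestRegionArea:
    def test_unit_cube_surface(self):
        assert region_area(cube_mesh(), "whole_spine") == pytest.approx(6.0)

    def test_icosphere_surface(self):
        sphere = trimesh.creation.icosphere(subdivisions=4, radius=0.5)
        tm = TaggedMesh(mesh=sphere, region_tags={"all": np.arange(len(sphere.faces))})
        assert region_area(tm, "all") == pytest.approx(4 * np.pi * 0.25, rel=0.02)

    def test_empty_region_and_unknown_region(self):
        tm = cube_mesh()
        tm.region_tags["empty"] = np.array([], dtype=int)
        assert region_area(tm, "empty") == 0.0
        with pytest.raises(TaggingError):
            region_area(tm, "nope")


class TestNeckVolume:
    def test_subtraction(self):
        assert neck_volume(1.0, 0.6) == pytest.approx(0.4)
        assert neck_volume(0.5, 0.5) == 0.0

    def test_inconsistent_segmentation_flagged(self):
        with pytest.raises(ConsistencyError):
            neck_volume(0.5, 0.6)

    def test_generated_cylinder_neck(self, spine_mesh):
        # whole-spine volume from the closed mesh, head from its hull; the
        # difference matches the analytic cylinder (+ junction cap) volume
        whole = float(spine_mesh.mesh.volume)
        neck = neck_volume(whole, region_hull_volume(spine_mesh, "head"))
        assert neck == pytest.approx(spine_mesh.ground_truth["neck_volume"], rel=0.05)


class TestCountDocked:
    def test_empty_cloud(self, spine_mesh):
        cloud = VesicleCloud(centers_nm=np.zeros((0, 3)))
        assert count_docked(cloud, spine_mesh) == 0

    def test_constructed_counts(self, spine_mesh):
        cloud = generate_vesicle_cloud(100, spine_mesh, docked_fraction_target=0.3,
                                       seed=4)
        assert cloud.docked_truth.sum() == 30
        assert count_docked(cloud, spine_mesh) == 30

    def test_matches_brute_force_oracle_exactly(self, spine_mesh):
        cloud = generate_vesicle_cloud(150, spine_mesh, docked_fraction_target=0.4,
                                       seed=6)
        tris = spine_mesh.region_triangles("active_zone")
        pts_um = cloud.centers_nm / 1000.0
        oracle_d = brute_force_min_distances(pts_um, tris) * 1000.0
        fast_d = min_distance_to_region(pts_um, spine_mesh, "active_zone") * 1000.0
        np.testing.assert_allclose(fast_d, oracle_d, atol=1e-9)
        assert count_docked(cloud, spine_mesh) == int(np.sum(oracle_d <= 100.0))

    def test_monotone_in_threshold(self, spine_mesh):
        cloud = generate_vesicle_cloud(120, spine_mesh, docked_fraction_target=0.25,
                                       seed=8)
        counts = [count_docked(cloud, spine_mesh, t) for t in (0, 50, 100, 300, 1000)]
        assert counts == sorted(counts)

    def test_unit_mismatch_detected(self, spine_mesh):
        # coordinates accidentally in µm: extent far too small for nm
        cloud_um = VesicleCloud(centers_nm=np.random.default_rng(0).uniform(
            -0.3, 0.3, size=(50, 3)))
        with pytest.raises(UnitError):
            count_docked(cloud_um, spine_mesh)

    def test_missing_region(self):
        tm = cube_mesh()
        cloud = VesicleCloud(centers_nm=np.array([[0.0, 0.0, 2000.0]]))
        with pytest.raises(TaggingError):
            count_docked(cloud, tm)


class TestPointsInMesh:
    def test_winding_number_cube(self):
        tm = cube_mesh()
        pts = np.array([[0, 0, 0], [0.49, 0.49, 0.49], [0.51, 0, 0], [2, 2, 2]])
        np.testing.assert_array_equal(points_in_mesh(pts, tm),
                                      [True, True, False, False])


class TestPsdCentroidDistance:
    def test_identical_meshes(self, spine_mesh):
        assert psd_centroid_distance(spine_mesh, spine_mesh) == 0.0

    def test_three_four_five_translation(self, spine_mesh):
        moved_mesh = spine_mesh.mesh.copy()
        moved_mesh.apply_translation([3.0, 4.0, 0.0])
        other = TaggedMesh(mesh=moved_mesh, region_tags=dict(spine_mesh.region_tags))
        assert psd_centroid_distance(spine_mesh, other) == pytest.approx(5.0, rel=1e-9)

    def test_matches_direct_centroid_computation(self, spine_mesh):
        tris = spine_mesh.region_triangles("psd")
        areas = 0.5 * np.linalg.norm(
            np.cross(tris[:, 1] - tris[:, 0], tris[:, 2] - tris[:, 0]), axis=1)
        direct = (tris.mean(axis=1) * areas[:, None]).sum(axis=0) / areas.sum()
        moved_mesh = spine_mesh.mesh.copy()
        moved_mesh.apply_translation([1.0, 0.0, 0.0])
        other = TaggedMesh(mesh=moved_mesh, region_tags=dict(spine_mesh.region_tags))
        tris2 = other.region_triangles("psd")
        areas2 = 0.5 * np.linalg.norm(
            np.cross(tris2[:, 1] - tris2[:, 0], tris2[:, 2] - tris2[:, 0]), axis=1)
        direct2 = (tris2.mean(axis=1) * areas2[:, None]).sum(axis=0) / areas2.sum()
        expected = float(np.linalg.norm(direct - direct2))
        assert psd_centroid_distance(spine_mesh, other) == pytest.approx(expected,
                                                                         rel=1e-12)

    def test_missing_psd_region(self):
        with pytest.raises(TaggingError):
            psd_centroid_distance(cube_mesh(), cube_mesh())


class TestMeasurementError:
    def test_identical_replicates(self):
        out = measurement_error(MeasurementReplicates("s0", [0.2, 0.2, 0.2]))
        assert out["sem"] == pytest.approx(0.0, abs=1e-15)

    def test_hand_computed_quadruple(self):
        out = measurement_error(MeasurementReplicates("s0", [0.10, 0.10, 0.11, 0.11]))
        assert out["sem"] == pytest.approx(0.00289, abs=2e-5)
        assert out["relative_sem"] == pytest.approx(0.0275, abs=2e-4)

    def test_single_replicate_insufficient(self):
        with pytest.raises(InsufficientDataError):
            measurement_error(MeasurementReplicates("s0", [0.1]))

    def test_two_percent_tracer_noise_gives_one_percent_median_sem(self):
        # 4 replicates at 2% multiplicative noise: median relative SEM ≈ 1%
        rng = np.random.default_rng(17)
        rels = []
        for _ in range(287):
            true = rng.lognormal(np.log(0.03), 0.6)
            reps = true * np.exp(rng.normal(0, 0.02, size=4))
            rels.append(measurement_error(
                MeasurementReplicates("s", reps))["relative_sem"])
        assert np.median(rels) == pytest.approx(0.01, abs=0.003)
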