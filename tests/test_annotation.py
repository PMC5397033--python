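"""Landmark schemes, reflection, meshes and the constrained local search."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bodysam import _body
from bodysam.annotation import (PointSet, TriangleMesh, constrained_local_fit,
                                default_mesh, load_points, load_scheme,
                                make_patch_templates, reflect, save_points,
                                save_scheme, scheme_52, scheme_82,
                                subset_to_torso, template_points,
                                validate_mesh)
from bodysam.shape_model import align_translation, fit_shape_pca


class TestSchemes:
    def test_scheme_sizes(self):
        assert scheme_82().count == 82
        assert scheme_52().count == 52
        assert len(scheme_82().torso_subset) == 52

    def test_symmetry_pairs_are_disjoint_and_cover_non_midline(self):
        for scheme in (scheme_82(), scheme_52()):
            paired = [i for p in scheme.symmetry_pairs for i in p]
            assert len(set(paired)) == len(paired)
            assert set(paired) | set(scheme.midline_points) \
                == set(range(scheme.count))

    def test_torso_subset_is_symmetry_closed(self):
        full = scheme_82()
        partner = full.partner()
        subset = set(full.torso_subset)
        assert all(partner[i] in subset for i in subset)

    def test_template_is_bilaterally_symmetric(self):
        # default pose is symmetric, so mirrored partners share |x - cx|
        pts = template_points().coords
        partner = scheme_82().partner()
        cx = _body.BodyShapeParams().cx
        mirrored = pts[partner].copy()
        mirrored[:, 0] = 2 * cx - mirrored[:, 0]
        assert np.abs(pts - mirrored).max() < 1e-9


class TestSubset:
    def test_subset_picks_torso_indices_in_order(self):
        full = template_points()
        torso = subset_to_torso(full)
        assert torso.n == 52 and torso.scheme_id == "torso52"
        idx = list(scheme_82().torso_subset)
        assert np.array_equal(torso.coords, full.coords[idx])

    def test_subset_commutes_with_mean(self, rng):
        sets = [PointSet(template_points().coords + rng.normal(0, 2, (82, 2)),
                         "body82") for _ in range(5)]
        mean_then_subset = subset_to_torso(
            PointSet(np.mean([s.coords for s in sets], axis=0), "body82"))
        subset_then_mean = np.mean(
            [subset_to_torso(s).coords for s in sets], axis=0)
        assert np.allclose(mean_then_subset.coords, subset_then_mean)

    def test_subset_twice_rejected(self):
        with pytest.raises(ValueError, match="body82"):
            subset_to_torso(subset_to_torso(template_points()))


class TestReflect:
    @given(st.integers(0, 2 ** 16))
    @settings(max_examples=30, deadline=None)
    def test_involution_exact(self, raw_seed):
        # dyadic coordinates make the float mirror map exactly invertible
        rng = np.random.default_rng(raw_seed)
        coords = rng.integers(0, 1300, (82, 2)) / 4.0
        ps = PointSet(coords, "body82")
        back = reflect(reflect(ps, 327), 327)
        assert np.array_equal(back.coords, ps.coords)

    def test_midline_point_on_axis_is_fixed(self):
        coords = template_points().coords.copy()
        width = 327
        mid = scheme_82().midline_points
        coords[list(mid), 0] = (width - 1) / 2
        out = reflect(PointSet(coords, "body82"), width)
        assert np.array_equal(out.coords[list(mid)], coords[list(mid)])

    def test_left_right_labels_swap(self):
        # a left shoulder at (10, 50) and right at (90, 50) in a width-100
        # image: after reflection the left-shoulder label sits at (100-1-90, 50)
        scheme = scheme_82()
        li = scheme.point_names.index("shoulder_tip_l")
        ri = scheme.point_names.index("shoulder_tip_r")
        coords = template_points().coords.copy()
        coords[li] = (10.0, 50.0)
        coords[ri] = (90.0, 50.0)
        out = reflect(PointSet(coords, "body82"), 100)
        assert tuple(out.coords[li]) == (9.0, 50.0)
        assert tuple(out.coords[ri]) == (89.0, 50.0)

    def test_subset_commutes_with_reflection(self, rng):
        ps = PointSet(template_points().coords + rng.normal(0, 2, (82, 2)),
                      "body82")
        a = subset_to_torso(reflect(ps, 327))
        b = reflect(subset_to_torso(ps), 327)
        assert np.allclose(a.coords, b.coords)


class TestMesh:
    @pytest.mark.parametrize("scheme_id", ["body82", "torso52"])
    def test_shipped_mesh_is_clean(self, scheme_id):
        report = validate_mesh(default_mesh(scheme_id),
                               template_points(scheme_id))
        assert report.ok

    def test_repeated_vertex_triangle_is_degenerate(self):
        mesh = TriangleMesh(((0, 1, 1),), "torso52")
        with pytest.raises(ValueError, match="degenerate"):
            validate_mesh(mesh, template_points("torso52"))

    def test_missing_landmark_reported_uncovered(self):
        full = default_mesh("torso52")
        hole = 51
        pruned = tuple(t for t in full.triangles if hole not in t)
        report = validate_mesh(TriangleMesh(pruned, "torso52"),
                               template_points("torso52"))
        assert hole in report.uncovered


def _clm_setup():
    """Image + truth + shape model + templates for local-search tests."""
    from bodysam.pipeline import _subject_channels
    from bodysam.synthetic_phantoms import CohortSpec, sample_cohort

    cohort = CohortSpec(n=8, seed=21, noise_sd=0.0)
    phantoms, _ = sample_cohort(cohort)
    images = [_subject_channels(p, ["rvalue"])[0] for p in phantoms]
    points = [p.points for p in phantoms]
    # full-rank model: training shapes lie exactly in the span, so the truth
    # is representable and can be a fixed point of the constrained search
    model = fit_shape_pca(align_translation(points), 1.0)
    templates = make_patch_templates(images[0], points[0])
    return images, points, model, templates


@pytest.fixture(scope="module")
def setup():
    return _clm_setup()


class TestConstrainedLocalFit:

    def test_truth_is_a_fixed_point(self, setup):
        images, points, model, templates = setup
        fitted, converged = constrained_local_fit(images[1], points[1],
                                                  model, templates)
        assert converged
        err = np.linalg.norm(fitted.coords - points[1].coords, axis=1)
        assert err.mean() <= 0.5

    def test_noisy_init_improves(self, setup):
        images, points, model, templates = setup
        rng = np.random.default_rng(7)
        improved = 0
        for i in (1, 2, 3):
            noisy = PointSet(points[i].coords + rng.uniform(-5, 5, (82, 2)),
                             "body82")
            fitted, _ = constrained_local_fit(images[i], noisy, model,
                                              templates)
            err0 = np.linalg.norm(noisy.coords - points[i].coords,
                                  axis=1).mean()
            err1 = np.linalg.norm(fitted.coords - points[i].coords,
                                  axis=1).mean()
            improved += err1 < err0
        assert improved >= 2

    def test_blank_image_converges_to_shape_projection(self, setup):
        _, points, model, templates = setup
        blank = np.zeros((975, 327))
        fitted, converged = constrained_local_fit(blank, points[0], model,
                                                  templates)
        assert converged
        assert np.isfinite(fitted.coords).all()


class TestFileFormats:
    def test_points_round_trip(self, tmp_path):
        ps = template_points()
        save_points(tmp_path / "a.pts", ps)
        back = load_points(tmp_path / "a.pts")
        assert back.scheme_id == ps.scheme_id
        assert np.array_equal(back.coords, ps.coords)

    def test_scheme_round_trip(self, tmp_path):
        save_scheme(tmp_path / "s.json", scheme_82(), default_mesh("body82"))
        scheme, mesh = load_scheme(tmp_path / "s.json")
        assert scheme == scheme_82()
        assert mesh.triangles == default_mesh("body82").triangles
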