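import itertools

import numpy as np
import pytest

from infatlas.errors import ParameterError, SingularSystemError, SpaceError
from infatlas.phantom import PhantomConfig, generate_cohort, generate_smooth_field
from infatlas.registration import (
    EDGE_NONE,
    AffineTransform,
    SparseCorrespondences,
    affine_register,
    affine_to_field,
    apply_affine,
    compose,
    dct_basis,
    dct_normalise,
    deformable_register,
    detect_correspondences,
    extract_features,
    invert,
    mean_field,
    select_driving_voxels,
    tps_interpolate,
    warp,
)
from infatlas.segmentation import SegmentationResult
from infatlas.volumes_io import (
    DeformationField,
    LabelVolume,
    SpaceDef,
    TissueMaps,
    Volume,
)


@pytest.fixture(scope="module")
def clean_tm(clean_subject):
    return clean_subject.tissues[2]


@pytest.fixture(scope="module")
def clean_feat(clean_subject):
    return extract_features(clean_subject.tissues[2], radius_vox=2)


class TestAffine:
    def test_identity_for_identical_images(self, clean_subject):
        fix = clean_subject.images[2]
        t = affine_register(fix, fix, levels=2)
        assert np.abs(t.params).max() < 1e-3

    def test_translation_recovery(self, clean_subject):
        fix = clean_subject.images[2]
        shift = AffineTransform.identity(center=fix.space.center_world)
        shift.translation = np.array([-4.0, 2.0, -3.0])
        moving = apply_affine(fix, shift)  # content moved by (+4, -2, +3) mm
        rec = affine_register(moving, fix, levels=2)
        assert np.all(np.abs(rec.translation - [4.0, -2.0, 3.0]) < 0.5)

    def test_isotropic_scale_recovery(self, clean_subject):
        fix = clean_subject.images[2]
        sc = AffineTransform.identity(center=fix.space.center_world)
        sc.scale = np.array([1 / 1.1] * 3)  # content scaled up by 1.1
        moving = apply_affine(fix, sc)
        rec = affine_register(moving, fix, levels=2)
        assert np.all(np.abs(rec.scale - 1.1) < 0.02)

    def test_matrix_determinant_positive(self):
        t = AffineTransform.identity()
        assert np.linalg.det(t.matrix[:3, :3]) > 0
        t.scale = np.array([0.5, 2.0, 1.0])
        assert np.linalg.det(t.matrix[:3, :3]) > 0


class TestFeatures:
    def test_interior_has_no_edge_type(self, clean_feat, clean_subject):
        """Deep single-class voxels carry edge code none."""
        from scipy import ndimage
        hard = clean_subject.tissues[2].hard().data
        wm_core = ndimage.binary_erosion(hard == 3, iterations=2)
        assert wm_core.any()
        assert np.all(clean_feat.edge_type[wm_core] == EDGE_NONE)

    def test_gmi_rotation_invariance(self, clean_subject):
        """GMI channels commute exactly with 90-degree grid rotations."""
        tm = clean_subject.tissues[2]
        feat = extract_features(tm, radius_vox=2)
        rot = TissueMaps(
            {k: np.rot90(v, k=1, axes=(0, 1)).copy() for k, v in tm.maps.items()},
            np.rot90(tm.mask, k=1, axes=(0, 1)).copy(), tm.affine.copy())
        feat_rot = extract_features(rot, radius_vox=2)
        gmi = feat.features[..., feat.gmi_slice]
        gmi_rot = feat_rot.features[..., feat_rot.gmi_slice]
        expected = np.rot90(gmi, k=1, axes=(0, 1))
        assert np.allclose(gmi_rot, expected, atol=1e-6)

    def test_halfspace_interface_edge_type(self):
        """A planar GM/WM interface carries the GM-WM edge code exactly on
        the voxels a brute-force 6-neighbourhood scan flags."""
        space = SpaceDef((16, 16, 16), (1.0, 1.0, 1.0), (8, 8, 8))
        hard = np.full(space.dims, 2, dtype=np.uint8)
        hard[8:] = 3
        mask = np.ones(space.dims, bool)
        stack = np.stack([(hard == i + 1).astype(np.float32) for i in range(3)])
        tm = TissueMaps.from_stack(stack, mask, space.affine)
        feat = extract_features(tm, radius_vox=2)
        # brute force: voxel is GM-WM edge iff a 6-neighbour differs 2<->3
        brute = np.zeros(space.dims, bool)
        brute[7:9, :, :] = True
        got = feat.edge_type == 2  # GM-WM code
        assert np.array_equal(got, brute)

    def test_radius_too_large_rejected(self, clean_tm):
        with pytest.raises(ParameterError):
            extract_features(clean_tm, radius_vox=10)


class TestDrivingVoxels:
    def test_count_contract_before_suppression(self, clean_feat):
        n_cand = int(((clean_feat.edge_type != EDGE_NONE)
                      & clean_feat.mask).sum())
        pts = select_driving_voxels(clean_feat, 1.0, min_spacing=1)
        assert len(pts) == n_cand  # spacing 1 suppresses nothing

    def test_greedy_suppression_matches_oracle(self, clean_feat):
        """Selection equals a brute-force greedy re-implementation."""
        pts = select_driving_voxels(clean_feat, 0.5, min_spacing=2)
        # oracle: same ranking, explicit pairwise Chebyshev check
        cand = (clean_feat.edge_type != EDGE_NONE) & clean_feat.mask
        idx = np.argwhere(cand)
        gmi = clean_feat.features[..., clean_feat.gmi_slice]
        score = np.linalg.norm(gmi[cand], axis=1) + 1.0
        order = np.lexsort((idx[:, 2], idx[:, 1], idx[:, 0], -score))
        m = int(np.ceil(0.5 * len(idx)))
        kept = []
        for p in idx[order[:m]]:
            if all(np.abs(p - q).max() >= 2 for q in kept):
                kept.append(p)
        assert np.array_equal(pts, np.array(kept))

    def test_min_spacing_respected(self, clean_feat):
        pts = select_driving_voxels(clean_feat, 1.0, min_spacing=2)
        d = np.abs(pts[:, None, :] - pts[None, :, :]).max(axis=-1)
        np.fill_diagonal(d, 99)
        assert d.min() >= 2

    def test_uniform_image_has_no_driving_voxels(self, small_space):
        mask = np.zeros(small_space.dims, bool)
        mask[4:-4, 4:-4, 4:-4] = True
        stack = np.zeros((3,) + tuple(small_space.dims), np.float32)
        stack[2][mask] = 1.0  # all WM, no boundaries inside the mask...
        tm = TissueMaps.from_stack(stack, mask, small_space.affine)
        feat = extract_features(tm, radius_vox=2)
        feat.edge_type[:] = EDGE_NONE  # ...and none at the mask rim either
        with pytest.raises(ParameterError):
            select_driving_voxels(feat, 0.5)


class TestCorrespondences:
    def test_self_match_is_identity(self, clean_feat):
        pts = select_driving_voxels(clean_feat, 0.2)
        corr = detect_correspondences(pts, clean_feat, clean_feat,
                                      radius_vox=3, k=1, sim_floor=0.0)
        assert len(corr) == len(pts)
        assert np.abs(corr.targets - corr.sources).max() < 1e-9

    def test_known_integer_shift_recovered(self, clean_subject):
        """Moving features shifted by 3 voxels along x -> mean recovered
        displacement within 0.5 voxel of (3, 0, 0)."""
        tm = clean_subject.tissues[2]
        shifted = TissueMaps(
            {k: np.roll(v, 3, axis=0) for k, v in tm.maps.items()},
            np.roll(tm.mask, 3, axis=0), tm.affine.copy())
        # radius-3 moment neighbourhoods give features distinctive enough
        # to disambiguate self-similar stretches of the tissue boundary
        feat_fixed = extract_features(tm, radius_vox=3)
        feat_mov = extract_features(shifted, radius_vox=3)
        pts = select_driving_voxels(feat_mov, 0.3)
        pts = pts[(pts[:, 0] > 6) & (pts[:, 0] < 26)]  # away from wrap
        corr = detect_correspondences(pts, feat_fixed, feat_mov,
                                      radius_vox=5, k=1, sim_floor=0.0,
                                      distance_sigma_vox=100.0)
        disp_vox = (corr.targets - corr.sources) / 2.0
        mean_disp = disp_vox.mean(axis=0)
        assert np.abs(mean_disp - [-3.0, 0.0, 0.0]).max() < 0.5

    def test_impossible_floor_gives_empty_set(self, clean_feat):
        pts = select_driving_voxels(clean_feat, 0.1)
        corr = detect_correspondences(pts, clean_feat, clean_feat,
                                      radius_vox=3, k=3, sim_floor=1.1)
        assert len(corr) == 0

    def test_k_below_one_rejected(self, clean_feat):
        pts = select_driving_voxels(clean_feat, 0.1)
        with pytest.raises(ParameterError):
            detect_correspondences(pts, clean_feat, clean_feat, k=0)


class TestTPS:
    def _random_corr(self, rng, n, scale=30.0, disp=4.0):
        src = rng.uniform(-scale, scale, size=(n, 3))
        tgt = src + rng.uniform(-disp, disp, size=(n, 3))
        return SparseCorrespondences(src, tgt, np.ones(n))

    def test_exact_interpolation_at_controls(self, small_space):
        rng = np.random.default_rng(0)
        corr = self._random_corr(rng, 10)
        field = tps_interpolate(corr, small_space, ridge=0.0)
        # evaluate the spline at the control points through the same kernel
        from infatlas.registration import _ball_offsets  # noqa: F401 (import guard)
        vox = small_space.world_to_voxel(corr.sources)
        # direct evaluation: rebuild the solution and check residuals
        got = _tps_eval(corr, corr.sources)
        assert np.abs(got - (corr.targets - corr.sources)).max() < 1e-6

    def test_affine_displacements_reproduced_everywhere(self, small_space):
        """Controls drawn from an affine map -> the dense field matches
        that affine map at every voxel to 1e-3 mm."""
        rng = np.random.default_rng(1)
        A = np.eye(3) + rng.uniform(-0.05, 0.05, (3, 3))
        b = rng.uniform(-3, 3, 3)
        src = rng.uniform(-25, 25, size=(12, 3))
        tgt = src @ A.T + b
        corr = SparseCorrespondences(src, tgt, np.ones(len(src)))
        field = tps_interpolate(corr, small_space, ridge=0.0)
        idx = np.indices(small_space.dims).astype(float)
        world = np.stack([idx[i] * 2.0 - 32.0 for i in range(3)], axis=-1)
        expect = world @ (A - np.eye(3)).T + b
        assert np.abs(field.disp - expect).max() < 1e-3

    def test_collinear_points_rejected(self, small_space):
        src = np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]])
        corr = SparseCorrespondences(src, src + 1.0, np.ones(4))
        with pytest.raises(SingularSystemError):
            tps_interpolate(corr, small_space, ridge=0.0)

    def test_too_few_points_rejected(self, small_space):
        src = np.array([[0.0, 0, 0], [10, 0, 0], [0, 10, 0]])
        corr = SparseCorrespondences(src, src, np.ones(3))
        with pytest.raises(SingularSystemError):
            tps_interpolate(corr, small_space)

    def test_strided_evaluation_close_to_exact(self, small_space):
        rng = np.random.default_rng(2)
        corr = self._random_corr(rng, 15)
        exact = tps_interpolate(corr, small_space, ridge=0.0, eval_stride=1)
        fast = tps_interpolate(corr, small_space, ridge=0.0, eval_stride=2)
        assert np.abs(exact.disp - fast.disp).mean() < 0.2


def _tps_eval(corr, query):
    """Independent dense TPS evaluation used as the control-point oracle."""
    pts = corr.sources
    disp = corr.targets - corr.sources
    n = len(pts)
    K = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
    P = np.hstack([np.ones((n, 1)), pts])
    A = np.zeros((n + 4, n + 4))
    A[:n, :n] = K
    A[:n, n:] = P
    A[n:, :n] = P.T
    rhs = np.zeros((n + 4, 3))
    rhs[:n] = disp
    sol = np.linalg.solve(A, rhs)
    d = np.linalg.norm(query[:, None] - pts[None, :], axis=-1)
    return d @ sol[:n] + np.hstack([np.ones((len(query), 1)), query]) @ sol[n:]


class TestFieldAlgebra:
    def test_compose_with_zero_is_identity(self, small_space):
        g = generate_smooth_field(small_space, 3.0, 8.0, seed=4)
        zero = DeformationField.zero(small_space)
        assert np.array_equal(compose(g, zero).disp, g.disp)
        # compose(zero, g) = g exactly: zero looked up anywhere is zero
        assert np.allclose(compose(zero, g).disp, g.disp, atol=1e-7)

    def test_compose_then_invert_small_residual(self, small_space):
        f = generate_smooth_field(small_space, 3.0, 8.0, seed=5)
        g = invert(f)
        assert compose(f, g).mean_magnitude_voxels() < 0.1

    def test_invert_zero_and_translation_closed_forms(self, small_space):
        zero = DeformationField.zero(small_space)
        assert np.array_equal(invert(zero).disp, zero.disp)
        t = np.array([3.0, -1.0, 2.0], dtype=np.float32)
        const = DeformationField(
            np.broadcast_to(t, tuple(small_space.dims) + (3,)).copy(),
            small_space)
        inv = invert(const)
        assert np.allclose(inv.disp, -t, atol=1e-5)

    def test_associativity_on_smooth_fields(self, small_space):
        f = generate_smooth_field(small_space, 2.0, 10.0, seed=6)
        g = generate_smooth_field(small_space, 2.0, 10.0, seed=7)
        h = generate_smooth_field(small_space, 2.0, 10.0, seed=8)
        lhs = compose(compose(f, g), h)
        rhs = compose(f, compose(g, h))
        diff = np.linalg.norm((lhs.disp - rhs.disp) / 2.0, axis=-1)
        assert diff.mean() < 0.05

    def test_mean_field_arithmetic(self, small_space):
        rng = np.random.default_rng(3)
        fields = [DeformationField(
            rng.normal(size=tuple(small_space.dims) + (3,)).astype(np.float32),
            small_space) for _ in range(4)]
        m = mean_field(fields)
        brute = sum(f.disp.astype(np.float64) for f in fields) / 4
        assert np.abs(m.disp - brute).max() < 1e-6
        assert np.allclose(mean_field([fields[0], DeformationField(
            -fields[0].disp, small_space)]).disp, 0.0)
        assert np.array_equal(mean_field([fields[1], fields[1]]).disp,
                              fields[1].disp)
        with pytest.raises(ParameterError):
            mean_field([])

    def test_space_mismatch_rejected(self, small_space):
        other = SpaceDef((16, 16, 16), (2.0, 2.0, 2.0), (8, 8, 8))
        with pytest.raises(SpaceError):
            compose(DeformationField.zero(small_space),
                    DeformationField.zero(other))


class TestWarp:
    def test_zero_field_is_voxel_identity(self, clean_subject, small_space):
        zero = DeformationField.zero(small_space)
        vol = clean_subject.images[2]
        assert np.array_equal(warp(vol, zero).data, vol.data)
        lab = clean_subject.tissues[2].hard()
        assert np.array_equal(warp(lab, zero).data, lab.data)

    def test_integer_translation_on_labels(self, clean_subject, small_space):
        lab = clean_subject.tissues[2].hard()
        t = np.array([4.0, 0.0, 0.0], dtype=np.float32)  # 2 voxels at 2 mm
        f = DeformationField(
            np.broadcast_to(t, tuple(small_space.dims) + (3,)).copy(),
            small_space)
        out = warp(lab, f)
        assert np.array_equal(out.data[:-2], lab.data[2:])
        assert set(np.unique(out.data)) <= set(np.unique(lab.data))

    def test_warped_tissue_maps_sum_to_one(self, clean_subject, small_space):
        f = generate_smooth_field(small_space, 3.0, 8.0, seed=9)
        out = warp(clean_subject.tissues[2], f)
        out.validate()


class TestDeformableRegistration:
    def test_fixed_equals_moving_gives_near_zero_field(self, clean_tm):
        phi = deformable_register(clean_tm, clean_tm,
                                  schedule=((2, 0.2, 1),))
        assert phi.mean_magnitude_voxels() < 0.1

    def test_known_field_recovery_improves_both_metrics(self, clean_tm,
                                                        small_space):
        """Recovery of a known smooth field: the warped segmentation beats
        the unregistered (affine-equivalent) baseline in Dice and in
        residual displacement error."""
        from infatlas.evaluation import dice
        f_true = generate_smooth_field(small_space, 6.0, 10.0, seed=5)
        moving = warp(clean_tm, f_true)
        phi = deformable_register(moving, clean_tm)
        finv = invert(f_true)
        th = clean_tm.hard().data
        before = [dice(moving.hard().data, th, i) for i in (1, 2, 3)]
        after = [dice(warp(moving, phi).hard().data, th, i) for i in (1, 2, 3)]
        assert np.mean(after) > np.mean(before)
        mask = clean_tm.mask
        resid_before = np.linalg.norm(finv.disp / 2.0, axis=-1)[mask].mean()
        resid_after = np.linalg.norm(
            (phi.disp - finv.disp) / 2.0, axis=-1)[mask].mean()
        assert resid_after < resid_before


class TestDCT:
    @pytest.mark.parametrize("dims,count", [
        ((7, 8, 7), 1176), ((4, 4, 4), 192), ((2, 3, 5), 90),
    ])
    def test_coefficient_count_formula(self, dims, count, small_space,
                                       clean_subject):
        from infatlas.registration import DCTWarp
        coeffs = np.zeros((3,) + dims)
        w = DCTWarp(dims, coeffs, AffineTransform.identity(), small_space)
        assert w.n_coefficients == count == int(np.prod(dims)) * 3

    def test_basis_is_dct_ii(self):
        B = dct_basis(16, 4)
        assert B.shape == (16, 4)
        assert np.allclose(B[:, 0], 1.0)  # constant mode
        i = np.arange(16)
        assert np.allclose(B[:, 2], np.cos(np.pi * (2 * i + 1) * 2 / 32))

    def test_identity_fit_keeps_coefficients_at_zero(self, clean_subject):
        tmpl = clean_subject.images[2]
        w, field = dct_normalise(tmpl, tmpl, basis_dims=(3, 3, 3),
                                 fwhm_mm=0.0, max_iter=20)
        assert np.abs(w.coeffs).max() < 1e-3

    def test_in_span_warp_recovery(self, clean_subject, small_space):
        """A subject displaced by a warp inside the DCT span is recovered:
        SSD after the fit drops by >= 90% versus affine-only.

        The template is pre-smoothed (the gradient-based fit needs smooth
        images, as in the full protocol), the warp uses non-affine cosine
        modes (mode-1 cosines are nearly linear, so the affine baseline
        would absorb them), and the subject is built with the INVERSE of
        the span field so the pull-back fit's optimum lies in the span."""
        from infatlas.preprocess import gaussian_smooth_fwhm
        tmpl = gaussian_smooth_fwhm(clean_subject.images[2], 6.0)
        basis = (3, 3, 3)
        B = [dct_basis(small_space.dims[i], basis[i]) for i in range(3)]
        rng = np.random.default_rng(12)
        coeffs = np.zeros((3,) + basis)
        coeffs[:, 2, 0, 0] = rng.uniform(-2, 2, 3)
        coeffs[:, 0, 2, 1] = rng.uniform(-2, 2, 3)
        u = np.einsum("dabc,ia,jb,kc->ijkd", coeffs, B[0], B[1], B[2])
        span = DeformationField(u.astype(np.float32), small_space)
        subject = warp(tmpl, invert(span))
        w, field = dct_normalise(subject, tmpl, basis_dims=basis,
                                 fwhm_mm=0.0, max_iter=80)
        ssd_affine = float(((apply_affine(subject, w.affine).data
                             - tmpl.data) ** 2).sum())
        ssd_fit = float(((warp(subject, field).data - tmpl.data) ** 2).sum())
        assert ssd_fit < 0.1 * ssd_affine

    def test_basis_exceeding_grid_rejected(self, clean_subject):
        with pytest.raises(ParameterError):
            dct_normalise(clean_subject.images[2], clean_subject.images[2],
                          basis_dims=(64, 4, 4))
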