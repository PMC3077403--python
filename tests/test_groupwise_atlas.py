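import numpy as np
import pytest

from infatlas.atlas import (
    build_atlas,
    load_bundle,
    longitudinal_atlas_correspondence,
    save_bundle,
)
from infatlas.errors import PairingError, ParameterError, SpaceError
from infatlas.evaluation import dice
from infatlas.groupwise import groupwise_register, unbias
from infatlas.phantom import (
    PhantomConfig,
    base_anatomy,
    generate_cohort,
    generate_smooth_field,
    true_cross_age_field,
)
from infatlas.registration import compose, invert, mean_field, warp
from infatlas.segmentation import SegmentationResult
from infatlas.volumes_io import DeformationField, LabelVolume, TissueMaps, Volume


@pytest.fixture(scope="module")
def cohort6(small_space):
    cfg = PhantomConfig(n_subjects=6, grid=small_space, seed=3,
                        noise_sigma=0.0, bias_amplitude=0.0)
    return generate_cohort(cfg)


class TestUnbias:
    def test_opposite_fields_unchanged(self, small_space):
        f = generate_smooth_field(small_space, 3.0, 8.0, seed=1)
        neg = DeformationField(-f.disp, small_space)
        out = unbias([f, neg])
        assert np.array_equal(out[0].disp, f.disp)
        assert np.array_equal(out[1].disp, neg.disp)

    def test_common_mode_removed(self, small_space):
        f = generate_smooth_field(small_space, 3.0, 8.0, seed=2)
        out = unbias([f, f, f])
        for o in out:
            assert o.mean_magnitude_voxels() < 0.15

    def test_random_set_mean_shrinks_by_90pct(self, small_space):
        rng_seeds = [11, 12, 13, 14]
        fields = [generate_smooth_field(small_space, 3.0, 10.0, seed=s)
                  for s in rng_seeds]
        # add a common bias so the mean is substantial
        bias = generate_smooth_field(small_space, 2.0, 12.0, seed=99)
        fields = [compose(f, bias) for f in fields]
        before = mean_field(fields).mean_magnitude_voxels()
        after = mean_field(unbias(fields)).mean_magnitude_voxels()
        assert after < 0.1 * before


class TestGroupwise:
    def test_identical_subjects_near_zero_fields(self, clean_subject):
        segs = [SegmentationResult.from_soft(clean_subject.tissues[2])] * 4
        ints = [clean_subject.images[2]] * 4
        res = groupwise_register(segs, ints, outer_iters=1,
                                 schedule=((2, 0.2, 1),))
        for f in res.fields:
            assert f.mean_magnitude_voxels() < 0.1
        assert np.allclose(res.mean_image.data, clean_subject.images[2].data,
                           atol=1e-3)

    def test_cohort_mean_recovers_base_anatomy(self, cohort6, small_space):
        """Phantoms = one anatomy under random smooth fields: the group
        mean recovers the base anatomy (Dice > 0.9 per class) and the
        mean of the final fields is below 0.25 voxel."""
        segs = [SegmentationResult.from_soft(s.tissues[2]) for s in cohort6]
        ints = [s.images[2] for s in cohort6]
        res = groupwise_register(segs, ints, outer_iters=2,
                                 schedule=((3, 0.3, 2), (2, 0.3, 2)))
        assert mean_field(res.fields).mean_magnitude_voxels() < 0.25
        base_labels, _, _ = base_anatomy(small_space, 8)
        mh = res.mean_tpms.hard().data
        for lab in (1, 2, 3):
            assert dice(mh, base_labels, lab) > 0.9

    def test_too_few_subjects_rejected(self, clean_subject):
        segs = [SegmentationResult.from_soft(clean_subject.tissues[2])] * 2
        with pytest.raises(ParameterError):
            groupwise_register(segs, [clean_subject.images[2]] * 2)

    def test_order_independent_up_to_permutation(self, cohort6):
        """Permuting subject order permutes the output fields but does not
        change them (deterministic reference rule)."""
        segs = [SegmentationResult.from_soft(s.tissues[2]) for s in cohort6[:4]]
        ints = [s.images[2] for s in cohort6[:4]]
        res_a = groupwise_register(segs, ints, outer_iters=1,
                                   schedule=((2, 0.3, 1),))
        perm = [2, 0, 3, 1]
        res_b = groupwise_register([segs[i] for i in perm],
                                   [ints[i] for i in perm],
                                   outer_iters=1, schedule=((2, 0.3, 1),))
        assert perm[res_b.reference_index] == res_a.reference_index \
            or res_a.reference_index == perm[res_b.reference_index]
        for i, j in enumerate(perm):
            assert np.abs(res_a.fields[j].disp
                          - res_b.fields[i].disp).max() < 1e-5
        assert np.abs(res_a.mean_image.data - res_b.mean_image.data).max() < 1e-5


class TestBuildAtlas:
    def test_single_subject_bundle(self, clean_subject, small_space):
        tm = clean_subject.tissues[2]
        bundle = build_atlas([clean_subject.images[2]], [tm],
                             [clean_subject.parcellations[2]], small_space,
                             age=2)
        assert np.array_equal(bundle.template.data,
                              clean_subject.images[2].data)
        assert np.allclose(bundle.tpms.stack, tm.stack, atol=1e-6)
        bundle.validate()

    def test_opposite_intensities_average_to_zero(self, clean_subject,
                                                  small_space):
        v = clean_subject.images[2]
        neg = v.copy_with(-v.data)
        tm = clean_subject.tissues[2]
        parc = clean_subject.parcellations[2]
        bundle = build_atlas([v, neg], [tm, tm], [parc, parc], small_space)
        assert np.allclose(bundle.template.data, 0.0, atol=1e-5)

    def test_bundle_roundtrip(self, tmp_path, clean_subject, small_space):
        bundle = build_atlas([clean_subject.images[2]],
                             [clean_subject.tissues[2]],
                             [clean_subject.parcellations[2]], small_space,
                             age=2, provenance="test")
        save_bundle(bundle, str(tmp_path / "b"))
        back = load_bundle(str(tmp_path / "b"))
        assert back.age == 2
        assert np.allclose(back.template.data, bundle.template.data, atol=1e-6)
        assert np.array_equal(back.parcellation.data, bundle.parcellation.data)

    def test_space_mismatch_rejected(self, clean_subject, small_space):
        from infatlas.volumes_io import SpaceDef
        other = SpaceDef((16, 16, 16), (2.0, 2.0, 2.0), (8, 8, 8))
        with pytest.raises(SpaceError):
            build_atlas([clean_subject.images[2]],
                        [clean_subject.tissues[2]],
                        [clean_subject.parcellations[2]], other)


class TestCorrespondences:
    def test_all_zero_inputs_give_zero(self, small_space):
        z = DeformationField.zero(small_space)
        out = longitudinal_atlas_correspondence([z, z], [z, z], [z, z])
        assert np.abs(out.disp).max() < 1e-6

    def test_pure_scaling_growth_recovered(self, small_space):
        """Identical subjects with pure scaling growth and identity
        subject-to-atlas fields: the averaged correspondence is the
        scaling field to < 0.5 voxel mean error (interior)."""
        g = (0.82, 0.96, 1.0)
        f02 = true_cross_age_field(small_space, g[0], g[2])
        z = DeformationField.zero(small_space)
        out = longitudinal_atlas_correspondence([f02, f02], [z, z], [z, z])
        err = np.linalg.norm((out.disp - f02.disp) / 2.0, axis=-1)
        inner = (slice(6, -6),) * 3
        assert err[inner].mean() < 0.5

    def test_transitivity_chain(self, clean_subject, small_space):
        """Phi(0->1) then Phi(1->2) agrees with the direct Phi(0->2) to
        better than 1 voxel mean over the brain."""
        z = DeformationField.zero(small_space)
        subjects = [clean_subject]
        phi01 = longitudinal_atlas_correspondence(
            [s.true_fields[(0, 1)] for s in subjects], [z], [z])
        phi12 = longitudinal_atlas_correspondence(
            [s.true_fields[(1, 2)] for s in subjects], [z], [z])
        phi02 = longitudinal_atlas_correspondence(
            [s.true_fields[(0, 2)] for s in subjects], [z], [z])
        chained = compose(phi12, phi01)
        err = np.linalg.norm((chained.disp - phi02.disp) / 2.0, axis=-1)
        mask = clean_subject.tissues[0].mask
        assert err[mask].mean() < 1.0

    def test_missing_subject_rejected(self, small_space):
        z = DeformationField.zero(small_space)
        with pytest.raises(PairingError):
            longitudinal_atlas_correspondence([z, z], [z], [z, z])
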