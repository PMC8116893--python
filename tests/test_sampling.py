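import numpy as np
import pytest

from histadapt import (LabelMap, PriorAtlas, Volume, extract_25d_patch, prior_vector,
                       roi_from_priors, sample_lesions_stage1, sample_lesions_stage2,
                       sample_structures, split_train_val)
from histadapt.sampling import PatchExtractor, assemble_arrays


def _cube_label(shape=(24, 24, 24), lo=10, hi=13, cls=1, n_classes=2):
    data = np.zeros(shape, dtype=np.int32)
    data[lo:hi, lo:hi, lo:hi] = cls
    return LabelMap(data=data, class_count=n_classes)


class TestPatchExtraction:
    def test_constant_volume_gives_constant_patches(self):
        vol = Volume(data=np.full((16, 16, 16), 3.5))
        for patch in extract_25d_patch(vol, (8, 8, 8), size=5):
            assert np.all(patch == 3.5)

    def test_axial_patch_constant_in_z(self):
        data = np.zeros((32, 32, 16), dtype=np.float32)
        data[:, :, :] = np.arange(16)[None, None, :]
        vol = Volume(data=data)
        axial, sagittal, coronal = extract_25d_patch(vol, (16, 16, 7), size=9)
        assert np.all(axial == 7)
        # the other two planes sweep z and therefore vary
        assert sagittal.std() > 0 and coronal.std() > 0

    def test_corner_patch_matches_bruteforce_crop(self, rng):
        data = rng.normal(size=(12, 12, 12)).astype(np.float32)
        vol = Volume(data=data)
        size, half = 7, 3
        axial, _, _ = extract_25d_patch(vol, (0, 0, 5), size=size)
        brute = np.zeros((size, size), dtype=np.float32)
        for i in range(size):
            for j in range(size):
                x, y = i - half, j - half
                if 0 <= x < 12 and 0 <= y < 12:
                    brute[i, j] = data[x, y, 5]
        np.testing.assert_array_equal(axial, brute)

    def test_interior_patch_matches_direct_crop(self, rng):
        data = rng.normal(size=(16, 16, 16)).astype(np.float32)
        axial, sagittal, coronal = extract_25d_patch(Volume(data=data), (8, 7, 6), size=5)
        np.testing.assert_array_equal(axial, data[6:11, 5:10, 6])
        np.testing.assert_array_equal(sagittal, data[8, 5:10, 4:9])
        np.testing.assert_array_equal(coronal, data[6:11, 7, 4:9])

    def test_voxel_outside_raises(self):
        vol = Volume(data=np.zeros((8, 8, 8)))
        with pytest.raises(IndexError):
            extract_25d_patch(vol, (8, 0, 0), size=3)


class TestPriorVector:
    def test_one_hot_atlas(self):
        data = np.zeros((4, 4, 4, 3), dtype=np.float32)
        data[..., 2] = 1.0
        vec = prior_vector(PriorAtlas(data=data), (1, 1, 1))
        np.testing.assert_array_equal(vec, [0.0, 0.0, 1.0])

    @pytest.mark.parametrize("k", [15, 3])
    def test_vector_length_matches_channels(self, k):
        data = np.full((4, 4, 4, k), 1.0 / k, dtype=np.float32)
        assert prior_vector(PriorAtlas(data=data), (0, 0, 0)).shape == (k,)

    def test_outside_raises(self):
        atlas = PriorAtlas(data=np.zeros((4, 4, 4, 2), dtype=np.float32))
        with pytest.raises(IndexError):
            prior_vector(atlas, (0, 4, 0))


class TestSampleStructures:
    def test_boundary_negative_count_closed_form(self):
        # 3^3 cube, margin 5, cubic structuring element: 13^3 - 3^3 = 2170
        label = _cube_label()
        positives, negatives = sample_structures(label, margin=5)
        assert len(positives[1]) == 27
        assert len(negatives) == 13 ** 3 - 3 ** 3 == 2170

    def test_margin_zero_gives_no_negatives(self):
        _, negatives = sample_structures(_cube_label(), margin=0)
        assert len(negatives) == 0

    def test_negatives_within_margin_bruteforce(self):
        label = _cube_label(shape=(20, 20, 20), lo=8, hi=11)
        _, negatives = sample_structures(label, margin=2)
        fg = np.argwhere(label.data > 0)
        for v in negatives:
            assert label.data[tuple(v)] == 0
            cheb = np.abs(fg - v).max(axis=1).min()
            assert cheb <= 2

    def test_touching_structures_are_never_negatives(self):
        data = np.zeros((20, 20, 20), dtype=np.int32)
        data[8:10, 8:12, 8:12] = 1
        data[10:12, 8:12, 8:12] = 2
        label = LabelMap(data=data, class_count=3)
        positives, negatives = sample_structures(label, margin=3)
        neg_set = {tuple(v) for v in negatives}
        for c in (1, 2):
            for v in positives[c]:
                assert tuple(v) not in neg_set

    def test_empty_label_raises(self):
        with pytest.raises(ValueError):
            sample_structures(LabelMap(data=np.zeros((8, 8, 8), dtype=np.int32),
                                       class_count=2))


class TestLesionSampling:
    def _setup(self):
        label = _cube_label(shape=(20, 20, 20), lo=9, hi=12)
        brain = np.ones((20, 20, 20), dtype=bool)
        return label, brain

    def test_stage1_balanced(self):
        label, brain = self._setup()
        pos, neg = sample_lesions_stage1(label, brain, seed=0)
        assert len(pos) == len(neg) == 27
        assert all(label.data[tuple(v)] == 0 for v in neg)

    def test_stage1_deterministic(self):
        label, brain = self._setup()
        _, n1 = sample_lesions_stage1(label, brain, seed=3)
        _, n2 = sample_lesions_stage1(label, brain, seed=3)
        np.testing.assert_array_equal(n1, n2)

    def test_stage1_insufficient_negatives_raises(self):
        label = _cube_label(shape=(4, 4, 4), lo=0, hi=4)  # all lesion
        with pytest.raises(ValueError):
            sample_lesions_stage1(label, np.ones((4, 4, 4), dtype=bool), seed=0)

    def test_stage2_prefers_false_positives(self):
        label, brain = self._setup()
        pred = label.data.copy()
        fp_voxels = [(0, 0, i) for i in range(10)]
        for v in fp_voxels:
            pred[v] = 1
        pred_map = LabelMap(data=pred, class_count=2)
        pos, neg = sample_lesions_stage2(label, pred_map, brain, seed=1)
        neg_set = {tuple(v) for v in neg}
        assert len(pos) == len(neg) == 27
        # all 10 FPs used, remaining 17 drawn from elsewhere in the brain
        assert set(fp_voxels) <= neg_set

    def test_stage2_perfect_prediction_falls_back(self):
        label, brain = self._setup()
        pos, neg = sample_lesions_stage2(label, label, brain, seed=2)
        assert len(neg) == len(pos)
        assert all(label.data[tuple(v)] == 0 for v in neg)

    def test_stage2_excess_fps_capped_at_balance(self):
        label, brain = self._setup()
        pred = np.zeros_like(label.data)
        pred[label.data > 0] = 1
        pred[0:4, 0:4, 0:4] = 1  # 64 FPs > 27 positives
        pos, neg = sample_lesions_stage2(label, LabelMap(pred, class_count=2),
                                         brain, seed=3)
        assert len(neg) == 27
        assert all(pred[tuple(v)] == 1 and label.data[tuple(v)] == 0 for v in neg)


class TestSplitTrainVal:
    @pytest.mark.parametrize("n,frac,expected_val", [(100, 0.25, 25), (8, 0.25, 2)])
    def test_split_sizes(self, n, frac, expected_val):
        train, val = split_train_val(list(range(n)), val_fraction=frac, seed=0)
        assert len(val) == expected_val
        assert len(train) == n - expected_val
        assert sorted(train + val) == list(range(n))

    def test_same_seed_same_partition(self):
        a = split_train_val(list(range(40)), seed=9)
        b = split_train_val(list(range(40)), seed=9)
        assert a == b

    def test_too_few_samples_raises(self):
        with pytest.raises(ValueError):
            split_train_val([1, 2, 3], seed=0)


class TestRoiFromPriors:
    def _atlas_with_cube(self, lo=10, hi=13, shape=(24, 24, 24)):
        data = np.zeros(shape + (2,), dtype=np.float32)
        data[..., 0] = 1.0
        data[lo:hi, lo:hi, lo:hi, 1] = 0.8
        data[lo:hi, lo:hi, lo:hi, 0] = 0.2
        return PriorAtlas(data=data)

    def test_dilation_matches_bruteforce(self):
        roi = roi_from_priors(self._atlas_with_cube(), dilation_radius=2)
        expected = np.zeros((24, 24, 24), dtype=bool)
        expected[8:15, 8:15, 8:15] = True  # 3-cube dilated by 2 -> 7-cube
        np.testing.assert_array_equal(roi, expected)

    def test_radius_zero_is_support(self):
        roi = roi_from_priors(self._atlas_with_cube(), dilation_radius=0)
        assert roi.sum() == 27

    def test_empty_atlas_gives_empty_roi(self):
        data = np.zeros((8, 8, 8, 3), dtype=np.float32)
        data[..., 0] = 1.0
        assert not roi_from_priors(PriorAtlas(data=data), dilation_radius=3).any()


class TestAssembleArrays:
    def test_patches_match_single_extraction(self, rng):
        vol = Volume(data=rng.normal(size=(16, 16, 16)).astype(np.float32))
        atlas = PriorAtlas(data=np.full((16, 16, 16, 3), 1 / 3, dtype=np.float32))
        voxels = np.array([[8, 8, 8], [3, 12, 5]])
        patches, priors, labels = assemble_arrays(vol, atlas, voxels,
                                                  np.array([1, 0]), size=7)
        assert patches.shape == (2, 3, 7, 7)
        for i, v in enumerate(voxels):
            a, s, c = extract_25d_patch(vol, v, size=7)
            np.testing.assert_array_equal(patches[i, 0], a)
            np.testing.assert_array_equal(patches[i, 1], s)
            np.testing.assert_array_equal(patches[i, 2], c)
        np.testing.assert_allclose(priors, 1 / 3, atol=1e-6)
        np.testing.assert_array_equal(labels, [1, 0])
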