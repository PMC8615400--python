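"""SUVmax-threshold tumor delineation and conventional features."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from crosspet import conventional_features, segment_tumor
from crosspet.errors import MaskConflictError, NoLesionError
from crosspet.segmentation import TumorRoi

from conftest import make_suv


class TestSegmentTumor:
    def test_block_at_half_max(self, block_volume):
        # adjacent voxel of 4 is below 0.5 * 10 and must be excluded
        roi = segment_tumor(block_volume, 0.5)
        expected = np.zeros((9, 9, 9), dtype=bool)
        expected[3:6, 3:6, 3:6] = True
        assert np.array_equal(roi.mask, expected)
        assert roi.suv_max_used == 10.0

    def test_uniform_volume_selects_everything(self):
        roi = segment_tumor(make_suv(np.full((4, 4, 4), 2.0)))
        assert roi.mask.all()

    def test_connected_component_excludes_disjoint_blob(self):
        vox = np.zeros((12, 12, 12))
        vox[1:4, 1:4, 1:4] = 10.0
        vox[8:11, 8:11, 8:11] = 8.0  # above threshold 5 but disconnected
        roi = segment_tumor(make_suv(vox), 0.5)
        # oracle: exhaustive flood fill from the seed over the supra-threshold set
        supra = vox >= 5.0
        seen = {tuple(roi.seed)}
        frontier = [roi.seed]
        while frontier:
            v = frontier.pop()
            for dz in (-1, 0, 1):
                for dy in (-1, 0, 1):
                    for dx in (-1, 0, 1):
                        w = (v[0] + dz, v[1] + dy, v[2] + dx)
                        if (
                            all(0 <= c < 12 for c in w)
                            and w not in seen
                            and supra[w]
                        ):
                            seen.add(w)
                            frontier.append(w)
        assert {tuple(v) for v in np.argwhere(roi.mask)} == seen
        assert not roi.mask[8:11, 8:11, 8:11].any()

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(
        lo=st.floats(min_value=0.2, max_value=0.5),
        hi=st.floats(min_value=0.5, max_value=0.95),
        seed=st.integers(min_value=0, max_value=100),
    )
    def test_threshold_monotonicity(self, lo, hi, seed):
        rng = np.random.default_rng(seed)
        vol = make_suv(rng.random((7, 7, 7)) + 0.1)
        small = segment_tumor(vol, max(lo, hi)).mask
        large = segment_tumor(vol, min(lo, hi)).mask
        assert np.all(large[small])  # raising the threshold never grows the ROI

    def test_scale_invariance(self, block_volume):
        base = segment_tumor(block_volume, 0.5)
        scaled = segment_tumor(make_suv(block_volume.voxels * 7.3), 0.5)
        assert np.array_equal(base.mask, scaled.mask)

    def test_suvmax_tie_resolves_to_lowest_linear_index(self):
        vox = np.zeros((5, 5, 5))
        vox[4, 4, 4] = 3.0
        vox[1, 1, 1] = 3.0
        roi = segment_tumor(make_suv(vox))
        assert roi.seed == (1, 1, 1)

    def test_all_zero_volume_rejected(self):
        with pytest.raises(NoLesionError):
            segment_tumor(make_suv(np.zeros((4, 4, 4))))

    def test_search_region_restricts_seed(self):
        vox = np.zeros((10, 10, 10))
        vox[1:3, 1:3, 1:3] = 10.0
        vox[7:9, 7:9, 7:9] = 6.0
        region = np.zeros((10, 10, 10), dtype=bool)
        region[6:, 6:, 6:] = True
        roi = segment_tumor(make_suv(vox), 0.5, search_region=region)
        assert roi.suv_max_used == 6.0
        assert roi.mask[7, 7, 7]

    def test_strict_threshold_excludes_boundary_value(self):
        vox = np.zeros((5, 5, 5))
        vox[2, 2, 2] = 10.0
        vox[2, 2, 3] = 5.0  # exactly 50 %
        inclusive = segment_tumor(make_suv(vox), 0.5)
        strict = segment_tumor(make_suv(vox), 0.5, strict=True)
        assert inclusive.mask[2, 2, 3] and not strict.mask[2, 2, 3]


class TestConventionalFeatures:
    def _roi(self, mask):
        seed = tuple(np.argwhere(mask)[0])
        return TumorRoi(mask=mask, seed=seed, threshold_fraction=0.5, suv_max_used=1.0)

    def test_hand_arithmetic(self):
        vox = np.zeros((2, 3, 1))
        vox[0, :, 0] = [2, 4, 6]
        vox[1, :, 0] = [1, 1, 2]
        tumor = np.zeros_like(vox, dtype=bool)
        tumor[0] = True
        normal = np.zeros_like(vox, dtype=bool)
        normal[1] = True
        suv = make_suv(vox)
        roi = self._roi(tumor)
        roi.suv_max_used = 6.0
        feats = conventional_features(suv, roi, normal)
        assert feats.suv_max == 6 and feats.suv_median == 4 and feats.suv_min == 2
        assert feats.tn_ratio == pytest.approx(3.0)

    def test_equal_means_give_unit_ratio(self):
        vox = np.concatenate([np.full((2, 2, 2), 5.0), np.full((2, 2, 2), 5.0)])
        tumor = np.zeros((4, 2, 2), dtype=bool)
        tumor[:2] = True
        normal = ~tumor
        feats = conventional_features(make_suv(vox), self._roi(tumor), normal)
        assert feats.tn_ratio == pytest.approx(1.0)

    def test_tn_invariant_under_global_scaling(self):
        rng = np.random.default_rng(3)
        vox = rng.random((4, 4, 4)) + 1
        tumor = np.zeros((4, 4, 4), dtype=bool)
        tumor[:2] = True
        normal = ~tumor
        f1 = conventional_features(make_suv(vox), self._roi(tumor), normal)
        f2 = conventional_features(make_suv(vox * 11.0), self._roi(tumor), normal)
        assert f1.tn_ratio == pytest.approx(f2.tn_ratio)

    def test_phantom_ground_truth_tn_ratio(self, phantom_pair):
        # generator truth: lesion mean 5, background mean 2 -> T/N near 2.5
        vol_a, _, lesion, normal = phantom_pair
        roi = self._roi(lesion)
        feats = conventional_features(vol_a, roi, normal)
        assert feats.tn_ratio == pytest.approx(2.5, rel=0.12)

    def test_overlapping_masks_rejected(self):
        vox = np.ones((3, 3, 3))
        tumor = np.zeros((3, 3, 3), dtype=bool)
        tumor[0] = True
        with pytest.raises(MaskConflictError):
            conventional_features(make_suv(vox), self._roi(tumor), tumor)

    def test_zero_normal_mean_rejected(self):
        vox = np.zeros((3, 3, 3))
        vox[0] = 1.0
        tumor = np.zeros((3, 3, 3), dtype=bool)
        tumor[0] = True
        normal = np.zeros((3, 3, 3), dtype=bool)
        normal[2] = True
        with pytest.raises(ZeroDivisionError):
            conventional_features(make_suv(vox), self._roi(tumor), normal)
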