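"""Copy-paste synthesis: ROI, patch transforms, placement, setup semantics."""

import numpy as np
import pytest
from scipy import ndimage

from appleseg import (DefectPatch, Sample, SynthesisConfig, classic_augment,
                      compute_roi, extract_defects, place_defects,
                      rotate_patch, synthesize, warp_patch)
from appleseg.synthesis import SETUP_TABLE


class TestComputeRoi:
    def test_recovers_phantom_ellipse(self, healthy_samples):
        s = healthy_samples[0]
        roi = compute_roi(s, 0.04)
        # agreement within a 2-pixel boundary band of the generator ellipse
        ell = s._ellipse_mask
        band = ndimage.binary_dilation(ell, iterations=2) & ~ndimage.binary_erosion(ell, iterations=2)
        disagree = roi.mask ^ ell
        assert not np.any(disagree & ~band)

    def test_all_black_raises_all_bright_full(self):
        black = Sample(image=np.zeros((8, 8, 3)), mask=np.zeros((8, 8), np.uint8))
        with pytest.raises(ValueError, match="empty ROI"):
            compute_roi(black, 0.04)
        bright = Sample(image=np.full((8, 8, 3), 0.9), mask=np.zeros((8, 8), np.uint8))
        assert compute_roi(bright, 0.04).mask.all()


class TestExtractDefects:
    def test_one_patch_per_annotation_with_conserved_pixels(self, defective_samples):
        s = defective_samples[0]
        patches = extract_defects(s)
        assert len(patches) == len(s.defects)
        for patch, ann in zip(patches, s.defects):
            assert patch.sub_class == ann.sub_class
            assert patch.mask.sum() == ann.defect_mask.sum()

    def test_paste_back_at_source_is_identity(self, defective_samples):
        s = defective_samples[0]
        ann = s.defects[0]
        patch = extract_defects(s)[0]
        ys, xs = np.nonzero(ann.defect_mask)
        y0, x0 = ys.min(), xs.min()
        img = s.image.copy()
        img[y0:y0 + patch.mask.shape[0], x0:x0 + patch.mask.shape[1]][patch.mask] = \
            patch.pixels[patch.mask]
        assert np.array_equal(img, s.image)

    def test_healthy_sample_rejected(self, healthy_samples):
        with pytest.raises(ValueError):
            extract_defects(healthy_samples[0])


def _disc_patch(r=5, channels=4):
    yy, xx = np.mgrid[-r:r + 1, -r:r + 1]
    mask = yy * yy + xx * xx <= r * r
    pix = np.full((*mask.shape, channels), 0.5)
    return DefectPatch(pixels=pix, mask=mask, sub_class="rot")


class TestRotatePatch:
    def test_angle_zero_is_identity(self):
        p = _disc_patch()
        q = rotate_patch(p, 0.0)
        assert np.array_equal(q.mask, p.mask)
        assert np.array_equal(q.pixels, p.pixels)

    def test_right_angle_equals_index_permutation(self, rng):
        mask = rng.random((9, 9)) > 0.5
        mask[4, 4] = True
        pix = rng.random((9, 9, 4))
        p = DefectPatch(pixels=pix, mask=mask, sub_class="rot")
        q = rotate_patch(p, 90.0)
        # oracle: exact 90-degree index permutation, then crop to the mask
        om = np.rot90(mask)
        ys, xs = np.nonzero(om)
        sl = (slice(ys.min(), ys.max() + 1), slice(xs.min(), xs.max() + 1))
        assert np.array_equal(q.mask, om[sl])
        assert np.allclose(q.pixels[q.mask], np.rot90(pix)[sl][q.mask], atol=1e-9)

    def test_two_half_turns_restore_mask(self):
        p = _disc_patch(6)
        q = rotate_patch(rotate_patch(p, 180.0), 180.0)
        assert np.array_equal(q.mask, p.mask)


class TestWarpPatch:
    CFG = SynthesisConfig(setup_id=6)

    def test_zero_scale_is_identity(self, rng):
        p = _disc_patch(6)
        cfg = SynthesisConfig(setup_id=6, warp_grid=(3, 0.0))
        q = warp_patch(p, cfg, rng)
        assert np.array_equal(q.mask, p.mask)
        assert np.allclose(q.pixels[q.mask], p.pixels[p.mask])

    def test_deterministic_given_seed(self):
        p = _disc_patch(6)
        a = warp_patch(p, self.CFG, np.random.default_rng(42))
        b = warp_patch(p, self.CFG, np.random.default_rng(42))
        assert np.array_equal(a.mask, b.mask)
        assert np.array_equal(a.pixels, b.pixels)

    def test_area_stays_within_band_at_default_scale(self):
        """Monte-Carlo over 100 seeds: the warped disc's area stays within
        +-40% of the input area at the default displacement scale."""
        p = _disc_patch(8)
        area = p.mask.sum()
        for seed in range(100):
            q = warp_patch(p, self.CFG, np.random.default_rng(seed))
            assert 0.6 * area <= q.mask.sum() <= 1.4 * area


class TestPlaceDefects:
    def test_disc_placed_inside_roi_with_conserved_count(self, healthy_samples, rng):
        s = healthy_samples[0]
        roi = compute_roi(s, 0.04)
        patch = _disc_patch(3)
        out = place_defects(s, [patch], roi, SynthesisConfig(), rng)
        assert out.mask.sum() == patch.mask.sum()
        assert np.all(roi.mask[out.mask > 0])

    def test_unplaceable_patch_leaves_input_unchanged(self, healthy_samples, rng):
        s = healthy_samples[0]
        roi = compute_roi(s, 0.04)
        huge = DefectPatch(pixels=np.full((150, 150, 4), 0.5),
                           mask=np.ones((150, 150), dtype=bool),
                           sub_class="rot")
        out = place_defects(s, [huge], roi, SynthesisConfig(), rng)
        assert out.is_healthy
        assert np.array_equal(out.image, s.image)

    def test_three_patches_union_and_flags(self, healthy_samples, rng):
        s = healthy_samples[1]
        roi = compute_roi(s, 0.04)
        out = place_defects(s, [_disc_patch(3)] * 3, roi, SynthesisConfig(), rng)
        assert not out.is_healthy
        _, nlab = ndimage.label(out.mask)
        assert 1 <= nlab <= 3


class TestSynthesize:
    def test_setup_table_matches_six_row_matrix(self):
        expected = {1: ((0, 0), False, False), 2: ((1, 1), False, False),
                    3: ((1, 1), True, False), 4: ((1, 1), True, True),
                    5: ((1, 3), True, False), 6: ((1, 3), True, True)}
        assert SETUP_TABLE == expected

    def test_setup1_is_identity(self, healthy_samples, defective_samples, rng):
        s = healthy_samples[0]
        out = synthesize(s, defective_samples, SynthesisConfig(setup_id=1), rng)
        assert out is s

    def test_p_zero_is_identity(self, healthy_samples, defective_samples):
        rng = np.random.default_rng(0)
        cfg = SynthesisConfig(setup_id=5, probability_p=0.0)
        s = healthy_samples[0]
        for _ in range(200):
            assert synthesize(s, defective_samples, cfg, rng) is s

    def test_empty_pool_raises(self, healthy_samples, rng):
        with pytest.raises(ValueError, match="pool"):
            synthesize(healthy_samples[0], [], SynthesisConfig(setup_id=2), rng)

    def test_contracts_over_seeded_calls(self, healthy_samples, defective_samples):
        """Changed pixels lie inside the output mask; every defect pixel is
        inside the ROI; same seed reproduces bit-identical output."""
        cfg = SynthesisConfig(setup_id=5, probability_p=1.0)
        s = healthy_samples[2]
        roi = compute_roi(s, cfg.roi_threshold)
        for seed in range(30):
            out = synthesize(s, defective_samples, cfg,
                             np.random.default_rng(seed))
            changed = np.any(out.image != s.image, axis=2)
            assert not np.any(changed & (out.mask == 0))
            assert np.all(roi.mask[out.mask > 0])
            again = synthesize(s, defective_samples, cfg,
                               np.random.default_rng(seed))
            assert np.array_equal(again.image, out.image)
            assert np.array_equal(again.mask, out.mask)


class TestClassicAugment:
    def test_gate_not_fired_is_identity(self, defective_samples):
        s = defective_samples[0]
        # find a seed whose first uniform draw is >= 0.5 (gate closed)
        seed = next(i for i in range(50)
                    if np.random.default_rng(i).random() >= 0.5)
        out = classic_augment(s, np.random.default_rng(seed))
        assert out is s

    def test_flips_conserve_mask_count(self, defective_samples):
        s = defective_samples[1]
        count = s.mask.sum()
        for seed in range(20):
            out = classic_augment(s, np.random.default_rng(seed))
            # rotation interpolates, flips are exact; either way the mask
            # count stays within the interpolation band
            assert abs(int(out.mask.sum()) - int(count)) <= 0.2 * count

    def test_hflip_twice_is_identity(self, defective_samples):
        s = defective_samples[2]
        flipped = Sample(image=np.ascontiguousarray(s.image[:, ::-1]),
                         mask=np.ascontiguousarray(s.mask[:, ::-1]),
                         sample_id=s.sample_id)
        twice = np.ascontiguousarray(flipped.image[:, ::-1])
        assert np.array_equal(twice, s.image)
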