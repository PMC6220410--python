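"""Resampling, normalisation, slice filtering, balancing, augmentation."""

from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gtvnet.imaging_io import ImageVolume
from gtvnet.preprocess import (SamplePair, apply_gamma, apply_geometric,
                               augment, balance_samples,
                               filter_small_tumor_slices, minmax_normalize,
                               resample_pet_to_ct)


def brute_force_resample(pet, ct):
    """Per-voxel closed-form trilinear interpolation with edge clamping."""
    out = np.zeros(ct.voxels.shape)
    src = pet.voxels
    for idx in np.ndindex(out.shape):
        pos = [i * cs / ps for i, cs, ps in
               zip(idx, ct.spacing_mm, pet.spacing_mm)]
        pos = [min(max(p, 0.0), n - 1) for p, n in zip(pos, src.shape)]
        lo = [int(np.floor(p)) for p in pos]
        hi = [min(l + 1, n - 1) for l, n in zip(lo, src.shape)]
        f = [p - l for p, l in zip(pos, lo)]
        acc = 0.0
        for dx in (0, 1):
            for dy in (0, 1):
                for dz in (0, 1):
                    w = ((f[0] if dx else 1 - f[0])
                         * (f[1] if dy else 1 - f[1])
                         * (f[2] if dz else 1 - f[2]))
                    acc += w * src[hi[0] if dx else lo[0],
                                   hi[1] if dy else lo[1],
                                   hi[2] if dz else lo[2]]
        out[idx] = acc
    return out


class TestResample:
    def test_identity_when_grids_match(self):
        rng = np.random.default_rng(0)
        pet = ImageVolume(rng.random((8, 8, 4)), (2, 2, 2), "PET")
        ct = ImageVolume(np.zeros((8, 8, 4)), (2, 2, 2), "CT")
        out = resample_pet_to_ct(pet, ct)
        np.testing.assert_array_equal(out.voxels, pet.voxels)

    def test_constant_field_preserved(self):
        pet = ImageVolume(np.full((6, 6, 3), 3.7), (4, 4, 4), "PET")
        ct = ImageVolume(np.zeros((12, 12, 6)), (2, 2, 2), "CT")
        out = resample_pet_to_ct(pet, ct)
        np.testing.assert_allclose(out.voxels, 3.7)

    def test_linear_ramp_midpoints(self):
        """Halving the spacing along x puts new voxels at the arithmetic
        means of their neighbours (closed-form linear interpolation)."""
        ramp = np.arange(8, dtype=float)[:, None, None] * np.ones((8, 4, 2))
        pet = ImageVolume(ramp, (2, 2, 2), "PET")
        ct = ImageVolume(np.zeros((15, 4, 2)), (1, 2, 2), "CT")
        out = resample_pet_to_ct(pet, ct)
        np.testing.assert_allclose(out.voxels[1, 0, 0], 0.5)
        np.testing.assert_allclose(out.voxels[7, 0, 0], 3.5)
        np.testing.assert_allclose(out.voxels[14, 0, 0], 7.0)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(5):
            pet = ImageVolume(rng.random((5, 6, 3)), (3.1, 2.7, 3.9), "PET")
            ct = ImageVolume(np.zeros((8, 8, 4)), (1.9, 2.0, 2.8), "CT")
            out = resample_pet_to_ct(pet, ct)
            np.testing.assert_allclose(out.voxels,
                                       brute_force_resample(pet, ct),
                                       atol=1e-10)

    def test_convexity_bounds(self):
        rng = np.random.default_rng(1)
        pet = ImageVolume(rng.random((6, 6, 4)), (3, 3, 3), "PET")
        ct = ImageVolume(np.zeros((10, 10, 7)), (1.7, 1.7, 1.7), "CT")
        out = resample_pet_to_ct(pet, ct)
        assert out.voxels.min() >= pet.voxels.min() - 1e-12
        assert out.voxels.max() <= pet.voxels.max() + 1e-12


class TestNormalize:
    def test_basic_rescale(self):
        vol = ImageVolume(np.array([[[0.0, 5.0, 10.0]]]), (1, 1, 1), "CT")
        out = minmax_normalize(vol)
        np.testing.assert_allclose(out.voxels, [[[0.0, 0.5, 1.0]]])

    def test_idempotent_on_unit_range(self):
        rng = np.random.default_rng(0)
        v = rng.random((4, 4, 2))
        v.flat[0], v.flat[-1] = 0.0, 1.0
        vol = ImageVolume(v, (1, 1, 1), "CT")
        np.testing.assert_allclose(minmax_normalize(vol).voxels, v)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(a=st.floats(0.1, 50.0), b=st.floats(-20.0, 20.0))
    def test_affine_invariance(self, a, b):
        rng = np.random.default_rng(9)
        v = rng.random((4, 4, 2))
        base = minmax_normalize(ImageVolume(v, (1, 1, 1), "CT")).voxels
        scaled = minmax_normalize(
            ImageVolume(a * v + b, (1, 1, 1), "CT")).voxels
        np.testing.assert_allclose(scaled, base, atol=1e-9)

    def test_constant_volume_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            minmax_normalize(ImageVolume(np.ones((3, 3, 2)), (1, 1, 1), "CT"))


class TestSliceFilter:
    def _case_with_areas(self, pixel_counts, spacing=(0.49, 0.49, 2.5)):
        from gtvnet.phantom import PatientCase
        n = len(pixel_counts)
        shape = (64, 64, n)
        rng = np.random.default_rng(0)
        mask = np.zeros(shape, dtype=np.uint8)
        for k, cnt in enumerate(pixel_counts):
            mask[:, :, k].flat[:cnt] = 1
        ct = ImageVolume(rng.random(shape), spacing, "CT")
        pet = ImageVolume(rng.random(shape), spacing, "PET")
        return PatientCase("f", "A", ct, pet,
                           ImageVolume(mask, spacing, "MASK"), 0.0)

    def test_threshold_arithmetic_at_clinical_spacing(self):
        """208 px * 0.2401 mm^2 = 49.94 mm^2 < 0.5 cm^2 is dropped;
        209 px = 50.18 mm^2 is kept positive."""
        case = self._case_with_areas([208, 209, 0])
        samples = filter_small_tumor_slices(case, min_area_cm2=0.5)
        kept = {s.slice_index: s.is_positive for s in samples}
        assert 0 not in kept
        assert kept[1] is True
        assert kept[2] is False

    def test_full_mask_slice_positive(self):
        case = self._case_with_areas([64 * 64])
        samples = filter_small_tumor_slices(case, 0.5)
        assert samples[0].is_positive

    def test_normalized_channels_in_unit_interval(self, desk_case):
        for s in filter_small_tumor_slices(desk_case, 0.5):
            assert 0.0 <= s.ct_slice.min() and s.ct_slice.max() <= 1.0
            assert 0.0 <= s.pet_slice.min() and s.pet_slice.max() <= 1.0


class TestBalance:
    def _samples(self, n_pos, n_neg):
        def mk(i, pos):
            m = np.zeros((8, 8), dtype=np.uint8)
            if pos:
                m[:4, :4] = 1
            return SamplePair(np.zeros((8, 8)), np.zeros((8, 8)), m,
                              (2.0, 2.0), 4.0, "p", i, pos)
        return ([mk(i, True) for i in range(n_pos)]
                + [mk(100 + i, False) for i in range(n_neg)])

    def test_equal_counts_after_balancing(self):
        out = balance_samples(self._samples(10, 30),
                              np.random.default_rng(0))
        assert len(out) == 20
        assert sum(s.is_positive for s in out) == 10

    def test_positives_all_retained(self):
        samples = self._samples(10, 30)
        out = balance_samples(samples, np.random.default_rng(0))
        assert {id(s) for s in samples if s.is_positive} <= {id(s)
                                                             for s in out}

    def test_few_negatives_kept_with_warning(self):
        with pytest.warns(UserWarning, match="negatives"):
            out = balance_samples(self._samples(10, 4),
                                  np.random.default_rng(0))
        assert len(out) == 14

    def test_deterministic_under_seed(self):
        samples = self._samples(5, 20)
        a = balance_samples(samples, np.random.default_rng(7))
        b = balance_samples(samples, np.random.default_rng(7))
        assert [s.slice_index for s in a] == [s.slice_index for s in b]

    def test_no_positives_rejected(self):
        with pytest.raises(ValueError):
            balance_samples(self._samples(0, 5), np.random.default_rng(0))


class TestAugment:
    def test_mirror_is_involution(self, toy_sample):
        once = apply_geometric(toy_sample, mirror=True)
        twice = apply_geometric(once, mirror=True)
        np.testing.assert_array_equal(twice.ct_slice, toy_sample.ct_slice)
        np.testing.assert_array_equal(twice.gold_mask, toy_sample.gold_mask)

    def test_mirror_preserves_mask_area_exactly(self, toy_sample):
        out = apply_geometric(toy_sample, mirror=True)
        assert out.gold_mask.sum() == toy_sample.gold_mask.sum()

    def test_gamma_leaves_mask_untouched(self, toy_sample):
        out = apply_gamma(toy_sample, 1.2)
        np.testing.assert_array_equal(out.gold_mask, toy_sample.gold_mask)
        assert not np.array_equal(out.ct_slice, toy_sample.ct_slice)

    def test_rotation_preserves_area_within_tolerance(self, toy_sample):
        rng = np.random.default_rng(5)
        base = toy_sample.gold_mask.sum()
        for _ in range(10):
            out = apply_geometric(toy_sample,
                                  angle_deg=rng.uniform(-15, 15))
            assert abs(int(out.gold_mask.sum()) - int(base)) / int(base) <= 0.15

    def test_scaling_changes_area_quadratically(self, toy_sample):
        base = toy_sample.gold_mask.sum()
        for scale in (0.9, 1.1):
            out = apply_geometric(toy_sample, scale=scale)
            assert out.gold_mask.sum() == pytest.approx(base * scale ** 2,
                                                        rel=0.2)

    def test_factor_count_and_clipping(self, toy_sample, rng):
        out = augment(toy_sample, rng, factor=16)
        assert len(out) == 16
        for s in out:
            assert s.ct_slice.min() >= 0.0 and s.ct_slice.max() <= 1.0

    def test_deterministic_under_seed(self, toy_sample):
        a = augment(toy_sample, np.random.default_rng(3), 4)
        b = augment(toy_sample, np.random.default_rng(3), 4)
        for sa, sb in zip(a, b):
            np.testing.assert_array_equal(sa.ct_slice, sb.ct_slice)
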