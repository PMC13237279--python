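"""CarveMix hard-replacement semantics, Mixup, flips/rotation, M+kM expansion."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from kitefusion.augmentation import (
    FROM_A,
    FROM_B,
    AugmentationError,
    MixupSample,
    basic_augment,
    carvemix,
    expand_dataset,
    hflip,
    mixup,
    rotate,
    sample_mixup_lambda,
    vflip,
)
from kitefusion.imaging_io import SlicePair


def make_pair(image, mask, modality="PET", pid="p", label="benign"):
    return SlicePair(
        image=np.asarray(image, dtype=np.float32),
        mask=np.asarray(mask, dtype=np.uint8),
        modality=modality,
        patient_id=pid,
        label=label,
    )


def random_pair(rng, shape=(16, 16), pid="p"):
    return make_pair(
        rng.normal(size=shape), (rng.random(shape) < 0.2).astype(np.uint8), pid=pid
    )


class TestCarveMix:
    def test_single_pixel_carve(self):
        m1 = np.zeros((4, 4), np.uint8)
        m1[1, 1] = 1
        a = make_pair(np.full((4, 4), 10.0), m1, pid="a")
        b = make_pair(np.full((4, 4), 2.0), np.zeros((4, 4)), pid="b")
        out = carvemix(a, b)
        expected = np.full((4, 4), 2.0)
        expected[1, 1] = 10.0
        np.testing.assert_array_equal(out.image, expected)
        np.testing.assert_array_equal(out.mask, m1)
        assert out.patient_id.startswith("synthetic:")

    def test_empty_carve_is_identity_on_background_slice(self, rng):
        a = make_pair(rng.normal(size=(8, 8)), np.zeros((8, 8)), pid="a")
        b = random_pair(rng, (8, 8), pid="b")
        out = carvemix(a, b)
        np.testing.assert_array_equal(out.image, b.image)
        np.testing.assert_array_equal(out.mask, b.mask)

    def test_overlap_union_with_carve_priority(self):
        m1 = np.zeros((3, 3), np.uint8)
        m1[0, :] = 1
        m2 = np.zeros((3, 3), np.uint8)
        m2[:, 0] = 1
        a = make_pair(np.full((3, 3), 5.0), m1, pid="a")
        b = make_pair(np.full((3, 3), 1.0), m2, pid="b")
        out = carvemix(a, b)
        np.testing.assert_array_equal(out.mask, np.logical_or(m1, m2))
        assert out.image[0, 0] == 5.0  # overlapping pixel comes from the carve
        assert out.image[1, 0] == 1.0

    def test_provenance_partitions_image_exactly(self, rng):
        for _ in range(50):
            a, b = random_pair(rng, pid="a"), random_pair(rng, pid="b")
            out = carvemix(a, b)
            assert set(np.unique(out.provenance)) <= {FROM_A, FROM_B}
            np.testing.assert_array_equal(out.provenance == FROM_A, a.mask == 1)
            np.testing.assert_array_equal(
                out.image[out.provenance == FROM_A], a.image[a.mask == 1]
            )
            np.testing.assert_array_equal(
                out.image[out.provenance == FROM_B], b.image[a.mask == 0]
            )

    def test_lesion_pixels_never_blended(self, rng):
        a, b = random_pair(rng, pid="a"), random_pair(rng, pid="b")
        out = carvemix(a, b)
        carved = a.mask.astype(bool)
        np.testing.assert_array_equal(out.image[carved], a.image[carved])

    def test_mismatches_raise(self, rng):
        a = random_pair(rng, (8, 8))
        with pytest.raises(AugmentationError):
            carvemix(a, random_pair(rng, (6, 6)))
        b = random_pair(rng, (8, 8))
        b = b.with_(modality="CT")
        with pytest.raises(AugmentationError):
            carvemix(a, b)


class TestMixup:
    def test_lambda_one_returns_first_sample(self, rng):
        x1, x2 = rng.normal(size=(4, 4)), rng.normal(size=(4, 4))
        out = mixup(x1, [1, 0], x2, [0, 1], 1.0)
        np.testing.assert_allclose(out.image, x1, atol=1e-7)
        np.testing.assert_array_equal(out.soft_label, [1.0, 0.0])

    def test_half_mix_arithmetic(self):
        out = mixup(np.full((2, 2), 2.0), [1, 0], np.full((2, 2), 4.0), [0, 1], 0.5)
        np.testing.assert_allclose(out.image, 3.0)
        np.testing.assert_allclose(out.soft_label, [0.5, 0.5])
        assert out.soft_label.sum() == pytest.approx(1.0)

    def test_beta_lambda_mean_is_half(self):
        rng = np.random.default_rng(0)
        lams = [sample_mixup_lambda(0.2, rng) for _ in range(10_000)]
        assert abs(np.mean(lams) - 0.5) < 0.02

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(lam=st.floats(0.05, 1.0), seed=st.integers(0, 10_000))
    def test_first_image_reconstructable(self, lam, seed):
        r = np.random.default_rng(seed)
        x1, x2 = r.normal(size=(5, 5)), r.normal(size=(5, 5))
        out = mixup(x1, [1, 0], x2, [0, 1], lam)
        rec = (out.image - (1 - lam) * x2) / lam
        np.testing.assert_allclose(rec, x1, atol=1e-5)

    def test_invalid_inputs_raise(self, rng):
        with pytest.raises(AugmentationError):
            mixup(np.ones((2, 2)), [1, 0], np.ones((3, 3)), [0, 1], 0.5)
        with pytest.raises(AugmentationError):
            mixup(np.ones((2, 2)), [1, 0], np.ones((2, 2)), [0, 1], 1.5)
        with pytest.raises(AugmentationError):
            sample_mixup_lambda(0.0, rng)


class TestBasicAugment:
    def test_double_flip_is_identity(self, rng):
        p = random_pair(rng)
        for flip in (hflip, vflip):
            q = flip(flip(p))
            np.testing.assert_array_equal(q.image, p.image)
            np.testing.assert_array_equal(q.mask, p.mask)

    def test_zero_rotation_is_identity(self, rng):
        p = random_pair(rng)
        q = rotate(p, 0.0)
        np.testing.assert_array_equal(q.image, p.image)

    def test_flips_preserve_foreground_count_rotation_approximately(self):
        rng = np.random.default_rng(0)
        from kitefusion.phantoms import PhantomSpec, generate_lesion_mask

        spec = PhantomSpec(image_size=64, lesion_radius=(5, 12))
        for i in range(100):
            mask = generate_lesion_mask(spec, "benign", rng)
            p = make_pair(rng.normal(size=(64, 64)), mask)
            n0 = p.mask.sum()
            assert hflip(p).mask.sum() == n0
            assert vflip(p).mask.sum() == n0
            assert rotate(p, 90.0 * (1 + i % 3)).mask.sum() == n0
            n_rot = rotate(p, float(rng.uniform(-15, 15))).mask.sum()
            assert abs(int(n_rot) - int(n0)) <= max(8, 0.15 * n0)

    def test_random_augment_keeps_mask_binary_and_shapes(self, rng):
        p = random_pair(rng, (32, 32))
        q = basic_augment(p, rng)
        assert q.image.shape == p.image.shape
        assert set(np.unique(q.mask)) <= {0, 1}


class TestExpandDataset:
    def _slices(self, rng, n):
        return [random_pair(rng, (8, 8), pid=f"p{i}") for i in range(n)]

    def test_m_plus_km_count(self, rng):
        out = expand_dataset(self._slices(rng, 100), 2.0, "carvemix", seed=0)
        assert len(out) == 300
        assert out.n_synthetic == 200

    def test_k_zero_leaves_set_unchanged(self, rng):
        base = self._slices(rng, 7)
        out = expand_dataset(base, 0.0, "carvemix", seed=0)
        assert out.samples == base and out.n_synthetic == 0

    def test_sources_within_train_set_and_no_self_pairs(self, rng):
        m = 13
        out = expand_dataset(self._slices(rng, m), 1.5, "carvemix", seed=3)
        for src in out.sources[m:]:
            i, j = src
            assert 0 <= i < m and 0 <= j < m and i != j

    def test_deterministic_by_seed(self, rng):
        base = self._slices(rng, 10)
        a = expand_dataset(base, 1.0, "carvemix", seed=9)
        b = expand_dataset(base, 1.0, "carvemix", seed=9)
        assert a.sources == b.sources
        for sa, sb in zip(a.samples[10:], b.samples[10:]):
            np.testing.assert_array_equal(sa.image, sb.image)

    def test_mixup_expansion_produces_soft_labels(self, rng):
        base = [
            (rng.normal(size=(8, 8)), np.array([1.0, 0.0]) if i % 2 else np.array([0.0, 1.0]))
            for i in range(10)
        ]
        out = expand_dataset(base, 1.0, "mixup", seed=0)
        synth = [s for s in out.samples if isinstance(s, MixupSample)]
        assert len(synth) == 10
        for s in synth:
            assert s.soft_label.sum() == pytest.approx(1.0)
            assert 0.0 <= s.lam <= 1.0

    def test_invalid_arguments_raise(self, rng):
        base = self._slices(rng, 3)
        with pytest.raises(AugmentationError):
            expand_dataset(base, -1.0, "carvemix")
        with pytest.raises(AugmentationError):
            expand_dataset(base, 1.0, "smote")
        with pytest.raises(AugmentationError):
            expand_dataset([], 1.0, "carvemix")
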