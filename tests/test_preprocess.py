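import numpy as np
import pytest

from watunet.preprocess import (
    AugmentParams,
    ClaheParams,
    augment_pair,
    balance_classes,
    clahe_enhance,
    resize_normalize,
)
from watunet.phantom import PhantomConfig, generate_sample

IDENTITY = AugmentParams(
    rotation_range=0.0,
    zoom_range=(1.0, 1.0),
    horizontal_flip=False,
    width_shift=0.0,
    height_shift=0.0,
    shear=0.0,
    brightness_range=(1.0, 1.0),
)


class TestClahe:
    def test_constant_image_stays_constant(self):
        img = np.full((64, 64), 120, dtype=np.uint8)
        out = clahe_enhance(img)
        assert out.shape == img.shape
        assert np.ptp(out) <= 1  # flat up to integer rounding

    def test_deterministic(self, benign_sample):
        a = clahe_enhance(benign_sample.image)
        b = clahe_enhance(benign_sample.image)
        assert np.array_equal(a, b)

    def test_contrast_increases_on_low_contrast_ramp(self):
        ramp = np.tile(np.linspace(100, 140, 64).astype(np.uint8), (64, 1))
        out = clahe_enhance(ramp, ClaheParams(clip_limit=2.0, tile_grid=(8, 8)))
        assert out.std() >= ramp.std()

    def test_rejects_non_grayscale(self):
        with pytest.raises(ValueError):
            clahe_enhance(np.zeros((8, 8, 3)))

    def test_param_validation(self):
        with pytest.raises(ValueError):
            ClaheParams(clip_limit=0.0)
        with pytest.raises(ValueError):
            ClaheParams(tile_grid=(0, 8))


class TestResizeNormalize:
    def test_mask_stays_binary(self, malignant_sample):
        _, mask = resize_normalize(malignant_sample.image, malignant_sample.mask, (48, 48))
        assert set(np.unique(mask)) <= {0, 1}

    def test_identity_resize_only_rescales(self):
        img = np.arange(64 * 64, dtype=float).reshape(64, 64) % 256
        mask = (img > 128).astype(np.uint8)
        out, m2 = resize_normalize(img, mask, (64, 64))
        assert np.allclose(out, img / 255.0, atol=1e-6)
        assert np.array_equal(m2, mask)

    def test_full_white_maps_to_one(self):
        img = np.full((32, 32), 255, dtype=np.uint8)
        out, _ = resize_normalize(img, np.zeros((32, 32), np.uint8), (16, 16))
        assert np.allclose(out, 1.0)

    def test_rejects_bad_target(self):
        with pytest.raises(ValueError):
            resize_normalize(np.zeros((8, 8)), np.zeros((8, 8)), (0, 8))


class TestAugment:
    def test_identity_params_leave_pair_unchanged(self, benign_sample):
        img, mask = augment_pair(
            benign_sample.image, benign_sample.mask, IDENTITY, np.random.default_rng(0)
        )
        assert np.array_equal(img, benign_sample.image)
        assert np.array_equal(mask, benign_sample.mask)

    def test_horizontal_flip_is_involution(self, benign_sample):
        # a flip about the pixel-grid centre maps the grid onto itself, so
        # applying it twice must restore the pair exactly
        from skimage import transform

        from watunet.preprocess import _warp_pair

        h, w = benign_sample.image.shape
        center = np.array([(w - 1) / 2.0, (h - 1) / 2.0])
        flip = (
            transform.AffineTransform(translation=-center)
            + transform.AffineTransform(scale=(-1.0, 1.0))
            + transform.AffineTransform(translation=center)
        )
        img1, m1 = _warp_pair(benign_sample.image, benign_sample.mask, flip)
        assert not np.array_equal(m1, benign_sample.mask)
        img2, m2 = _warp_pair(img1, m1, flip)
        assert np.array_equal(m2, benign_sample.mask)
        assert np.allclose(img2, benign_sample.image, atol=1e-6)

    def test_mask_stays_binary_under_any_draw(self, malignant_sample, rng):
        params = AugmentParams()
        for _ in range(5):
            _, mask = augment_pair(malignant_sample.image, malignant_sample.mask, params, rng)
            assert set(np.unique(mask)) <= {0, 1}

    def test_same_geometric_transform_applied_to_both(self, malignant_sample, rng):
        from watunet.preprocess import _warp_pair

        params = AugmentParams(brightness_range=(1.0, 1.0))
        img, mask, tf = augment_pair(
            malignant_sample.image, malignant_sample.mask, params, rng, return_transform=True
        )
        _, mask_ref = _warp_pair(malignant_sample.image, malignant_sample.mask, tf)
        assert np.array_equal(mask, mask_ref)

    def test_seeded_reproducibility(self, benign_sample):
        params = AugmentParams()
        a = augment_pair(benign_sample.image, benign_sample.mask, params, np.random.default_rng(5))
        b = augment_pair(benign_sample.image, benign_sample.mask, params, np.random.default_rng(5))
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])

    def test_brightness_never_touches_mask(self, benign_sample):
        params = AugmentParams(
            rotation_range=0.0,
            zoom_range=(1.0, 1.0),
            horizontal_flip=False,
            width_shift=0.0,
            height_shift=0.0,
            shear=0.0,
            brightness_range=(0.5, 0.5),
        )
        img, mask = augment_pair(benign_sample.image, benign_sample.mask, params, np.random.default_rng(1))
        assert np.array_equal(mask, benign_sample.mask)
        assert img.mean() < benign_sample.image.mean()


def test_balance_classes_reaches_exact_target(rng):
    cfg = PhantomConfig(n_samples=1, image_size=(32, 32))
    samples = (
        [generate_sample(cfg, "benign", np.random.default_rng(i)) for i in range(2)]
        + [generate_sample(cfg, "malignant", np.random.default_rng(i + 10)) for i in range(3)]
        + [generate_sample(cfg, "no_mass", np.random.default_rng(i + 20)) for i in range(5)]
    )
    out = balance_classes(samples, target_count=5, params=AugmentParams(), rng=rng)
    labels = [lab for _, _, lab in out]
    assert all(labels.count(lab) == 5 for lab in ("benign", "malignant", "no_mass"))
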