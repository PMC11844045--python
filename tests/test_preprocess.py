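"""Preprocessing chain and exact augmentation bookkeeping."""

import numpy as np
import pytest
from skimage import exposure

from vesselseg.data import ImageSample
from vesselseg.preprocess import (PreprocessConfig, augment_flips,
                                  augment_translations, clahe,
                                  extract_green_normalize, gamma_correct,
                                  preprocess_sample, split_dataset)


def _sample(image, sid="img"):
    H, W = image.shape[:2]
    return ImageSample(image=image, mask=np.zeros((H, W), bool),
                       fov=np.ones((H, W), bool), id=sid)


def _make_set(n, size=64, seed=0):
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        img = rng.random((size, size)).astype(np.float32)
        mask = rng.random((size, size)) > 0.8
        fov = np.ones((size, size), bool)
        out.append(ImageSample(image=img, mask=mask, fov=fov, id=f"src{i:03d}"))
    return out


# -- green channel ------------------------------------------------------------


def test_green_extraction_picks_the_g_channel():
    rgb = np.zeros((4, 4, 3), np.uint8)
    rgb[..., 1] = 255
    out = extract_green_normalize(_sample(rgb))
    np.testing.assert_allclose(out.image, 1.0)

    px = np.zeros((1, 1, 3), np.uint8)
    px[0, 0] = (10, 200, 30)
    assert extract_green_normalize(_sample(px)).image[0, 0] == pytest.approx(
        200 / 255, abs=1e-6)


def test_green_extraction_grayscale_passthrough(rng):
    gray = (rng.random((4, 4)) * 255).astype(np.uint8)
    out = extract_green_normalize(_sample(gray.astype(np.float32)))
    np.testing.assert_allclose(out.image, gray / 255.0, atol=1e-6)


def test_green_extraction_rejects_bad_channel_counts(rng):
    with pytest.raises(ValueError, match="channel"):
        extract_green_normalize(_sample(np.zeros((4, 4, 2), np.uint8)))
    with pytest.raises(ValueError, match="channel"):
        extract_green_normalize(_sample(np.zeros((4, 4, 5), np.uint8)))


# -- CLAHE and gamma ----------------------------------------------------------


def test_clahe_constant_image_unchanged():
    img = np.full((32, 32), 0.4, np.float32)
    np.testing.assert_allclose(clahe(img, PreprocessConfig()), img)


def test_clahe_output_in_unit_range_and_same_size(rng):
    img = rng.random((48, 40)).astype(np.float32)
    out = clahe(img, PreprocessConfig())
    assert out.shape == img.shape
    assert out.min() >= 0.0 and out.max() <= 1.0


def test_clahe_does_not_reduce_checkerboard_contrast():
    """Cross-check against plain histogram equalization on the same input."""
    yy, xx = np.mgrid[0:64, 0:64]
    board = (0.45 + 0.1 * (((yy // 8) + (xx // 8)) % 2)).astype(np.float32)
    board += np.random.default_rng(0).normal(0, 0.01, board.shape).astype(np.float32)
    board = np.clip(board, 0, 1)
    out = clahe(board, PreprocessConfig())
    assert np.ptp(out) >= np.ptp(board) - 1e-6
    ref = exposure.equalize_hist(board)
    assert np.ptp(ref) >= np.ptp(board) - 1e-6  # equalization stretches contrast


def test_clahe_rejects_non_2d(rng):
    with pytest.raises(ValueError, match="2-D"):
        clahe(rng.random((4, 4, 3)).astype(np.float32), PreprocessConfig())


def test_gamma_identity_fixed_points_and_value():
    img = np.array([[0.0, 0.25], [0.5, 1.0]], np.float32)
    np.testing.assert_allclose(gamma_correct(img, 1.0), img)
    out = gamma_correct(img, 2.0)
    assert out[0, 0] == 0.0 and out[1, 1] == 1.0
    assert out[0, 1] == pytest.approx(0.0625, abs=1e-6)
    with pytest.raises(ValueError, match="gamma"):
        gamma_correct(img, 0.0)


def test_preprocess_chain_preserves_size_and_range(rng):
    rgb = (rng.random((40, 48, 3)) * 255).astype(np.uint8)
    s = ImageSample(image=rgb, mask=np.zeros((40, 48), bool),
                    fov=np.ones((40, 48), bool), id="x")
    out = preprocess_sample(s)
    assert out.image.shape == (40, 48)
    assert out.image.min() >= 0.0 and out.image.max() <= 1.0
    assert out.mask.shape == (40, 48)  # mask untouched


# -- flips --------------------------------------------------------------------


@pytest.mark.parametrize("n_in,n_out", [(40, 160), (28, 112)])
def test_flip_multiplicity_matches_dataset_bookkeeping(n_in, n_out):
    out = augment_flips(_make_set(n_in, size=16))
    assert len(out) == n_out
    assert len({s.id for s in out}) == n_out


def test_hflip_is_an_involution():
    s = _make_set(1)[0]
    once = augment_flips([s])[1]        # __hflip
    twice = augment_flips([once])[1]    # __hflip__hflip
    np.testing.assert_array_equal(twice.image, s.image)
    np.testing.assert_array_equal(twice.mask, s.mask)


def test_flips_transform_image_mask_and_fov_identically():
    """Coordinate-encoded image: the same permutation must hit all three."""
    size = 8
    coords = np.arange(size * size, dtype=np.float32).reshape(size, size) / 64
    s = ImageSample(image=coords, mask=coords > 0.5, fov=coords > 0.25, id="c")
    for variant in augment_flips([s]):
        np.testing.assert_array_equal(variant.mask, variant.image > 0.5)
        np.testing.assert_array_equal(variant.fov, variant.image > 0.25)


# -- translations -------------------------------------------------------------


@pytest.mark.parametrize("n_in,n_out", [(160, 800), (112, 560)])
def test_translation_multiplicity_matches_dataset_bookkeeping(n_in, n_out):
    out = augment_translations(_make_set(n_in, size=64), t=50)
    assert len(out) == n_out


def test_translation_round_trip_on_central_region():
    s = _make_set(1, size=64)[0]
    t = 20
    right = augment_translations([s], t=t)[1]   # shift +t in x
    back = augment_translations([right], t=t)[2]  # shift -t in x
    np.testing.assert_array_equal(back.image[:, : 64 - 2 * t],
                                  s.image[:, : 64 - 2 * t])


def test_translation_zero_fills_and_moves_mask_with_image():
    s = _make_set(1, size=64)[0]
    down = augment_translations([s], t=10)[3]   # +t rows
    assert np.all(down.image[:10] == 0)
    assert not down.mask[:10].any()
    np.testing.assert_array_equal(down.mask[10:], s.mask[:-10])


def test_translation_exceeding_image_raises():
    with pytest.raises(ValueError, match="translation exceeds image"):
        augment_translations(_make_set(1, size=32), t=50)


# -- split --------------------------------------------------------------------


def test_split_group_counts_and_leakage_control():
    base = _make_set(40, size=64)
    augmented = augment_translations(augment_flips(base), t=20)
    assert len(augmented) == 800
    train, test = split_dataset(augmented, seed=0)
    assert len(train) == 640 and len(test) == 160
    assert {s.id for s in train}.isdisjoint({s.id for s in test})
    # every source contributes all 20 variants to exactly one side
    train_sources = {s.source for s in train}
    test_sources = {s.source for s in test}
    assert train_sources.isdisjoint(test_sources)
    assert len(train_sources) == 32 and len(test_sources) == 8


def test_split_reproducible_and_partitioning():
    samples = _make_set(10, size=16)
    a_train, a_test = split_dataset(samples, seed=7)
    b_train, b_test = split_dataset(samples, seed=7)
    assert [s.id for s in a_train] == [s.id for s in b_train]
    assert len(a_train) + len(a_test) == len(samples)
    assert {s.id for s in a_train} | {s.id for s in a_test} == \
        {s.id for s in samples}


def test_split_rejects_tiny_sets():
    with pytest.raises(ValueError, match="at least 5"):
        split_dataset(_make_set(3, size=16))
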