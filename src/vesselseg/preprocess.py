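"""Fundus preprocessing and deterministic augmentation bookkeeping.

Preprocessing follows the standard fundus chain, in this fixed order:
green-channel extraction (vessels have their best contrast against the
background in the G channel), normalization to [0, 1], contrast-limited
adaptive histogram equalization (CLAHE), and gamma correction.

Augmentation is exact bookkeeping rather than random sampling: each
sample expands 4-fold under flips (original, horizontal, vertical,
both) and 5-fold under translations (original plus a fixed-magnitude
shift in each of the four cardinal directions), so 40 source images
become 160 after flips and 800 after translations, and 28 become 112
and then 560.  The train/test split is 4:1 and groups every augmented
variant of a source image on the same side, so no augmented copy of a
test image leaks into training.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from skimage import exposure

from .data import ImageSample

__all__ = [
    "PreprocessConfig", "extract_green_normalize", "clahe", "gamma_correct",
    "preprocess_sample", "augment_flips", "augment_translations",
    "split_dataset",
]


@dataclass
class PreprocessConfig:
    """Knobs of the preprocessing chain.

    ``clahe_clip`` is expressed in multiples of the uniform histogram
    bin height (the convention of most CLAHE implementations); 2.0 is a
    mild, standard setting.  ``gamma`` > 1 darkens midtones, which
    suppresses the bright artifacts left after equalization.
    """

    clahe_clip: float = 2.0
    clahe_tiles: tuple[int, int] = (8, 8)
    gamma: float = 1.2
    normalize: bool = True

    def __post_init__(self):
        if self.clahe_clip <= 0:
            raise ValueError("clahe_clip must be > 0")
        if self.gamma <= 0:
            raise ValueError("gamma must be > 0")


def extract_green_normalize(s: ImageSample) -> ImageSample:
    """Reduce to the green channel and scale intensities to [0, 1]."""
    img = np.asarray(s.image)
    if img.ndim == 3:
        if img.shape[2] in (3, 4):
            img = img[:, :, 1]
        else:
            raise ValueError(f"unsupported channel count: {img.shape[2]}")
    elif img.ndim != 2:
        raise ValueError("image must be 2-D or have a channel axis")
    img = img.astype(np.float32)
    if img.max() > 1.0:  # 8-bit input
        img = img / 255.0
    return replace(s, image=img)


def clahe(img: np.ndarray, cfg: PreprocessConfig) -> np.ndarray:
    """Contrast-limited adaptive histogram equalization on a [0,1] image."""
    img = np.asarray(img)
    if img.ndim != 2:
        raise ValueError("clahe expects a single-channel 2-D image")
    if img.max() == img.min():  # degenerate histogram: nothing to equalize
        return img.astype(np.float32)
    ty, tx = cfg.clahe_tiles
    kernel = (max(img.shape[0] // ty, 1), max(img.shape[1] // tx, 1))
    out = exposure.equalize_adapthist(
        np.clip(img, 0.0, 1.0), kernel_size=kernel,
        clip_limit=cfg.clahe_clip / 256.0)
    return out.astype(np.float32)


def gamma_correct(img: np.ndarray, gamma: float) -> np.ndarray:
    """Pointwise power-law transform img**gamma on a [0,1] image."""
    if gamma <= 0:
        raise ValueError("gamma must be > 0")
    return np.power(np.asarray(img, dtype=np.float32), gamma)


def preprocess_sample(s: ImageSample,
                      cfg: PreprocessConfig | None = None) -> ImageSample:
    """Full chain: green -> normalize -> CLAHE -> gamma."""
    cfg = cfg or PreprocessConfig()
    s = extract_green_normalize(s)
    img = clahe(s.image, cfg)
    img = gamma_correct(img, cfg.gamma)
    return replace(s, image=img)


# -- augmentation -------------------------------------------------------------

_FLIPS = (
    ("orig", lambda a: a),
    ("hflip", lambda a: a[:, ::-1].copy()),
    ("vflip", lambda a: a[::-1, :].copy()),
    ("hvflip", lambda a: a[::-1, ::-1].copy()),
)


def _apply(s: ImageSample, tag: str, fn) -> ImageSample:
    return ImageSample(
        image=fn(s.image),
        mask=fn(s.mask),
        fov=None if s.fov is None else fn(s.fov),
        id=f"{s.id}__{tag}",
    )


def augment_flips(samples: list[ImageSample]) -> list[ImageSample]:
    """x4 expansion: original, horizontal, vertical, and combined flips."""
    if not samples:
        raise ValueError("empty input set")
    return [_apply(s, tag, fn) for s in samples for tag, fn in _FLIPS]


def _shift(a: np.ndarray, dy: int, dx: int) -> np.ndarray:
    """Translate with zero fill (False fill for boolean masks)."""
    out = np.zeros_like(a)
    H, W = a.shape[:2]
    ys = slice(max(dy, 0), H + min(dy, 0))
    xs = slice(max(dx, 0), W + min(dx, 0))
    ys_src = slice(max(-dy, 0), H + min(-dy, 0))
    xs_src = slice(max(-dx, 0), W + min(-dx, 0))
    out[ys, xs] = a[ys_src, xs_src]
    return out


def augment_translations(samples: list[ImageSample],
                         t: int = 50) -> list[ImageSample]:
    """x5 expansion: original plus +-t pixel shifts along each axis."""
    if not samples:
        raise ValueError("empty input set")
    for s in samples:
        if min(s.mask.shape) <= t:
            raise ValueError("translation exceeds image")
    shifts = [("t0", 0, 0), (f"tx+{t}", 0, t), (f"tx-{t}", 0, -t),
              (f"ty+{t}", t, 0), (f"ty-{t}", -t, 0)]
    return [
        _apply(s, tag, lambda a, dy=dy, dx=dx: _shift(a, dy, dx))
        for s in samples for tag, dy, dx in shifts
    ]


def split_dataset(samples: list[ImageSample], ratio: float = 0.8,
                  seed: int = 0) -> tuple[list[ImageSample], list[ImageSample]]:
    """Source-grouped 4:1 split, reproducible from ``seed``.

    All augmented variants of one source image land on the same side.
    Whole source groups are assigned to the training side until it
    holds round(ratio * |set|) samples.
    """
    if len(samples) < 5:
        raise ValueError("need at least 5 samples to split")
    rng = np.random.default_rng(seed)
    groups: dict[str, list[ImageSample]] = {}
    for s in samples:
        groups.setdefault(s.source, []).append(s)
    order = sorted(groups)
    rng.shuffle(order)
    target = round(ratio * len(samples))
    train: list[ImageSample] = []
    test: list[ImageSample] = []
    for src in order:
        bucket = train if len(train) < target else test
        bucket.extend(groups[src])
    return train, test
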