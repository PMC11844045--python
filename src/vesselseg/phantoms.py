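"""Seeded synthetic fundus phantoms with pixel-perfect ground truth.

A phantom emulates the structure of a fundus photograph: a circular
field of view (FOV) containing a smooth radial background (brighter at
the centre), Gaussian sensor noise, and a set of darker curvilinear
vessel trees.  Trees are grown as random walks: each root starts on
the FOV rim heading inward and advances in 1-pixel steps, its heading
perturbed by Gaussian jitter, stamping a disk of the current vessel
width at every step.  With a small per-step probability a child branch
spawns at the current position with its width scaled down by
``width_decay``; branches below 1 px are pruned, and each tree has a
finite step budget so the vessel density stays in a realistic range.
Walks stop when they leave the FOV.

Everything is drawn from one ``numpy.random.Generator`` seeded by
``PhantomSpec.seed``, so a spec fully determines a phantom bit for bit
— phantoms are portable test vectors.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from .data import ImageSample, save_dataset

__all__ = ["PhantomSpec", "generate_phantom", "generate_dataset"]


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and noise parameters that fully determine one phantom."""

    seed: int = 0
    size: int = 128              # square image side, px
    n_roots: int = 4             # vessel trees entering the FOV
    root_width: float = 3.0      # stamped width of a root vessel, px
    width_decay: float = 0.7     # child width = parent width * decay
    branch_prob: float = 0.05    # per-step probability of spawning a child
    curvature_sigma: float = 0.15  # heading jitter, radians per step
    vessel_contrast: float = 0.35  # intensity drop under the vessel mask
    noise_sigma: float = 0.03    # background Gaussian noise std
    fov_radius_frac: float = 0.48  # FOV radius as fraction of size

    def __post_init__(self):
        if self.size < 64:
            raise ValueError("size must be >= 64")
        if not 0 < self.fov_radius_frac <= 0.5:
            raise ValueError("fov_radius_frac must be in (0, 0.5]")
        if self.root_width < 1:
            raise ValueError("root_width must be >= 1 px")
        if self.n_roots < 1:
            raise ValueError("need at least one vessel root")


def _fov_disk(size: int, radius: float) -> np.ndarray:
    c = (size - 1) / 2.0
    yy, xx = np.mgrid[0:size, 0:size]
    return (yy - c) ** 2 + (xx - c) ** 2 <= radius ** 2


def _stamp(mask: np.ndarray, y: float, x: float, width: float) -> None:
    """Set pixels within width/2 of (y, x)."""
    r = width / 2.0
    size = mask.shape[0]
    y0, y1 = max(int(y - r), 0), min(int(y + r) + 1, size)
    x0, x1 = max(int(x - r), 0), min(int(x + r) + 1, size)
    if y0 >= y1 or x0 >= x1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    mask[y0:y1, x0:x1] |= (yy - y) ** 2 + (xx - x) ** 2 <= r ** 2


def _grow_tree(rng: np.random.Generator, spec: PhantomSpec,
               fov: np.ndarray, root_angle: float) -> np.ndarray:
    """Grow one vessel tree; returns its stamped mask (before FOV clip)."""
    size = spec.size
    c = (size - 1) / 2.0
    radius = spec.fov_radius_frac * size
    tree = np.zeros((size, size), dtype=bool)
    start_y = c + 0.95 * radius * np.sin(root_angle)
    start_x = c + 0.95 * radius * np.cos(root_angle)
    inward = root_angle + np.pi  # head toward the centre
    queue = [(start_y, start_x,
              inward + rng.normal(0.0, 0.3), spec.root_width)]
    budget = 2 * size  # total steps per tree
    while queue and budget > 0:
        y, x, heading, width = queue.pop(0)
        while budget > 0:
            iy, ix = int(round(y)), int(round(x))
            if not (0 <= iy < size and 0 <= ix < size) or not fov[iy, ix]:
                break
            _stamp(tree, y, x, width)
            budget -= 1
            heading += rng.normal(0.0, spec.curvature_sigma)
            y += np.sin(heading)
            x += np.cos(heading)
            if rng.random() < spec.branch_prob:
                child_width = width * spec.width_decay
                if child_width >= 1.0:
                    side = 1.0 if rng.random() < 0.5 else -1.0
                    queue.append((y, x,
                                  heading + side * rng.uniform(0.5, 1.0),
                                  child_width))
    return tree


def generate_phantom(spec: PhantomSpec) -> ImageSample:
    """One phantom: image, vessel mask and FOV, all determined by the seed."""
    rng = np.random.default_rng(spec.seed)
    size = spec.size
    radius = spec.fov_radius_frac * size
    fov = _fov_disk(size, radius)

    c = (size - 1) / 2.0
    yy, xx = np.mgrid[0:size, 0:size]
    r2 = ((yy - c) ** 2 + (xx - c) ** 2) / radius ** 2
    background = 0.45 + 0.30 * np.clip(1.0 - r2, 0.0, 1.0)

    mask = np.zeros((size, size), dtype=bool)
    angles = rng.uniform(0.0, 2.0 * np.pi, size=spec.n_roots)
    for angle in angles:
        mask |= _grow_tree(rng, spec, fov, angle)
    mask &= fov

    image = background + rng.normal(0.0, spec.noise_sigma, size=(size, size))
    image = np.where(mask, image - spec.vessel_contrast, image)
    image = np.where(fov, image, 0.0)
    image = np.clip(image, 0.0, 1.0).astype(np.float32)
    return ImageSample(image=image, mask=mask, fov=fov,
                       id=f"phantom_{spec.seed:04d}")


def generate_dataset(n: int, base_seed: int = 0,
                     out_dir: Path | None = None,
                     spec: PhantomSpec | None = None) -> list[ImageSample]:
    """n phantoms with seeds base_seed .. base_seed + n - 1.

    If ``out_dir`` is given the samples are written in the standard
    dataset layout (images/, masks/, fov/, manifest.csv).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    base = spec or PhantomSpec()
    samples = [generate_phantom(replace(base, seed=base_seed + i))
               for i in range(n)]
    if out_dir is not None:
        save_dataset(samples, Path(out_dir))
    return samples
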