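"""Dataset records and on-disk layout.

An :class:`ImageSample` bundles a fundus image (grayscale or RGB, float
in [0, 1] in memory), its binary vessel mask, an optional binary
field-of-view (FOV) mask and a string identifier.  Augmented variants
carry the source identifier as the prefix before the first ``"__"`` in
their id, which is what keeps all variants of one source image on the
same side of a train/test split.

Directory layout mirrors the public fundus benchmarks::

    <root>/images/<id>.png     8-bit grayscale or RGB
    <root>/masks/<id>.png      binary vessel ground truth (0/255)
    <root>/fov/<id>.png        binary field of view (0/255), optional
    <root>/manifest.csv        id, source, split
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from PIL import Image

__all__ = ["ImageSample", "save_dataset", "load_dataset",
           "write_image", "read_image"]


@dataclass
class ImageSample:
    image: np.ndarray           # float32 in [0,1]; (H,W) or (H,W,3)
    mask: np.ndarray            # bool (H,W)
    fov: np.ndarray | None      # bool (H,W) or None
    id: str

    def __post_init__(self):
        shapes = {self.image.shape[:2], self.mask.shape}
        if self.fov is not None:
            shapes.add(self.fov.shape)
        if len(shapes) != 1:
            raise ValueError("image, mask and fov must share spatial size")

    @property
    def source(self) -> str:
        """Identifier of the un-augmented source image."""
        return self.id.split("__")[0]

    def with_id_suffix(self, tag: str) -> "ImageSample":
        return replace(self, id=f"{self.id}__{tag}")


def write_image(path: Path, array: np.ndarray) -> None:
    """Write a float [0,1] or boolean array as an 8-bit PNG."""
    if array.dtype == bool:
        data = array.astype(np.uint8) * 255
    else:
        data = np.clip(np.round(np.asarray(array, dtype=np.float64) * 255), 0,
                       255).astype(np.uint8)
    Image.fromarray(data).save(path)


def read_image(path: Path, binary: bool = False) -> np.ndarray:
    arr = np.asarray(Image.open(path))
    if binary:
        return arr > 127
    return arr.astype(np.float32) / 255.0


def save_dataset(samples: list[ImageSample], root: Path,
                 splits: dict[str, str] | None = None) -> None:
    """Write samples under ``root`` in the standard layout with a manifest."""
    root = Path(root)
    for sub in ("images", "masks", "fov"):
        (root / sub).mkdir(parents=True, exist_ok=True)
    with open(root / "manifest.csv", "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["id", "source", "split"])
        for s in samples:
            write_image(root / "images" / f"{s.id}.png", s.image)
            write_image(root / "masks" / f"{s.id}.png", s.mask)
            if s.fov is not None:
                write_image(root / "fov" / f"{s.id}.png", s.fov)
            writer.writerow([s.id, s.source,
                             (splits or {}).get(s.id, "")])


def load_dataset(root: Path, split: str | None = None) -> list[ImageSample]:
    """Read a dataset directory; optionally filter by manifest split."""
    root = Path(root)
    manifest = root / "manifest.csv"
    if not manifest.exists():
        raise FileNotFoundError(f"no manifest.csv under {root}")
    samples = []
    with open(manifest, newline="") as fh:
        for row in csv.DictReader(fh):
            if split is not None and row.get("split", "") != split:
                continue
            sid = row["id"]
            image = read_image(root / "images" / f"{sid}.png")
            mask = read_image(root / "masks" / f"{sid}.png", binary=True)
            fov_path = root / "fov" / f"{sid}.png"
            fov = read_image(fov_path, binary=True) if fov_path.exists() else None
            samples.append(ImageSample(image=image, mask=mask, fov=fov, id=sid))
    if not samples:
        raise ValueError(f"empty dataset under {root} (split={split!r})")
    return samples


def read_manifest_splits(root: Path) -> dict[str, str]:
    with open(Path(root) / "manifest.csv", newline="") as fh:
        return {row["id"]: row.get("split", "") for row in csv.DictReader(fh)}
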