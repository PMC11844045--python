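"""Training, prediction and evaluation orchestration.

Defaults follow standard practice for whole-image fundus segmentation:
Adam, initial learning rate 1e-3 (constant), weight decay 1e-4, batch
size 2, 100 epochs, binarization threshold 0.5.  Training minimizes
the deep-supervised Dice + cross-entropy objective; images are padded
with zeros to a multiple of 32 (minimum 64) and predictions are
cropped back.  A source-grouped validation carve-out (20% of the
training set) selects the checkpoint with the best validation Dice.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .data import ImageSample, load_dataset, read_image, write_image
from .losses import combined_loss, dice_loss
from .metrics import ConfusionCounts, compute_metrics, confusion_counts
from .network import (DoubleAttentionU2Net, NetworkConfig, build_network,
                      load_checkpoint, save_checkpoint)
from .nn import Parameter
from .preprocess import extract_green_normalize

logger = logging.getLogger("vesselseg")

__all__ = ["TrainConfig", "Adam", "fit", "train", "predict", "evaluate"]


@dataclass
class TrainConfig:
    batch_size: int = 2
    lr: float = 1e-3
    weight_decay: float = 1e-4
    epochs: int = 100
    seed: int = 0
    base_width: int = 16
    threshold: float = 0.5
    max_iterations: int | None = None   # hard cap across epochs, if set
    val_fraction: float = 0.2

    def __post_init__(self):
        if self.lr <= 0:
            raise ValueError("lr must be > 0")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if not 0 < self.threshold < 1:
            raise ValueError("threshold must be in (0, 1)")


class Adam:
    """Adam with decoupled-from-nothing classic L2 weight decay."""

    def __init__(self, params: list[Parameter], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 0.0):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1 ** self.t
        bc2 = 1.0 - self.b2 ** self.t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            self.m[i] = self.b1 * self.m[i] + (1.0 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1.0 - self.b2) * g * g
            p.data -= (self.lr * (self.m[i] / bc1)
                       / (np.sqrt(self.v[i] / bc2) + self.eps))


def _pad_to_multiple(a: np.ndarray, multiple: int = 32,
                     minimum: int = 64) -> tuple[np.ndarray, tuple[int, int]]:
    H, W = a.shape[:2]
    Ht = max(minimum, -(-H // multiple) * multiple)
    Wt = max(minimum, -(-W // multiple) * multiple)
    if (Ht, Wt) == (H, W):
        return a, (H, W)
    pad = [(0, Ht - H), (0, Wt - W)] + [(0, 0)] * (a.ndim - 2)
    return np.pad(a, pad), (H, W)


def _as_input(s: ImageSample) -> tuple[np.ndarray, np.ndarray, tuple[int, int]]:
    """Sample -> padded (1,H,W) image and (1,H,W) mask, plus original size."""
    s = extract_green_normalize(s)
    img, orig = _pad_to_multiple(s.image)
    mask, _ = _pad_to_multiple(s.mask.astype(np.float32))
    return img[None], mask[None], orig


@dataclass
class TrainHistory:
    epoch_loss: list[float] = field(default_factory=list)
    epoch_dice: list[float] = field(default_factory=list)
    val_dice: list[float] = field(default_factory=list)
    iterations: int = 0


def fit(samples: list[ImageSample], cfg: TrainConfig,
        net_cfg: NetworkConfig | None = None,
        val_samples: list[ImageSample] | None = None,
        checkpoint_path: Path | None = None
        ) -> tuple[DoubleAttentionU2Net, TrainHistory]:
    """Train a network on in-memory samples; the core of :func:`train`."""
    if not samples:
        raise ValueError("empty dataset")
    net_cfg = net_cfg or NetworkConfig(base_width=cfg.base_width)
    net = build_network(net_cfg, seed=cfg.seed)
    logger.info("built network: %d parameters", net.num_parameters())
    opt = Adam(list(net.parameters()), lr=cfg.lr,
               weight_decay=cfg.weight_decay)
    rng = np.random.default_rng(cfg.seed)

    prepared = [_as_input(s) for s in samples]
    history = TrainHistory()
    best_val = -1.0
    best_state = None
    done = False
    for epoch in range(cfg.epochs):
        order = rng.permutation(len(prepared))
        losses, dices = [], []
        net.train()
        for start in range(0, len(order), cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            x = Tensor(np.concatenate([prepared[i][0] for i in idx])[:, None],
                       requires_grad=False)
            y = np.concatenate([prepared[i][1] for i in idx])[:, None]
            out = net(x)
            loss, _ = combined_loss(out, y)
            net.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
            dices.append(1.0 - float(
                dice_loss((out.fused.data > cfg.threshold).astype(np.float32),
                          y).data))
            history.iterations += 1
            if (cfg.max_iterations is not None
                    and history.iterations >= cfg.max_iterations):
                done = True
                break
        history.epoch_loss.append(float(np.mean(losses)))
        history.epoch_dice.append(float(np.mean(dices)))
        if val_samples:
            vd = _dataset_dice(net, val_samples, cfg.threshold)
            history.val_dice.append(vd)
            if vd > best_val:
                best_val = vd
                best_state = net.state_dict()
        logger.info("epoch %d: loss=%.4f train_dice=%.4f%s", epoch + 1,
                    history.epoch_loss[-1], history.epoch_dice[-1],
                    f" val_dice={history.val_dice[-1]:.4f}" if val_samples else "")
        if done:
            break
    if best_state is not None:
        net.load_state_dict(best_state)
    net.eval()
    if checkpoint_path is not None:
        save_checkpoint(net, checkpoint_path)
    return net, history


def _dataset_dice(net: DoubleAttentionU2Net, samples: list[ImageSample],
                  threshold: float) -> float:
    """Pooled binary Dice of thresholded predictions over a sample list."""
    net.eval()
    inter = tot = 0.0
    with ad.no_grad():
        for s in samples:
            x, y, orig = _as_input(s)
            pred = (net(Tensor(x[:, None])).fused.data[0, 0] > threshold)
            truth = y[0] > 0.5
            inter += float(np.count_nonzero(pred & truth))
            tot += float(np.count_nonzero(pred) + np.count_nonzero(truth))
    return 2.0 * inter / tot if tot else 0.0


def _carve_validation(samples: list[ImageSample], fraction: float,
                      seed: int) -> tuple[list[ImageSample], list[ImageSample]]:
    """Source-grouped validation carve-out (may be empty for tiny sets)."""
    sources = sorted({s.source for s in samples})
    if len(sources) < 3 or fraction <= 0:
        return samples, []
    rng = np.random.default_rng(seed + 1)
    rng.shuffle(sources)
    n_val = max(1, int(round(fraction * len(sources))))
    val_src = set(sources[:n_val])
    train = [s for s in samples if s.source not in val_src]
    val = [s for s in samples if s.source in val_src]
    return train, val


def train(data_dir: Path, cfg: TrainConfig,
          net_cfg: NetworkConfig | None = None,
          checkpoint_path: Path | None = None
          ) -> tuple[DoubleAttentionU2Net, TrainHistory]:
    """Train from a dataset directory (manifest layout, real or phantom)."""
    try:
        samples = load_dataset(Path(data_dir), split="train")
    except ValueError:
        samples = load_dataset(Path(data_dir))
    tr, val = _carve_validation(samples, cfg.val_fraction, cfg.seed)
    t0 = time.time()
    net, history = fit(tr, cfg, net_cfg, val_samples=val,
                       checkpoint_path=checkpoint_path)
    logger.info("training finished in %.1f s (%d iterations)",
                time.time() - t0, history.iterations)
    return net, history


def predict(checkpoint, samples: list[ImageSample],
            threshold: float = 0.5,
            out_dir: Path | None = None
            ) -> list[tuple[str, np.ndarray, np.ndarray]]:
    """Fused probability map and thresholded binary mask per sample.

    ``checkpoint`` is a path or an in-memory network.  Outputs are
    cropped back to each sample's original size.  If ``out_dir`` is
    given, writes ``<id>_prob.png`` (16-bit) and ``<id>_mask.png``
    (binary 8-bit).
    """
    net = checkpoint if isinstance(checkpoint, DoubleAttentionU2Net) \
        else load_checkpoint(checkpoint)
    net.eval()
    results = []
    for s in samples:
        x, _, (H, W) = _as_input(s)
        with ad.no_grad():
            prob = net(Tensor(x[:, None])).fused.data[0, 0][:H, :W]
        binary = prob > threshold
        results.append((s.id, prob, binary))
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        from PIL import Image
        for sid, prob, binary in results:
            p16 = np.round(prob.astype(np.float64) * 65535).astype(np.uint16)
            Image.fromarray(p16).save(out_dir / f"{sid}_prob.png")
            write_image(out_dir / f"{sid}_mask.png", binary)
    return results


def evaluate(pred_dir: Path, truth_dir: Path, fov_dir: Path | None = None,
             per_image: bool = False,
             csv_path: Path | None = None) -> dict:
    """Pooled (default) or per-image metrics from prediction/truth PNGs.

    Predictions are ``<id>_mask.png`` under ``pred_dir``; ground truth
    masks are ``<id>.png`` under ``truth_dir``.
    """
    pred_dir, truth_dir = Path(pred_dir), Path(truth_dir)
    pred_ids = {p.name[:-len("_mask.png")]
                for p in pred_dir.glob("*_mask.png")}
    truth_ids = {p.stem for p in truth_dir.glob("*.png")}
    common = sorted(pred_ids & truth_ids)
    # truth directories may cover more images than were predicted;
    # a prediction without ground truth is an error
    orphans = sorted(pred_ids - truth_ids)
    if not common:
        raise ValueError(f"no matching ids; predictions: {sorted(pred_ids)}")
    if orphans:
        raise ValueError(f"id mismatch: predictions without ground truth: {orphans}")

    pooled = ConfusionCounts()
    rows = []
    for sid in common:
        pred = read_image(pred_dir / f"{sid}_mask.png", binary=True)
        truth = read_image(truth_dir / f"{sid}.png", binary=True)
        fov = None
        if fov_dir is not None:
            fov_path = Path(fov_dir) / f"{sid}.png"
            fov = read_image(fov_path, binary=True) if fov_path.exists() else None
        c = confusion_counts(pred, truth, fov)
        pooled = pooled + c
        if per_image:
            rows.append({"id": sid, **compute_metrics(c)})
    report = {"pooled": compute_metrics(pooled), "n_images": len(common)}
    if per_image:
        report["per_image"] = rows
    if csv_path is not None:
        import csv as _csv
        with open(csv_path, "w", newline="") as fh:
            writer = _csv.writer(fh)
            writer.writerow(["id", "Acc", "SP", "SE", "F1", "MIoU"])
            for row in rows or []:
                writer.writerow([row["id"]] + [f"{row[k]:.6f}"
                                               for k in ("Acc", "SP", "SE", "F1", "MIoU")])
            pm = report["pooled"]
            writer.writerow(["POOLED"] + [f"{pm[k]:.6f}"
                                          for k in ("Acc", "SP", "SE", "F1", "MIoU")])
    return report


def format_metrics_table(report: dict) -> str:
    """Pretty-print an :func:`evaluate` report."""
    pm = report["pooled"]
    header = f"{'':10s}" + "".join(f"{k:>10s}" for k in ("Acc", "SP", "SE", "F1", "MIoU"))
    lines = [header]
    for row in report.get("per_image", []):
        lines.append(f"{row['id'][:10]:10s}" + "".join(
            f"{row[k]:10.4f}" for k in ("Acc", "SP", "SE", "F1", "MIoU")))
    lines.append(f"{'POOLED':10s}" + "".join(
        f"{pm[k]:10.4f}" for k in ("Acc", "SP", "SE", "F1", "MIoU")))
    return "\n".join(lines)
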