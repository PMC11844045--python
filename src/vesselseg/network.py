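"""The double-attention nested-U segmentation network.

Six encoder stages and five decoder stages, each a residual U-block:
the stage plan is fixed at depths [7, 6, 5, 4, 4F, 4F] for En1..En6 and
[7, 6, 5, 4, 4F] for De1..De5, where "4F" is the dilated variant used
once the resolution has dropped too far for further pooling.  Stages
are connected by 2x2 max pooling on the way down and bilinear
upsampling plus concatenation on the way up.  Each decoder stage (and
the deepest encoder) emits a one-channel side logit which is upsampled
to the input size; the six side logits are fused by a 1x1 convolution
into the final logit, and a sigmoid maps all seven to probability maps
— the deep-supervision scheme the loss is applied to.

Channel widths follow a geometric plan ``base_width * (1, 2, 4, 8, 8,
8)`` over En1..En6 (mirrored for the decoders), so ``base_width``
scales the whole network: 4 for desk-scale experiments and tests, 16+
for real training runs.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .blocks import AttentiveRSU, AttentiveRSU4F
from .nn import Conv2d, Module, ModuleList

__all__ = ["NetworkConfig", "NetworkOutput", "DoubleAttentionU2Net",
           "build_network", "save_checkpoint", "load_checkpoint"]

# (depth, is_dilated) for En1..En6; De1..De5 mirror the first five.
STAGE_PLAN = [(7, False), (6, False), (5, False), (4, False),
              (4, True), (4, True)]
WIDTH_MULTIPLIERS = (1, 2, 4, 8, 8, 8)


@dataclass
class NetworkConfig:
    """Architecture hyperparameters; the stage plan itself is fixed."""

    base_width: int = 16
    in_channels: int = 1
    use_gate: bool = True
    use_sam: bool = True
    use_cam: bool = True

    def __post_init__(self):
        if self.base_width < 2:
            raise ValueError("base_width must be >= 2")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkConfig":
        return cls(**d)


@dataclass
class NetworkOutput:
    """Fused and side probability maps (and their pre-sigmoid logits)."""

    fused: Tensor
    side: list[Tensor]
    fused_logit: Tensor
    side_logits: list[Tensor]

    @property
    def maps(self) -> list[Tensor]:
        """All seven probability maps: fused first, then the six sides."""
        return [self.fused] + list(self.side)


def _make_stage(depth: int, dilated: bool, in_ch: int, out_ch: int,
                rng: np.random.Generator, cfg: NetworkConfig) -> Module:
    mid = max(out_ch // 2, 2)
    if dilated:
        return AttentiveRSU4F(in_ch, mid, out_ch, rng,
                              use_gate=cfg.use_gate, use_cam=cfg.use_cam)
    return AttentiveRSU(depth, in_ch, mid, out_ch, rng,
                        use_gate=cfg.use_gate, use_sam=cfg.use_sam)


class DoubleAttentionU2Net(Module):
    """Nested-U network with double attention in every stage block."""

    def __init__(self, cfg: NetworkConfig, seed: int = 0):
        super().__init__()
        self.cfg = cfg
        self.seed = seed
        rng = np.random.default_rng(seed)
        b = cfg.base_width
        enc_out = [b * m for m in WIDTH_MULTIPLIERS]

        encoders = []
        in_ch = cfg.in_channels
        for (depth, dil), out_ch in zip(STAGE_PLAN, enc_out):
            encoders.append(_make_stage(depth, dil, in_ch, out_ch, rng, cfg))
            in_ch = out_ch
        self.encoders = ModuleList(encoders)

        # De5..De1 built deepest-first; De_k pairs with En_k's depth.
        dec_out = enc_out[:5]  # De1..De5 output widths
        decoders = []
        upstream = enc_out[5]  # En6 output feeds De5
        for k in reversed(range(5)):
            depth, dil = STAGE_PLAN[k] if k < 4 else (4, True)
            in_ch = upstream + enc_out[k]
            decoders.append(_make_stage(depth, dil, in_ch, dec_out[k], rng, cfg))
            upstream = dec_out[k]
        self.decoders = ModuleList(decoders)  # order: De5, De4, De3, De2, De1

        side_srcs = dec_out + [enc_out[5]]  # De1..De5, En6
        self.side_convs = ModuleList(
            [Conv2d(c, 1, 3, rng) for c in side_srcs])
        self.fuse = Conv2d(6, 1, 1, rng)

    # -- forward --------------------------------------------------------------
    def forward(self, image: Tensor) -> NetworkOutput:
        H, W = image.shape[2], image.shape[3]
        if H % 32 or W % 32 or H < 64 or W < 64:
            raise ValueError("pad or resize to multiple of 32 (min 64)")
        if image.shape[1] != self.cfg.in_channels:
            raise ValueError(
                f"expected {self.cfg.in_channels} input channels, got {image.shape[1]}")

        enc_feats = []
        h = image
        for i, enc in enumerate(self.encoders):
            if i > 0:
                h = ad.max_pool2x2(h)
            h = enc(h)
            enc_feats.append(h)

        dec_feats = []  # De5..De1
        g = enc_feats[5]
        for k, dec in zip(reversed(range(5)), self.decoders):
            skip = enc_feats[k]
            up = ad.upsample_bilinear(g, (skip.shape[2], skip.shape[3]))
            g = dec(ad.concat([up, skip], axis=1))
            dec_feats.append(g)

        # side logits from De1..De5 then En6, each at full resolution
        side_feats = list(reversed(dec_feats)) + [enc_feats[5]]
        side_logits = [
            ad.upsample_bilinear(conv(f), (H, W))
            for conv, f in zip(self.side_convs, side_feats)
        ]
        fused_logit = self.fuse(ad.concat(side_logits, axis=1))
        return NetworkOutput(
            fused=ad.sigmoid(fused_logit),
            side=[ad.sigmoid(s) for s in side_logits],
            fused_logit=fused_logit,
            side_logits=side_logits,
        )

    # -- introspection --------------------------------------------------------
    def stage_plan(self) -> dict[str, list[str]]:
        """Human-readable block assignment, encoders then decoders."""
        def label(m: Module) -> str:
            if isinstance(m, AttentiveRSU4F):
                return "4F"
            return str(m.depth)

        return {
            "encoders": [label(m) for m in self.encoders],
            "decoders": [label(m) for m in reversed(list(self.decoders))],
        }


def build_network(cfg: NetworkConfig, seed: int = 0) -> DoubleAttentionU2Net:
    """Construct the network with reproducible seeded initialization."""
    return DoubleAttentionU2Net(cfg, seed=seed)


def save_checkpoint(net: DoubleAttentionU2Net, path) -> None:
    """Serialize parameters, buffers and config to a single .npz archive."""
    state = net.state_dict()
    state["__config__"] = np.frombuffer(
        json.dumps({"cfg": net.cfg.to_dict(), "seed": net.seed}).encode(),
        dtype=np.uint8).copy()
    np.savez(path, **state)


def load_checkpoint(path) -> DoubleAttentionU2Net:
    """Rebuild a network from :func:`save_checkpoint` output."""
    try:
        with np.load(path) as archive:
            state = {k: archive[k] for k in archive.files}
    except Exception as exc:  # corrupt or not an archive
        raise ValueError(f"corrupt checkpoint: {path}") from exc
    if "__config__" not in state:
        raise ValueError(f"corrupt checkpoint (missing config): {path}")
    meta = json.loads(state.pop("__config__").tobytes().decode())
    net = DoubleAttentionU2Net(NetworkConfig.from_dict(meta["cfg"]),
                               seed=meta["seed"])
    net.load_state_dict(state)
    return net
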