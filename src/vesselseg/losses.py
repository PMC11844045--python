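"""Training objective: Dice loss + binary cross-entropy, deep-supervised.

The Dice term measures overlap between the predicted probability map
and the binary label,

    DiceLoss = 1 - (2 * sum(y * y_hat) + eps) / (sum(y) + sum(y_hat) + eps),

and saturates on thin structures, so a per-pixel binary cross-entropy
term complements it.  The deep-supervision total applies the combined
(Dice + CE) loss to the fused probability map and to each of the six
side maps with unit weights.

The cross-entropy here is the full two-class form, scoring background
pixels as well as vessel pixels; predictions are clipped to
[1e-7, 1 - 1e-7] before the logarithm.
"""

from __future__ import annotations

from . import autodiff as ad
from .autodiff import Tensor, as_tensor
from .network import NetworkOutput

__all__ = ["dice_loss", "cross_entropy_loss", "combined_loss"]

_CLIP = 1e-7


def _check(y_hat: Tensor, y: Tensor) -> None:
    if y_hat.shape != y.shape:
        raise ValueError(f"shape mismatch: {y_hat.shape} vs {y.shape}")


def dice_loss(y_hat, y, epsilon: float = 1e-6) -> Tensor:
    """1 minus the (smoothed) Dice coefficient; differentiable in y_hat."""
    y_hat, y = as_tensor(y_hat), as_tensor(y)
    _check(y_hat, y)
    inter = (y_hat * y).sum()
    denom = y_hat.sum() + y.sum()
    return 1.0 - (2.0 * inter + epsilon) / (denom + epsilon)


def cross_entropy_loss(y_hat, y) -> Tensor:
    """Mean binary cross-entropy over all pixels."""
    y_hat, y = as_tensor(y_hat), as_tensor(y)
    _check(y_hat, y)
    p = ad.clamp(y_hat, _CLIP, 1.0 - _CLIP)
    ll = y * ad.log(p) + (1.0 - y) * ad.log(1.0 - p)
    return -ll.mean()


def combined_loss(outputs: NetworkOutput, y) -> tuple[Tensor, dict[str, float]]:
    """Deep-supervised total over the fused map and all six side maps.

    Returns the differentiable total and a per-term float breakdown
    (keys ``fused_dice``, ``fused_ce``, ``side{i}_dice``, ``side{i}_ce``).
    """
    y = as_tensor(y)
    breakdown: dict[str, float] = {}
    total = None
    for name, prob in [("fused", outputs.fused)] + [
            (f"side{i}", s) for i, s in enumerate(outputs.side)]:
        d = dice_loss(prob, y)
        c = cross_entropy_loss(prob, y)
        breakdown[f"{name}_dice"] = float(d.data)
        breakdown[f"{name}_ce"] = float(c.data)
        term = d + c
        total = term if total is None else total + term
    return total, breakdown
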