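"""LV myocardium segmentation: U-Net training, contour extraction, metrics.

The network segments myocardium versus background (two classes); the
cavity is recovered downstream as the hole enclosed by the myocardium, so
endocardial and epicardial contours come out of a single mask.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import measure

from lvhquant.contours import ContourSet, SliceContours
from lvhquant.nn.losses import dice_loss_grad, soft_dice
from lvhquant.nn.optim import make_optimizer
from lvhquant.nn.unet import UNet


@dataclass(frozen=True)
class UNetSpec:
    """U-Net depth/width configuration; depth is blocks per side."""

    depth: int = 4
    base_filters: int = 16
    in_channels: int = 1
    out_classes: int = 2
    pooling: str = "average"

    def __post_init__(self) -> None:
        if self.depth not in (3, 4, 5):
            raise ValueError(f"U-Net depth must be in {{3, 4, 5}}, got {self.depth}")
        if self.pooling not in ("average", "max"):
            raise ValueError("pooling must be 'average' or 'max'")


def build_unet(spec: UNetSpec, seed: int = 0) -> UNet:
    """Instantiate the network; zero-padded convs keep output size == input."""
    return UNet(
        depth=spec.depth,
        base_filters=spec.base_filters,
        in_channels=spec.in_channels,
        out_classes=spec.out_classes,
        pooling=spec.pooling,
        rng=np.random.default_rng(seed),
    )


@dataclass
class SegTrainConfig:
    learning_rate: float = 1e-2
    optimizer: str = "adam"
    batch_size: int = 4
    epochs: int = 15
    seed: int = 0
    val_fraction: float = 0.25

    def __post_init__(self) -> None:
        if self.batch_size < 1 or self.epochs < 1:
            raise ValueError("batch_size and epochs must be >= 1")


def train_segmenter(cases, config: SegTrainConfig, spec: UNetSpec | None = None):
    """Train on (image, myocardium-mask) pairs with soft-Dice loss.

    Images are normalized per slice before batching. History records
    per-epoch mean training Dice (soft, from the training batches), hard
    validation Dice (percent) and mean loss; the parameter state of the
    best validation epoch is restored before returning.
    """
    cases = list(cases)
    if not cases:
        raise ValueError("empty training set")
    from lvhquant.imaging_io import normalize_minmax

    spec = spec or UNetSpec()
    rng = np.random.default_rng(config.seed)
    model = build_unet(spec, seed=config.seed)
    opt = make_optimizer(config.optimizer, model.params(), config.learning_rate)

    xs = np.stack([normalize_minmax(np.asarray(img, dtype=float)) for img, _ in cases])
    ys = np.stack([np.asarray(m).astype(float) for _, m in cases])
    idx = rng.permutation(len(cases))
    n_val = max(1, int(round(config.val_fraction * len(cases)))) if len(cases) > 1 else 0
    val_idx, train_idx = idx[:n_val], idx[n_val:]
    if train_idx.size == 0:
        train_idx, val_idx = idx, idx

    history = []
    best = (-np.inf, None)
    for epoch in range(config.epochs):
        order = rng.permutation(train_idx)
        losses, dices = [], []
        for start in range(0, len(order), config.batch_size):
            batch = order[start:start + config.batch_size]
            xb = xs[batch][:, None]
            yb = ys[batch]
            probs = model.forward(xb, training=True)
            loss, grad = dice_loss_grad(probs, yb)
            model.backward(grad)
            opt.step()
            losses.append(loss)
            dices.append(soft_dice(probs, yb))
        val_dice = _hard_dice(model, xs[val_idx], ys[val_idx]) if val_idx.size else float("nan")
        history.append(
            {"epoch": epoch + 1, "train_dice": float(np.mean(dices)),
             "val_dice": val_dice, "loss": float(np.mean(losses))}
        )
        if val_idx.size and val_dice > best[0]:
            best = (val_dice, model.get_state())
    if best[1] is not None:
        model.set_state(best[1])
    import pandas as pd

    return model, pd.DataFrame(history)


def _hard_dice(model: UNet, xs: np.ndarray, ys: np.ndarray) -> float:
    scores = []
    for x, y in zip(xs, ys):
        pred = model.predict(x)
        scores.append(dsc(pred == 1, y > 0.5))
    return float(np.mean(scores))


def predict_mask(model: UNet, image: np.ndarray) -> np.ndarray:
    """Binary myocardium mask for one slice (normalized internally)."""
    from lvhquant.imaging_io import normalize_minmax

    return (model.predict(normalize_minmax(np.asarray(image, dtype=float))) == 1).astype(np.uint8)


def depth_study(cases, depths=(3, 4, 5), config: SegTrainConfig | None = None,
                base_filters: int = 8):
    """Train one U-Net per depth on the same cases; returns a tidy frame
    with final train/validation Dice and the generalization gap per depth."""
    import pandas as pd

    config = config or SegTrainConfig()
    rows = []
    for d in depths:
        _, hist = train_segmenter(cases, config, UNetSpec(depth=d, base_filters=base_filters))
        last = hist.iloc[-1]
        rows.append(
            {"depth": d, "train_dice": last.train_dice * 100.0, "val_dice": last.val_dice,
             "gap": last.train_dice * 100.0 - last.val_dice,
             "n_parameters": build_unet(UNetSpec(depth=d, base_filters=base_filters)).n_parameters}
        )
    return pd.DataFrame(rows)


def masks_to_contours(mask: np.ndarray, spacing: tuple[float, float], level: str = "mid") -> SliceContours:
    """Endo/epi polygons from a myocardium label mask at sub-pixel precision.

    Keeps the largest connected component (warning if others are dropped),
    takes the outer marching-squares boundary as the epicardium and the
    boundary of the enclosed hole as the endocardium. Apex-labelled filled
    discs yield an epicardium only; a non-apex mask without a cavity is an
    error.
    """
    mask = np.asarray(mask) > 0
    labeled, n = ndimage.label(mask)
    if n == 0:
        raise ValueError("empty mask")
    if n > 1:
        sizes = ndimage.sum_labels(np.ones_like(labeled), labeled, index=range(1, n + 1))
        keep = int(np.argmax(sizes)) + 1
        warnings.warn(f"mask has {n} components; keeping the largest", stacklevel=2)
        mask = labeled == keep
    filled = ndimage.binary_fill_holes(mask)
    hole = filled & ~mask
    epi = _longest_contour(filled)
    if not hole.any():
        if level == "apex":
            return SliceContours(epi=epi, endo=None, level=level)
        raise ValueError("no cavity found on a non-apex slice")
    endo = _longest_contour(hole)
    return SliceContours(epi=epi, endo=endo, level=level)


def _longest_contour(binary: np.ndarray) -> np.ndarray:
    contours = measure.find_contours(binary.astype(float), 0.5)
    if not contours:
        raise ValueError("no contour found")
    return max(contours, key=len)


def dsc(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Dice similarity coefficient in percent: 2TP / (2TP + FP + FN) * 100.

    Two empty masks agree perfectly by convention (100).
    """
    a = np.asarray(mask_a) > 0
    b = np.asarray(mask_b) > 0
    if a.shape != b.shape:
        raise ValueError("masks must share one shape")
    denom = a.sum() + b.sum()
    if denom == 0:
        return 100.0
    return float(2.0 * np.logical_and(a, b).sum() / denom * 100.0)


def hausdorff(contour_a: np.ndarray, contour_b: np.ndarray,
              spacing: tuple[float, float] = (1.0, 1.0)) -> float:
    """Symmetric Hausdorff distance between closed polygons, in mm.

    Distances are point-to-segment (each vertex of one polygon against
    every edge of the other), which is robust to differing vertex
    discretizations; vertices are scaled to physical mm first.
    """
    a = np.asarray(contour_a, dtype=float)
    b = np.asarray(contour_b, dtype=float)
    if a.ndim != 2 or b.ndim != 2 or len(a) == 0 or len(b) == 0:
        raise ValueError("contours must be non-empty (N, 2) arrays")
    s = np.asarray(spacing, dtype=float)
    a = a * s[None, :]
    b = b * s[None, :]
    return max(_directed_hd(a, b), _directed_hd(b, a))


def _directed_hd(points: np.ndarray, poly: np.ndarray) -> float:
    """max over points of min distance to the closed polyline ``poly``."""
    p0 = poly
    p1 = np.roll(poly, -1, axis=0)
    seg = p1 - p0  # (M, 2)
    seg_len2 = (seg ** 2).sum(axis=1)
    seg_len2 = np.where(seg_len2 == 0, 1.0, seg_len2)
    diff = points[:, None, :] - p0[None, :, :]  # (N, M, 2)
    t = np.clip((diff * seg[None, :, :]).sum(axis=2) / seg_len2[None, :], 0.0, 1.0)
    proj = p0[None, :, :] + t[..., None] * seg[None, :, :]
    d = np.linalg.norm(points[:, None, :] - proj, axis=2)
    return float(d.min(axis=1).max())
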