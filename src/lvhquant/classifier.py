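"""CNN classifier of myocardial sub-segments by hypertrophy severity.

The reference architecture is a 25-layer network: five blocks of (3x3 conv
-> ReLU -> batch norm -> 2x2 average pool, stride 2) with 32/64/128/256/512
filters, where the first conv is same-padded and the later convs use an
explicit zero pad of 2 (each map grows by 4 before pooling, e.g. 128 ->
130); pooling uses floor division on odd sizes (67 -> 33). The features
are flattened into a 128-unit ReLU dense layer, dropout 0.3, a 16-unit
ReLU dense layer, and a softmax over the four severity classes. The
softmax head carries its own (16+1)*4 output projection.

A sub-segment is presented to the network as the full normalized slice
with every pixel outside the region's myocardial sector zeroed, replicated
to three channels — localizing the evidence while preserving the
fixed-size whole-image input contract. Reduced-width variants of the same
topology are used for phantom-scale training.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from lvhquant.aha import APEX, LandmarkSet, RegionPartition
from lvhquant.contours import SliceContours
from lvhquant.nn.layers import (
    AvgPool2D,
    BatchNorm2D,
    Conv2D,
    Dense,
    Dropout,
    Flatten,
    MaxPool2D,
    ReLU,
    Sequential,
    _Pool2D,
)
from lvhquant.nn.losses import softmax_cross_entropy
from lvhquant.nn.optim import make_optimizer
from lvhquant.severity import EvalReport, macro_metrics


@dataclass(frozen=True)
class ClassifierSpec:
    input_size: int = 256
    in_channels: int = 3
    filters: tuple[int, ...] = (32, 64, 128, 256, 512)
    dense: tuple[int, ...] = (128, 16)
    dropout: float = 0.3
    n_classes: int = 4
    pooling: str = "average"
    first_conv_padding: str | int = "same"
    later_conv_padding: int = 2

    def scaled(self, input_size: int, width_factor: float) -> "ClassifierSpec":
        """Same topology at reduced input size and filter widths."""
        return replace(
            self,
            input_size=input_size,
            filters=tuple(max(4, int(f * width_factor)) for f in self.filters),
        )


@dataclass(frozen=True)
class TraceRow:
    index: int
    name: str
    output_shape: tuple[int, ...]
    parameters: int


def shape_trace(spec: ClassifierSpec) -> list[TraceRow]:
    """Analytic 25-row layer trace: output shapes and parameter counts.

    Conv parameters follow ``(kh*kw*Cin + 1)*Cout``, batch norm ``2*C`` and
    dense ``(Nin + 1)*Nout``. Raises at the first layer whose output shape
    collapses.
    """
    rows: list[TraceRow] = []
    h = w = spec.input_size
    c = spec.in_channels
    rows.append(TraceRow(1, "input", (h, w, c), 0))
    idx = 2
    for i, f in enumerate(spec.filters):
        pad = spec.first_conv_padding if i == 0 else spec.later_conv_padding
        p = 1 if pad == "same" else int(pad)
        ho, wo = h + 2 * p - 2, w + 2 * p - 2
        if ho < 1 or wo < 1:
            raise ValueError(f"layer {idx} (conv {i + 1}): output shape collapses at {ho}x{wo}")
        params = (3 * 3 * c + 1) * f
        rows.append(TraceRow(idx, f"conv{i + 1}", (ho, wo, f), params)); idx += 1
        rows.append(TraceRow(idx, f"relu{i + 1}", (ho, wo, f), 0)); idx += 1
        rows.append(TraceRow(idx, f"batchnorm{i + 1}", (ho, wo, f), 2 * f)); idx += 1
        hp, wp = _Pool2D.out_shape(ho, wo)
        if hp < 1 or wp < 1:
            raise ValueError(f"layer {idx} (pool {i + 1}): output shape collapses")
        rows.append(TraceRow(idx, f"{spec.pooling}pool{i + 1}", (hp, wp, f), 0)); idx += 1
        h, w, c = hp, wp, f
    flat = h * w * c
    nin = flat
    for j, nout in enumerate(spec.dense):
        rows.append(TraceRow(idx, f"dense{j + 1}", (nout,), (nin + 1) * nout)); idx += 1
        if j == 0:
            rows.append(TraceRow(idx, "dropout", (nout,), 0)); idx += 1
        nin = nout
    rows.append(TraceRow(idx, "softmax", (spec.n_classes,), (nin + 1) * spec.n_classes))
    return rows


def build_classifier(spec: ClassifierSpec, seed: int = 0) -> tuple[Sequential, list[TraceRow]]:
    """Construct the network and its per-layer trace.

    The returned network ends in logits (the softmax is folded into the
    cross-entropy loss during training and applied in ``predict``).
    """
    trace = shape_trace(spec)  # validates shapes before any allocation
    rng = np.random.default_rng(seed)
    pool_cls = AvgPool2D if spec.pooling == "average" else MaxPool2D
    layers = []
    c = spec.in_channels
    for i, f in enumerate(spec.filters):
        pad = spec.first_conv_padding if i == 0 else spec.later_conv_padding
        layers += [Conv2D(c, f, 3, padding=pad, rng=rng), ReLU(), BatchNorm2D(f), pool_cls()]
        c = f
    layers.append(Flatten())
    flat_row = trace[1 + 4 * len(spec.filters) - 1]  # last pool row
    nin = int(np.prod(flat_row.output_shape))
    for j, nout in enumerate(spec.dense):
        layers += [Dense(nin, nout, rng=rng), ReLU()]
        if j == 0:
            layers.append(Dropout(spec.dropout, rng=np.random.default_rng(seed + 1)))
        nin = nout
    layers.append(Dense(nin, spec.n_classes, rng=rng))
    net = Sequential(layers)
    return net, trace


def predict_classes(net: Sequential, x: np.ndarray) -> np.ndarray:
    logits = net.forward(x, training=False)
    return logits.argmax(axis=1)


def encode_subsegment(
    image: np.ndarray,
    partition: RegionPartition,
    region_id: int,
    contours_slice: SliceContours,
    landmarks: LandmarkSet,
    out_size: int = 256,
) -> np.ndarray:
    """Sector-masked classifier input for one region, shape (3, S, S).

    The normalized slice is zeroed outside the region's angular sector
    between the endo- and epicardial contours, padded to square if needed,
    resized, and replicated to three channels.
    """
    from skimage.draw import polygon as draw_polygon
    from skimage.transform import resize

    from lvhquant.imaging_io import normalize_minmax

    img = normalize_minmax(np.asarray(image, dtype=float))
    h, w = img.shape
    myo = np.zeros((h, w), dtype=bool)
    rr, cc = draw_polygon(contours_slice.epi[:, 0], contours_slice.epi[:, 1], shape=(h, w))
    myo[rr, cc] = True
    if contours_slice.endo is not None:
        rr, cc = draw_polygon(contours_slice.endo[:, 0], contours_slice.endo[:, 1], shape=(h, w))
        myo[rr, cc] = False

    b = partition.bin_by_id(region_id)
    if b.level == APEX:
        sector = np.ones((h, w), dtype=bool)
    else:
        rows = np.arange(h)[:, None] - landmarks.lv_center[0]
        cols = np.arange(w)[None, :] - landmarks.lv_center[1]
        ang = (np.degrees(np.arctan2(-rows, np.broadcast_to(cols, (h, w))))
               - partition.anchor_deg) % 360.0
        sector = (ang >= b.start_deg) & (ang < b.end_deg)
    masked = np.where(myo & sector, img, 0.0)
    if not masked.any():
        raise ValueError(f"region {region_id} contains no myocardial pixels")
    if h != w:  # pad to square, preserving aspect
        side = max(h, w)
        sq = np.zeros((side, side))
        sq[(side - h) // 2:(side - h) // 2 + h, (side - w) // 2:(side - w) // 2 + w] = masked
        masked = sq
    if masked.shape[0] != out_size:
        masked = resize(masked, (out_size, out_size), order=1, anti_aliasing=True)
    return np.repeat(masked[None], 3, axis=0)


@dataclass
class ClassifierTrainConfig:
    optimizer: str = "adamax"
    learning_rate: float = 1e-3
    batch_size: int = 4
    epochs: int = 70
    split: tuple[float, float, float] = (0.7, 0.1, 0.2)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.optimizer.lower() not in ("adam", "adamax", "rmsprop", "sgd"):
            raise ValueError(f"unsupported optimizer {self.optimizer!r}")
        if abs(sum(self.split) - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")


def stratified_split(labels, split=(0.7, 0.1, 0.2), seed: int = 0):
    """Per-class shuffled index split into (train, val, test) lists."""
    labels = np.asarray(labels, dtype=int)
    rng = np.random.default_rng(seed)
    train, val, test = [], [], []
    for c in np.unique(labels):
        idx = np.flatnonzero(labels == c)
        rng.shuffle(idx)
        n = len(idx)
        n_tr = max(1, int(round(split[0] * n)))
        n_val = int(round(split[1] * n))
        train += list(idx[:n_tr])
        val += list(idx[n_tr:n_tr + n_val])
        test += list(idx[n_tr + n_val:])
    for c in np.unique(labels):
        if not any(labels[i] == c for i in train):
            raise ValueError(f"stratification failed: class {c} absent from training split")
    return sorted(train), sorted(val), sorted(test)


def train_classifier(dataset, config: ClassifierTrainConfig, spec: ClassifierSpec | None = None):
    """Train on (input, label) pairs; returns (net, history, split_indices).

    Dataset entries are ``(x, label)`` with ``x`` of shape (3, S, S) as
    produced by :func:`encode_subsegment`. The split is stratified by
    class under the config seed; history records per-epoch training
    accuracy and validation loss/accuracy and the best-validation state is
    restored.
    """
    dataset = list(dataset)
    if not dataset:
        raise ValueError("empty dataset")
    xs = np.stack([x for x, _ in dataset])
    ys = np.asarray([int(y) for _, y in dataset])
    spec = spec or ClassifierSpec(input_size=xs.shape[-1])
    net, _ = build_classifier(spec, seed=config.seed)
    opt = make_optimizer(config.optimizer, net.params(), config.learning_rate)
    train_idx, val_idx, test_idx = stratified_split(ys, config.split, config.seed)
    rng = np.random.default_rng(config.seed + 7)

    history = []
    best = (-np.inf, None)
    for epoch in range(config.epochs):
        order = rng.permutation(train_idx)
        correct = 0
        for start in range(0, len(order), config.batch_size):
            batch = order[start:start + config.batch_size]
            logits = net.forward(xs[batch], training=True)
            _, grad = softmax_cross_entropy(logits, ys[batch])
            correct += int((logits.argmax(axis=1) == ys[batch]).sum())
            net.backward(grad)
            opt.step()
        train_acc = correct / len(order) * 100.0
        val_loss, val_acc = _evaluate_loss_acc(net, xs, ys, val_idx, config.batch_size)
        history.append(
            {"epoch": epoch + 1, "train_accuracy": train_acc,
             "val_loss": val_loss, "val_accuracy": val_acc}
        )
        if val_acc >= best[0]:
            best = (val_acc, net.get_state())
    if best[1] is not None:
        net.set_state(best[1])
    import pandas as pd

    return net, pd.DataFrame(history), (train_idx, val_idx, test_idx)


def _evaluate_loss_acc(net, xs, ys, idx, batch_size):
    if not idx:
        return float("nan"), float("nan")
    losses, correct = [], 0
    for start in range(0, len(idx), batch_size):
        batch = np.asarray(idx[start:start + batch_size])
        logits = net.forward(xs[batch], training=False)
        loss, _ = softmax_cross_entropy(logits, ys[batch])
        losses.append(loss * len(batch))
        correct += int((logits.argmax(axis=1) == ys[batch]).sum())
    return float(np.sum(losses) / len(idx)), correct / len(idx) * 100.0


def evaluate_classifier(net, dataset, indices, batch_size: int = 8) -> EvalReport:
    xs = np.stack([dataset[i][0] for i in indices])
    ys = [int(dataset[i][1]) for i in indices]
    preds = []
    for start in range(0, len(indices), batch_size):
        preds.extend(predict_classes(net, xs[start:start + batch_size]).tolist())
    return macro_metrics(ys, preds)


def hyperparameter_grid(dataset, optimizers=("rmsprop", "adam", "adamax"),
                        learning_rates=(1e-1, 1e-2, 1e-3), batch_sizes=(4, 8),
                        epochs_list=(10,), spec: ClassifierSpec | None = None,
                        seed: int = 0):
    """Train one classifier per (optimizer, LR, batch, epochs) combination.

    Emits one row per combination with the final training and validation
    accuracies — the harness behind optimizer/learning-rate comparisons.
    """
    import pandas as pd

    rows = []
    for opt in optimizers:
        for lr in learning_rates:
            for bs in batch_sizes:
                for ep in epochs_list:
                    cfg = ClassifierTrainConfig(
                        optimizer=opt, learning_rate=lr, batch_size=bs, epochs=ep, seed=seed
                    )
                    _, hist, _ = train_classifier(dataset, cfg, spec)
                    last = hist.iloc[-1]
                    rows.append(
                        {"optimizer": opt, "learning_rate": lr, "batch_size": bs,
                         "epochs": ep, "train_accuracy": last.train_accuracy,
                         "val_accuracy": last.val_accuracy}
                    )
    return pd.DataFrame(rows)
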