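"""U-Net-style encoder-decoder for binary lung-nodule segmentation.

The architecture mirrors the classic contracting/expanding design: ``depth``
encoder levels of two 3x3 same-padding convolutions + ReLU followed by 2x2
max-pooling, dropout at the bottleneck, and a decoder of 2x2 stride-2
transposed convolutions with skip concatenation from the matching encoder
level and two convolutions per level.  Filter counts double per level from
``base_filters`` (8-16-32-...).  ``skip_mode="nested"`` switches to densely
re-aggregated (U-Net++-style) skip pathways.  The head is a 1x1 convolution
with a sigmoid (default) or two-class softmax.

Training minimizes the Dice loss

    L = 1 - (2 sum(p*t) + eps) / (sum(p) + sum(t) + eps),   eps = 1,

with an Adam optimizer and L2 weight decay on convolution kernels.  Everything
runs in float64 on a single CPU thread, so a fixed seed reproduces runs
bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor

__all__ = [
    "NetworkSpec", "TrainConfig", "TrainReport", "UNet", "build_network",
    "count_layers", "dice_loss", "split_dataset", "train", "predict_mask",
    "save_checkpoint", "load_checkpoint",
]


@dataclass(frozen=True)
class NetworkSpec:
    """Declarative description of the encoder-decoder."""

    input_size: tuple[int, int] = (128, 128)
    depth: int = 5
    base_filters: int = 8
    dropout_rate: float = 0.5
    l2_lambda: float = 0.001
    skip_mode: Literal["plain", "nested"] = "plain"
    out_activation: Literal["sigmoid", "softmax"] = "sigmoid"

    def __post_init__(self) -> None:
        h, w = self.input_size
        if h % 2**self.depth or w % 2**self.depth:
            raise ValueError(
                f"input size {self.input_size} not divisible by 2^depth={2**self.depth}"
            )
        if self.base_filters < 1:
            raise ValueError("base_filters must be >= 1")
        if not (0 <= self.dropout_rate < 1):
            raise ValueError("dropout_rate must be in [0, 1)")

    def filters(self, level: int) -> int:
        return self.base_filters * 2**level


def _he_init(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


class UNet:
    """Trainable model handle; parameters live in ``self.params``."""

    def __init__(self, spec: NetworkSpec, seed: int = 0):
        self.spec = spec
        self.seed = seed
        self.params: dict[str, Tensor] = {}
        rng = np.random.default_rng(seed)
        d = spec.depth

        def add_conv(name: str, cin: int, cout: int, k: int = 3) -> None:
            self.params[f"{name}_w"] = Tensor(
                _he_init(rng, (cout, cin, k, k), cin * k * k), requires_grad=True)
            self.params[f"{name}_b"] = Tensor(np.zeros(cout), requires_grad=True)

        def add_up(name: str, cin: int, cout: int) -> None:
            self.params[f"{name}_w"] = Tensor(
                _he_init(rng, (cin, cout, 2, 2), cin * 4), requires_grad=True)
            self.params[f"{name}_b"] = Tensor(np.zeros(cout), requires_grad=True)

        cin = 1
        for i in range(d):
            f = spec.filters(i)
            add_conv(f"enc{i}_c1", cin, f)
            add_conv(f"enc{i}_c2", f, f)
            cin = f

        if spec.skip_mode == "plain":
            prev = spec.filters(d - 1)
            for i in reversed(range(d)):
                f = spec.filters(i)
                add_up(f"up{i}", prev, f)
                add_conv(f"dec{i}_c1", 2 * f, f)
                add_conv(f"dec{i}_c2", f, f)
                prev = f
        else:
            for j in range(1, d + 1):
                for i in range(d - j, -1, -1):
                    f = spec.filters(i)
                    below = spec.filters(i + 1) if i + 1 < d else spec.filters(d - 1)
                    add_up(f"up{i}_{j}", below, f)
                    add_conv(f"node{i}_{j}_c1", j * f + f, f)
                    add_conv(f"node{i}_{j}_c2", f, f)

        out_ch = 2 if spec.out_activation == "softmax" else 1
        add_conv("head", spec.filters(0), out_ch, k=1)

    # ------------------------------------------------------------------

    def _conv_block(self, x: Tensor, name: str) -> Tensor:
        p = self.params
        x = ad.relu(ad.conv2d(x, p[f"{name}_c1_w"], p[f"{name}_c1_b"]))
        return ad.relu(ad.conv2d(x, p[f"{name}_c2_w"], p[f"{name}_c2_b"]))

    def forward(self, x, training: bool = False,
                rng: np.random.Generator | None = None) -> Tensor:
        """Probability maps in [0,1]; input (n,h,w) or (n,1,h,w)."""
        x = np.asarray(x, dtype=np.float64)
        if x.ndim == 3:
            x = x[:, None]
        if x.shape[2:] != tuple(self.spec.input_size):
            raise ValueError(
                f"input spatial size {x.shape[2:]} != spec {self.spec.input_size}")
        if training and rng is None:
            rng = np.random.default_rng(self.seed)
        p, d = self.params, self.spec.depth
        h = Tensor(x)

        if self.spec.skip_mode == "plain":
            skips = []
            for i in range(d):
                h = self._conv_block(h, f"enc{i}")
                skips.append(h)
                h = ad.maxpool2x2(h)
            h = ad.dropout(h, self.spec.dropout_rate, rng, training)
            for i in reversed(range(d)):
                h = ad.relu(ad.conv_transpose2x2(h, p[f"up{i}_w"], p[f"up{i}_b"]))
                h = ad.concat([skips[i], h])
                h = self._conv_block(h, f"dec{i}")
        else:
            X: dict[tuple[int, int], Tensor] = {}
            for i in range(d):
                h = self._conv_block(h, f"enc{i}")
                X[i, 0] = h
                h = ad.maxpool2x2(h)
            X[d, 0] = ad.dropout(h, self.spec.dropout_rate, rng, training)
            for j in range(1, d + 1):
                for i in range(d - j, -1, -1):
                    up = ad.relu(ad.conv_transpose2x2(
                        X[i + 1, j - 1], p[f"up{i}_{j}_w"], p[f"up{i}_{j}_b"]))
                    h = ad.concat([X[i, jj] for jj in range(j)] + [up])
                    X[i, j] = self._conv_block(h, f"node{i}_{j}")
            h = X[0, d]

        logits = ad.conv2d(h, p["head_w"], p["head_b"])
        if self.spec.out_activation == "softmax":
            return ad.softmax2(logits)
        return ad.sigmoid(logits)

    def predict_proba(self, x) -> np.ndarray:
        """Eval-mode probability maps, (n,h,w)."""
        return self.forward(x, training=False).data[:, 0]

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.params.items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for k, v in state.items():
            self.params[k].data = np.asarray(v, dtype=np.float64).copy()

    def parameter_count(self) -> int:
        return sum(t.data.size for t in self.params.values())


def build_network(spec: NetworkSpec, seed: int = 0) -> UNet:
    """Instantiate the network described by ``spec``."""
    return UNet(spec, seed=seed)


def count_layers(spec: NetworkSpec) -> dict[str, int]:
    """Per-kind layer counts of the constructed graph."""
    d = spec.depth
    enc = 2 * d
    if spec.skip_mode == "plain":
        dec = 2 * d
        up = d
    else:
        n_nodes = d * (d + 1) // 2
        dec = 2 * n_nodes
        up = n_nodes
    return {"conv": enc + dec + 1, "encoder_conv": enc, "decoder_conv": dec,
            "conv_transpose": up, "pool": d, "dropout": 1}


def dice_loss(pred, target, eps: float = 1.0) -> float:
    """Dice loss 1 - (2 sum(p t) + eps)/(sum p + sum t + eps) on arrays."""
    pred = np.asarray(pred, dtype=float)
    target = np.asarray(target, dtype=float)
    if pred.shape != target.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {target.shape}")
    inter = float((pred * target).sum())
    return 1.0 - (2.0 * inter + eps) / (float(pred.sum()) + float(target.sum()) + eps)


def _dice_loss_t(pred: Tensor, target: np.ndarray, eps: float = 1.0) -> Tensor:
    t = Tensor(target)
    inter = (pred * t).sum()
    return 1.0 - (2.0 * inter + eps) / (pred.sum() + t.sum() + eps)


@dataclass(frozen=True)
class TrainConfig:
    """Adam/Dice training recipe with a 70/15/15 split."""

    learning_rate: float = 0.001
    batch_size: int = 32
    epochs: int = 100
    split_fractions: tuple[float, float, float] = (0.70, 0.15, 0.15)
    seed: int = 0
    threshold: float = 0.5

    def __post_init__(self) -> None:
        f = np.asarray(self.split_fractions, dtype=float)
        if np.any(f <= 0) or abs(f.sum() - 1.0) > 1e-9:
            raise ValueError("split fractions must be positive and sum to 1")


@dataclass
class TrainReport:
    """Per-epoch loss/Dice records and the best-checkpoint reference."""

    epochs: list[dict[str, float]] = field(default_factory=list)
    best_epoch: int = -1
    best_state: dict[str, np.ndarray] | None = None
    seed: int = 0

    @property
    def elapsed_epochs(self) -> int:
        return len(self.epochs)

    def to_csv(self, path) -> None:
        import csv

        with open(path, "w", newline="") as fh:
            writer = csv.DictWriter(
                fh, fieldnames=["epoch", "train_loss", "val_loss", "train_dice", "val_dice"])
            writer.writeheader()
            for row in self.epochs:
                writer.writerow(row)


def split_dataset(items, cfg: TrainConfig):
    """Seeded shuffle, then contiguous 70/15/15 partition of indices.

    Train/val sizes round down; the remainder goes to test.  The three index
    lists are disjoint and exhaustive.
    """
    n = len(items)
    if n < 3:
        raise ValueError("need at least 3 items to split")
    order = np.random.default_rng(cfg.seed).permutation(n)
    n_train = int(np.floor(cfg.split_fractions[0] * n))
    n_val = int(np.floor(cfg.split_fractions[1] * n))
    if n_train == 0 or n_val == 0 or n - n_train - n_val == 0:
        raise ValueError(f"split of {n} items produced an empty subset")
    return (order[:n_train].tolist(),
            order[n_train:n_train + n_val].tolist(),
            order[n_train + n_val:].tolist())


class _Adam:
    def __init__(self, params: dict[str, Tensor], lr: float, l2: float):
        self.params = params
        self.lr = lr
        self.l2 = l2
        self.t = 0
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}

    def step(self) -> None:
        self.t += 1
        b1, b2, eps = 0.9, 0.999, 1e-8
        for k, p in self.params.items():
            g = p.grad if p.grad is not None else np.zeros_like(p.data)
            if self.l2 > 0 and k.endswith("_w"):
                g = g + 2.0 * self.l2 * p.data
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = self.m[k] / (1 - b1**self.t)
            vhat = self.v[k] / (1 - b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + eps)

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None


def _epoch_metrics(model: UNet, images, masks, threshold: float):
    prob = model.predict_proba(images)
    loss = dice_loss(prob, masks)
    d = [  # mean per-sample Dice of the thresholded predictions
        _binary_dice(prob[i] >= threshold, masks[i]) for i in range(len(images))
    ]
    return loss, float(np.mean(d))


def _binary_dice(a, b) -> float:
    a, b = np.asarray(a, bool), np.asarray(b, bool)
    s = a.sum() + b.sum()
    return 1.0 if s == 0 else float(2 * np.sum(a & b) / s)


def train(model: UNet, dataset, cfg: TrainConfig | None = None,
          val_dataset=None, verbose: bool = False) -> TrainReport:
    """Seeded single-device training loop minimizing the Dice loss.

    ``dataset`` is a sequence of (image, mask) pairs of arrays matching the
    model's input size.  The report tracks per-epoch train/val loss and Dice
    (computed in eval mode) and keeps the best-validation checkpoint (best
    train loss when no validation set is given).
    """
    cfg = cfg or TrainConfig()
    if len(dataset) == 0:
        raise ValueError("dataset must be non-empty")
    images = np.stack([np.asarray(im, dtype=float) for im, _ in dataset])
    masks = np.stack([np.asarray(mk, dtype=float) for _, mk in dataset])
    if val_dataset:
        vimages = np.stack([np.asarray(im, dtype=float) for im, _ in val_dataset])
        vmasks = np.stack([np.asarray(mk, dtype=float) for _, mk in val_dataset])
    rng = np.random.default_rng(cfg.seed)
    opt = _Adam(model.params, cfg.learning_rate, model.spec.l2_lambda)
    report = TrainReport(seed=cfg.seed)
    best = np.inf

    for epoch in range(1, cfg.epochs + 1):
        order = rng.permutation(len(images))
        for b0 in range(0, len(images), cfg.batch_size):
            idx = order[b0:b0 + cfg.batch_size]
            pred = model.forward(images[idx], training=True, rng=rng)
            loss = _dice_loss_t(pred, masks[idx][:, None])
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}, batch {b0 // cfg.batch_size}")
            opt.zero_grad()
            loss.backward()
            opt.step()

        tr_loss, tr_dice = _epoch_metrics(model, images, masks, cfg.threshold)
        if val_dataset:
            va_loss, va_dice = _epoch_metrics(model, vimages, vmasks, cfg.threshold)
        else:
            va_loss, va_dice = float("nan"), float("nan")
        report.epochs.append({"epoch": epoch, "train_loss": tr_loss,
                              "val_loss": va_loss, "train_dice": tr_dice,
                              "val_dice": va_dice})
        monitor = va_loss if val_dataset else tr_loss
        if monitor < best:
            best = monitor
            report.best_epoch = epoch
            report.best_state = model.state_dict()
        if verbose:
            print(f"epoch {epoch:4d}  train_loss {tr_loss:.4f}  train_dice {tr_dice:.4f}"
                  + (f"  val_loss {va_loss:.4f}" if val_dataset else ""))
    return report


def predict_mask(model: UNet, image, threshold: float = 0.5):
    """Binary mask and probability map for a single image."""
    arr = np.asarray(getattr(image, "pixels", image), dtype=float)
    if arr.shape != tuple(model.spec.input_size):
        raise ValueError(f"image size {arr.shape} != spec {model.spec.input_size}")
    prob = model.predict_proba(arr[None])[0]
    return (prob >= threshold), prob


def save_checkpoint(model: UNet, path) -> None:
    """Serialize spec + weights to an .npz checkpoint."""
    meta = dict(
        input_h=model.spec.input_size[0], input_w=model.spec.input_size[1],
        depth=model.spec.depth, base_filters=model.spec.base_filters,
        dropout_rate=model.spec.dropout_rate, l2_lambda=model.spec.l2_lambda,
        skip_mode=model.spec.skip_mode, out_activation=model.spec.out_activation,
        seed=model.seed,
    )
    np.savez(path, __meta__=np.array([repr(meta)]), **model.state_dict())


def load_checkpoint(path) -> UNet:
    import ast
    from pathlib import Path

    if not Path(path).exists():
        raise FileNotFoundError(f"checkpoint not found: {path}")
    with np.load(path, allow_pickle=False) as data:
        meta = ast.literal_eval(str(data["__meta__"][0]))
        spec = NetworkSpec(
            input_size=(int(meta["input_h"]), int(meta["input_w"])),
            depth=int(meta["depth"]), base_filters=int(meta["base_filters"]),
            dropout_rate=float(meta["dropout_rate"]), l2_lambda=float(meta["l2_lambda"]),
            skip_mode=meta["skip_mode"], out_activation=meta["out_activation"])
        model = UNet(spec, seed=int(meta["seed"]))
        model.load_state_dict({k: data[k] for k in data.files if k != "__meta__"})
    return model
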