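"""Trainable QA classifier: predicts per-slice contour quality from images.

The classifier consumes a stack of up to three co-registered channels
(CT, segmentation probability map, uncertainty map) and emits a softmax
distribution over either 3 quality levels (good / medium / bad) or 101
discretized DSC classes.  The default backbone is a small convolutional
network (conv-ReLU-maxpool blocks, global average pooling, linear head)
implemented directly on numpy with hand-written backpropagation, trained
with SGD (momentum, weight decay) under a poly learning-rate schedule
``lr = base_lr * (1 - iter/max_iter)^power``.  Training supports random
left-right flipping, crop-and-resize "cutting" and small rotations as
augmentation, and minority-class oversampling for imbalanced label
distributions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Iterable, Sequence

import numpy as np
from scipy import ndimage
from skimage import transform

from . import preprocess, qa

__all__ = [
    "ClassifierConfig",
    "TrainedQAModel",
    "build_model",
    "augment",
    "oversample_minority",
    "train",
    "predict",
    "prepare_inputs",
]

HEADS = {"levels3": 3, "dsc101": 101}


@dataclass
class ClassifierConfig:
    """Hyperparameters of the QA classifier.

    Optimizer defaults (batch size 16, momentum 0.9, weight decay 0.0005,
    poly learning-rate policy with base rate 0.00025 and power 0.9) follow
    the published fine-tuning schedule for a pretrained ResNet-101; for
    the from-scratch ``small_cnn`` backbone a larger ``base_lr`` is
    appropriate (the reference benchmark uses 0.05).
    """

    channel_set: tuple[str, ...] = ("ct", "prob", "unc")
    head: str = "levels3"
    backbone: str = "small_cnn"
    input_size: int = 224
    batch_size: int = 16
    momentum: float = 0.9
    weight_decay: float = 0.0005
    lr_policy: str = "poly"
    base_lr: float = 0.00025
    power: float = 0.9
    max_iterations: int = 1000
    eval_interval: int = 50
    flip_lr: bool = True
    random_crop: bool = True
    crop_fraction: float = 0.9
    rotation_range_deg: float = 5.0
    oversample: bool = True
    hidden_channels: tuple[int, ...] = (8, 16, 32)
    seed: int = 0

    def __post_init__(self) -> None:
        self.channel_set = qa.parse_channel_set(self.channel_set)
        if self.head not in HEADS:
            raise ValueError(f"unknown head {self.head!r}; expected one of {sorted(HEADS)}")
        if self.backbone not in ("small_cnn", "resnet101"):
            raise ValueError(f"unknown backbone {self.backbone!r}")
        if self.rotation_range_deg < 0:
            raise ValueError("rotation range must be symmetric about 0 (non-negative half-width)")
        if self.lr_policy != "poly":
            raise ValueError(f"unsupported lr_policy {self.lr_policy!r}")

    @property
    def n_classes(self) -> int:
        return HEADS[self.head]


# ---------------------------------------------------------- numpy layers ---


def _im2col(xpad: np.ndarray, k: int, h: int, w: int) -> np.ndarray:
    """(N, C, H+k-1, W+k-1) -> (N, H*W, C*k*k) patch matrix (stride 1)."""
    n, c = xpad.shape[:2]
    s = xpad.strides
    view = np.lib.stride_tricks.as_strided(
        xpad, shape=(n, c, h, w, k, k), strides=(s[0], s[1], s[2], s[3], s[2], s[3]),
    )
    return view.transpose(0, 2, 3, 1, 4, 5).reshape(n, h * w, c * k * k)


class _Conv:
    """3x3 same-padding convolution + ReLU."""

    k = 3

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        fan_in = c_in * self.k * self.k
        self.w = rng.normal(0.0, np.sqrt(2.0 / fan_in), (c_out, fan_in)).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        n, c, h, w = x.shape
        pad = self.k // 2
        xpad = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
        cols = _im2col(xpad, self.k, h, w)
        pre = cols @ self.w.T + self.b
        out = np.maximum(pre, 0.0)
        if training:
            self._cols, self._mask, self._hw = cols, pre > 0, (h, w)
        return out.transpose(0, 2, 1).reshape(n, -1, h, w)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        h, w = self._hw
        n = dout.shape[0]
        kk = self.k * self.k
        d = dout.reshape(n, -1, h * w).transpose(0, 2, 1) * self._mask
        dflat = d.reshape(-1, d.shape[2])
        self.dw = (dflat.T @ self._cols.reshape(-1, self._cols.shape[2])).astype(np.float32)
        self.db = dflat.sum(axis=0).astype(np.float32)
        dcols = dflat @ self.w  # (N*H*W, C*k*k)
        c_in = dcols.shape[1] // kk
        # scatter-add via strided views: entry layout is c*kk + (di*k + dj)
        dcols4 = dcols.reshape(n, h, w, c_in * kk)
        pad = self.k // 2
        dxpad = np.zeros((n, c_in, h + 2 * pad, w + 2 * pad), dtype=np.float32)
        for di in range(self.k):
            for dj in range(self.k):
                view = dcols4[:, :, :, di * self.k + dj::kk]  # (N, H, W, C)
                dxpad[:, :, di:di + h, dj:dj + w] += view.transpose(0, 3, 1, 2)
        return dxpad[:, :, pad:pad + h, pad:pad + w]

    @property
    def params(self):
        return [("w", self.w, "dw"), ("b", self.b, "db")]


class _MaxPool:
    """Non-overlapping k x k max pooling; gradient split across ties."""

    def __init__(self, k: int):
        self.k = k

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        n, c, h, w = x.shape
        k = self.k
        hk, wk = h // k, w // k
        xr = x[:, :, : hk * k, : wk * k].reshape(n, c, hk, k, wk, k)
        out = xr.max(axis=(3, 5))
        if training:
            mask = xr == out[:, :, :, None, :, None]
            self._mask = mask / mask.sum(axis=(3, 5), keepdims=True)
            self._in_shape = x.shape
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c, h, w = self._in_shape
        k = self.k
        hk, wk = h // k, w // k
        dx = (self._mask * dout[:, :, :, None, :, None]).reshape(n, c, hk * k, wk * k)
        if (hk * k, wk * k) != (h, w):
            dx = np.pad(dx, ((0, 0), (0, 0), (0, h - hk * k), (0, w - wk * k)))
        return dx

    params = ()


class _GapLinear:
    """Global average pooling followed by the classification head."""

    def __init__(self, c_in: int, n_classes: int):
        # zero head: initial softmax is exactly uniform
        self.w = np.zeros((n_classes, c_in), dtype=np.float32)
        self.b = np.zeros(n_classes, dtype=np.float32)

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        feat = x.mean(axis=(2, 3))
        if training:
            self._feat, self._in_shape = feat, x.shape
        return feat @ self.w.T + self.b

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.dw = (dout.T @ self._feat).astype(np.float32)
        self.db = dout.sum(axis=0).astype(np.float32)
        dfeat = dout @ self.w
        n, c, h, w = self._in_shape
        return np.broadcast_to(dfeat[:, :, None, None] / (h * w), (n, c, h, w)).astype(np.float32)

    @property
    def params(self):
        return [("w", self.w, "dw"), ("b", self.b, "db")]


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class _SmallCnn:
    """Conv-ReLU-MaxPool blocks + GAP + linear head, pure numpy."""

    def __init__(self, n_channels: int, n_classes: int,
                 hidden: Sequence[int], rng: np.random.Generator):
        self.layers: list = []
        c = n_channels
        pools = [4] + [2] * (len(hidden) - 1)
        for c_out, pk in zip(hidden, pools):
            self.layers.append(_Conv(c, c_out, rng))
            self.layers.append(_MaxPool(pk))
            c = c_out
        self.head = _GapLinear(c, n_classes)
        self.layers.append(self.head)

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        out = x.astype(np.float32)
        for layer in self.layers:
            out = layer.forward(out, training)
        return out

    def backward(self, dlogits: np.ndarray) -> None:
        d = dlogits.astype(np.float32)
        for layer in reversed(self.layers):
            d = layer.backward(d)

    def parameters(self):
        for layer in self.layers:
            for name, arr, gname in layer.params:
                yield layer, name, arr, gname

    def state_arrays(self) -> list[np.ndarray]:
        return [arr for _, _, arr, _ in self.parameters()]

    def load_arrays(self, arrays: Sequence[np.ndarray]) -> None:
        for (layer, name, arr, _), new in zip(self.parameters(), arrays):
            setattr(layer, name, new.astype(np.float32).copy())


@dataclass
class TrainedQAModel:
    """A (possibly trained) QA classifier with its configuration."""

    config: ClassifierConfig
    net: _SmallCnn
    training_history: list[dict] = field(default_factory=list)
    class_priors: np.ndarray | None = None

    def save(self, path) -> None:
        arrays = {f"p{k}": a for k, a in enumerate(self.net.state_arrays())}
        cfg = asdict(self.config)
        cfg["channel_set"] = list(cfg["channel_set"])
        cfg["hidden_channels"] = list(cfg["hidden_channels"])
        np.savez(
            path,
            config_json=np.frombuffer(json.dumps(cfg).encode(), dtype=np.uint8),
            history_json=np.frombuffer(json.dumps(self.training_history).encode(), dtype=np.uint8),
            priors=self.class_priors if self.class_priors is not None else np.zeros(0),
            **arrays,
        )

    @classmethod
    def load(cls, path) -> "TrainedQAModel":
        data = np.load(path)
        cfg = json.loads(bytes(data["config_json"]).decode())
        cfg["channel_set"] = tuple(cfg["channel_set"])
        cfg["hidden_channels"] = tuple(cfg["hidden_channels"])
        config = ClassifierConfig(**cfg)
        model = build_model(config)
        n_params = len(list(model.net.parameters()))
        model.net.load_arrays([data[f"p{k}"] for k in range(n_params)])
        model.training_history = json.loads(bytes(data["history_json"]).decode())
        priors = data["priors"]
        model.class_priors = priors if priors.size else None
        return model


def build_model(config: ClassifierConfig) -> TrainedQAModel:
    """Construct an untrained QA classifier for the given configuration."""
    if config.backbone == "resnet101":
        raise NotImplementedError(
            "the resnet101 backbone (101-layer residual network, 2048-wide "
            "pooled features) is defined but not trainable in this package; "
            "use backbone='small_cnn'"
        )
    rng = np.random.default_rng([config.seed, 11])
    net = _SmallCnn(len(config.channel_set), config.n_classes,
                    config.hidden_channels, rng)
    return TrainedQAModel(config=config, net=net)


# ----------------------------------------------------------- data plumbing -


def prepare_inputs(
    dataset,
    channel_set: Iterable[str] = ("ct", "prob", "unc"),
    input_size: int = 224,
    clahe_clip: float = preprocess.DEFAULT_CLIP_LIMIT,
    clahe_tiles: int = preprocess.DEFAULT_TILE_GRID,
) -> dict[str, dict[str, np.ndarray]]:
    """Turn a SyntheticDataset into per-split QA-network tensors.

    For every slice: CLAHE-normalize the CT at full resolution, derive the
    uncertainty map from the probability map, downsample the requested
    channels to ``input_size`` and stack them in canonical order.  Labels
    (DSC, quality level, DSC class) come from the manifest, i.e. from
    full-resolution masks.  Returns ``{split: {"x", "level", "dsc_class",
    "dsc", "patient_id"}}``.
    """
    channels = qa.parse_channel_set(channel_set)
    out: dict[str, dict[str, list]] = {
        s: {"x": [], "level": [], "dsc_class": [], "dsc": [], "patient_id": []}
        for s in ("train", "val", "test")
    }
    man = dataset.manifest.set_index(["patient_id", "slice_index"])
    for pid, chans in dataset.volumes.items():
        split = dataset.split[pid]
        n = chans["ct"].shape[2]
        for s in range(n):
            row = man.loc[(pid, s)]
            planes = {}
            ranges = []
            if "ct" in channels:
                planes["ct"] = preprocess.enhance_contrast(
                    chans["ct"][:, :, s], clahe_clip, clahe_tiles)
                ranges.append((0.0, 1.0))
            if "prob" in channels:
                planes["prob"] = chans["prob"][:, :, s].astype(np.float64)
                ranges.append((0.0, 1.0))
            if "unc" in channels:
                planes["unc"] = qa.uncertainty_map(
                    np.clip(chans["prob"][:, :, s].astype(np.float64), 0.0, 1.0))
                ranges.append((0.0, 0.5))
            ordered = [planes[c] for c in channels]
            small = preprocess.downsample_for_qa(ordered, input_size, ranges)
            out[split]["x"].append(np.stack(small, axis=0))
            out[split]["level"].append(int(row["quality_level"]))
            out[split]["dsc_class"].append(int(row["dsc_class"]))
            out[split]["dsc"].append(float(row["dsc"]))
            out[split]["patient_id"].append(pid)
    result = {}
    for split, d in out.items():
        result[split] = {
            "x": np.asarray(d["x"], dtype=np.float32) if d["x"] else
            np.zeros((0, len(channels), input_size, input_size), dtype=np.float32),
            "level": np.asarray(d["level"], dtype=np.int64),
            "dsc_class": np.asarray(d["dsc_class"], dtype=np.int64),
            "dsc": np.asarray(d["dsc"], dtype=np.float64),
            "patient_id": np.asarray(d["patient_id"], dtype=object),
        }
    return result


# ------------------------------------------------------------ augmentation -


def augment(
    x: np.ndarray,
    rng: np.random.Generator,
    flip_lr: bool = True,
    random_crop: bool = True,
    crop_fraction: float = 0.9,
    rotation_range_deg: float = 5.0,
) -> np.ndarray:
    """Randomly flip / crop-and-resize / rotate one (C, H, W) sample.

    All channels are transformed jointly; the label is untouched by
    construction.  Deterministic for a given generator state.  With all
    augmentations disabled this is the identity.
    """
    out = x
    if flip_lr and rng.random() < 0.5:
        out = out[:, :, ::-1]
    if random_crop:
        c, h, w = out.shape
        ch, cw = int(round(h * crop_fraction)), int(round(w * crop_fraction))
        if ch < h or cw < w:
            top = rng.integers(0, h - ch + 1)
            left = rng.integers(0, w - cw + 1)
            crop = out[:, top:top + ch, left:left + cw]
            out = np.stack([
                transform.resize(crop[k], (h, w), order=1, preserve_range=True,
                                 anti_aliasing=False)
                for k in range(c)
            ], axis=0)
    if rotation_range_deg > 0:
        angle = np.deg2rad(rng.uniform(-rotation_range_deg, rotation_range_deg))
        c, s = np.cos(angle), np.sin(angle)
        h, w = out.shape[1:]
        center = np.array([(h - 1) / 2.0, (w - 1) / 2.0])
        rot = np.array([[c, s], [-s, c]])
        # one affine call rotating all channels jointly about the center
        mat = np.eye(3)
        mat[1:, 1:] = rot
        offset = np.r_[0.0, center - rot @ center]
        out = ndimage.affine_transform(
            np.ascontiguousarray(out, dtype=np.float32), mat, offset,
            order=1, mode="constant", cval=0.0)
    return np.ascontiguousarray(out, dtype=np.float32)


def oversample_minority(indices_or_records: Sequence, labels: Sequence[int],
                        seed: int = 0) -> list:
    """Balance class counts by resampling minority classes with replacement.

    Every original record is retained; minority classes are topped up to
    the majority count by seeded sampling with replacement.  Labels are
    never modified.  Works on any record sequence aligned with ``labels``.
    """
    records = list(indices_or_records)
    if not records:
        raise ValueError("empty input")
    labels = np.asarray(labels)
    if len(labels) != len(records):
        raise ValueError("labels must align with records")
    rng = np.random.default_rng([seed, 17])
    classes, counts = np.unique(labels, return_counts=True)
    majority = counts.max()
    out = list(records)
    for cls, cnt in zip(classes, counts):
        if cnt < majority:
            pool = np.flatnonzero(labels == cls)
            extra = rng.choice(pool, size=majority - cnt, replace=True)
            out.extend(records[i] for i in extra)
    return out


# ---------------------------------------------------------------- training -


def _cross_entropy(probs: np.ndarray, y: np.ndarray) -> float:
    return float(-np.log(np.clip(probs[np.arange(len(y)), y], 1e-12, None)).mean())


def _val_metric(model: "TrainedQAModel", x: np.ndarray, y: np.ndarray) -> dict:
    from . import metrics as m

    scores, hard = _forward_scores(model, x)
    if model.config.head == "levels3":
        counts = m.ovr_confusion(y, hard)
        bas = []
        for cls in np.unique(y):
            try:
                bas.append(m.balanced_accuracy(counts[int(cls)]))
            except ValueError:
                pass
        ba = float(np.mean(bas)) if bas else 0.0
        return {"val_metric": ba, "higher_is_better": True, "val_ba": ba}
    pred_dsc = hard / 100.0
    true_dsc = y / 100.0
    mae = float(np.abs(pred_dsc - true_dsc).mean())
    return {"val_metric": mae, "higher_is_better": False, "val_mae": mae}


def _forward_scores(model: "TrainedQAModel", x: np.ndarray,
                    batch: int = 64) -> tuple[np.ndarray, np.ndarray]:
    scores = []
    for k in range(0, len(x), batch):
        logits = model.net.forward(x[k:k + batch], training=False)
        scores.append(_softmax(logits))
    s = np.concatenate(scores) if scores else np.zeros((0, model.config.n_classes))
    return s, s.argmax(axis=1)


def train(model: TrainedQAModel, data: dict, config: ClassifierConfig | None = None,
          progress=None) -> TrainedQAModel:
    """Train the classifier, returning the best-on-validation checkpoint.

    ``data`` is the output of :func:`prepare_inputs`.  Minimizes softmax
    cross-entropy with SGD (momentum + weight decay) under the poly
    learning-rate schedule; the validation metric (mean one-vs-rest
    balanced accuracy for the 3-level head, MAE for the 101-class head) is
    logged every ``eval_interval`` iterations and the best checkpoint is
    kept.  Minority-class oversampling (on quality levels) is applied
    before the on-the-fly augmentation.  Reproducible under a fixed seed.
    """
    cfg = config or model.config
    x_tr, x_val = data["train"]["x"], data["val"]["x"]
    if len(x_tr) == 0 or len(x_val) == 0:
        raise ValueError("train and validation splits must be nonempty")
    label_key = "level" if cfg.head == "levels3" else "dsc_class"
    y_tr = data["train"][label_key]
    y_val = data["val"][label_key]

    idx = np.arange(len(x_tr))
    if cfg.oversample:
        # balance on the 3-level grouping for both heads: the 101-class
        # head has too few samples per class for per-class balancing
        idx = np.asarray(oversample_minority(idx, data["train"]["level"], seed=cfg.seed))

    counts = np.bincount(data["train"]["level"], minlength=3)
    model.class_priors = counts / counts.sum()

    rng = np.random.default_rng([cfg.seed, 19])
    velocity = [np.zeros_like(a) for a in model.net.state_arrays()]
    best_arrays = [a.copy() for a in model.net.state_arrays()]
    best_metric, higher_better = None, True
    history = model.training_history

    for it in range(cfg.max_iterations):
        lr = cfg.base_lr * (1.0 - it / cfg.max_iterations) ** cfg.power
        take = rng.choice(len(idx), size=min(cfg.batch_size, len(idx)), replace=False)
        batch_idx = idx[take]
        xb = np.stack([
            augment(x_tr[i], rng, cfg.flip_lr, cfg.random_crop,
                    cfg.crop_fraction, cfg.rotation_range_deg)
            for i in batch_idx
        ])
        yb = y_tr[batch_idx]

        logits = model.net.forward(xb, training=True)
        probs = _softmax(logits)
        loss = _cross_entropy(probs, yb)
        dlogits = probs.copy()
        dlogits[np.arange(len(yb)), yb] -= 1.0
        model.net.backward(dlogits / len(yb))

        for k, (layer, name, arr, gname) in enumerate(model.net.parameters()):
            g = getattr(layer, gname) + cfg.weight_decay * arr
            velocity[k] = cfg.momentum * velocity[k] - lr * g
            setattr(layer, name, arr + velocity[k])

        entry = {"iteration": it, "loss": loss, "lr": lr}
        if (it + 1) % cfg.eval_interval == 0 or it == cfg.max_iterations - 1:
            vm = _val_metric(model, x_val, y_val)
            higher_better = vm.pop("higher_is_better")
            entry.update(vm)
            metric = entry["val_metric"]
            if (best_metric is None
                    or (higher_better and metric > best_metric)
                    or (not higher_better and metric < best_metric)):
                best_metric = metric
                best_arrays = [a.copy() for a in model.net.state_arrays()]
            if progress is not None:
                progress(f"iter {it + 1}/{cfg.max_iterations} loss {loss:.3f} "
                         f"val {metric:.3f}")
        history.append(entry)

    model.net.load_arrays(best_arrays)
    return model


def predict(model: TrainedQAModel, x: np.ndarray) -> dict:
    """Score slices with a trained model.

    Returns softmax ``scores``, the ``hard`` argmax class (ties break to
    the lower index) and, for the 101-class head, ``pred_dsc = class/100``.
    """
    x = np.asarray(x, dtype=np.float32)
    if x.ndim != 4 or x.shape[1] != len(model.config.channel_set):
        raise ValueError(
            f"expected (N, {len(model.config.channel_set)}, H, W) input for "
            f"channels {model.config.channel_set}, got shape {x.shape}"
        )
    scores, hard = _forward_scores(model, x)
    out = {"scores": scores, "hard": hard}
    if model.config.head == "dsc101":
        out["pred_dsc"] = hard / 100.0
    return out
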