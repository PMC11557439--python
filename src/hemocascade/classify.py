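"""Slice-level hemorrhage filtering and mask-guided subtype classification.

Two classifiers live here.  The binary filter screens slices before
segmentation so hemorrhage-free slices never reach the heavier models.
The multi-label subtype classifier consumes a :class:`FusionInput`: the
full slice with the predicted mask superimposed as a second channel
(global view) and the ROI crop with its mask crop (local view).  Each
view runs through its own convolutional backbone ending in global
pooling (concatenated spatial mean and max per channel); the pooled
vectors of the two views are concatenated and a single linear layer
maps them to five sigmoid outputs (EDH, IPH, IVH, SAH, SDH).
Training uses focal loss, which down-weights easy examples — most
slice/label pairs are negative.

A global-only ablation (one backbone, no local branch) is provided so
the value of the local view can be measured on the same split.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np

from . import nn
from .image_io import LabelMask, SubtypeLabels
from .roi import ROIBox, crop_and_resize

_N_LABELS = 5


@dataclass
class ClsTrainConfig:
    backbone: str = "tiny"
    task: str = "binary"  # 'binary' (cross-entropy) or 'multilabel' (focal)
    lr: float = 1e-4
    epochs: int = 100
    batch_size: int = 8
    focal_gamma: float = 2.0
    focal_alpha: float = 0.25
    seed: int = 0

    def __post_init__(self):
        if self.backbone not in ("tiny", "resnet50", "efficientnet_b6"):
            raise ValueError(f"unknown backbone {self.backbone!r}")
        if self.backbone != "tiny":
            raise NotImplementedError(
                "only the tiny backbone ships with this build; "
                "resnet50/efficientnet_b6 are config placeholders"
            )
        if self.task not in ("binary", "multilabel"):
            raise ValueError("task must be 'binary' or 'multilabel'")
        if self.lr <= 0:
            raise ValueError("lr must be positive")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.focal_gamma < 0:
            raise ValueError("focal_gamma must be >= 0")
        if not 0 < self.focal_alpha <= 1:
            raise ValueError("focal_alpha must be in (0, 1]")


@dataclass
class FusionInput:
    """Two spatially aligned 2-channel views: (slice, mask) stacks."""

    global_view: np.ndarray  # (2, H, W)
    local_view: np.ndarray  # (2, H', W')

    def __post_init__(self):
        for v in (self.global_view, self.local_view):
            if v.ndim != 3 or v.shape[0] != 2:
                raise ValueError("views must be 2-channel (2, H, W) stacks")


def build_fusion_input(
    slice_: np.ndarray,
    pred_mask,
    roi: Optional[ROIBox],
    local_side: Optional[int] = None,
) -> FusionInput:
    """Superimpose the predicted mask on slice and ROI crop.

    When the cascade found nothing (``roi is None``) the local view
    degenerates to a copy of the global view.
    """
    slice_ = np.asarray(slice_, dtype=np.float32)
    mask = pred_mask.binary() if isinstance(pred_mask, LabelMask) else np.asarray(pred_mask)
    mask = (mask > 0).astype(np.float32)
    if slice_.shape != mask.shape:
        raise ValueError("slice and mask must be aligned")
    global_view = np.stack([slice_, mask])
    if roi is None:
        return FusionInput(global_view=global_view, local_view=global_view.copy())
    side = local_side if local_side is not None else slice_.shape[0]
    local_view = np.stack(
        [
            crop_and_resize(slice_, roi, side, is_mask=False),
            crop_and_resize(mask.astype(np.uint8), roi, side, is_mask=True).astype(
                np.float32
            ),
        ]
    )
    return FusionInput(global_view=global_view, local_view=local_view)


def focal_loss(
    probs: np.ndarray,
    targets: np.ndarray,
    gamma: float = 2.0,
    alpha: float = 0.25,
) -> float:
    """Mean of -alpha (1-p_t)^gamma log(p_t) over labels.

    With gamma=0, alpha=1 this is exactly binary cross-entropy.
    """
    p = np.asarray(probs, dtype=np.float64)
    t = np.asarray(targets, dtype=np.float64)
    if p.shape != t.shape:
        raise ValueError("probs and targets must have equal shape")
    if p.min() < 0 or p.max() > 1:
        raise ValueError("probs must lie in [0, 1]")
    pt = np.clip(np.where(t > 0.5, p, 1.0 - p), 1e-7, 1.0)
    return float(np.mean(-alpha * (1.0 - pt) ** gamma * np.log(pt)))


def _focal_grad_logits(p, t, gamma, alpha):
    """d(focal)/d(logit) with p = sigmoid(logit); vectorized, stable."""
    pt = np.clip(np.where(t > 0.5, p, 1.0 - p), 1e-7, 1.0 - 1e-7)
    one_m = 1.0 - pt
    dl_dpt = -alpha * (-gamma * one_m ** (gamma - 1.0) * np.log(pt) + one_m**gamma / pt)
    sign = np.where(t > 0.5, 1.0, -1.0)
    return dl_dpt * sign * pt * (1.0 - pt) / p.size


def _bce_grad_logits(p, t):
    return (p - t) / p.size


FEAT_WIDTH = 64  # 32 avg-pooled + 32 max-pooled channels


class _TinyBackbone:
    """conv8-pool-conv16-pool-conv32, then global avg+max pooling.

    Instance-normalized convolutions keep small-batch CPU training well
    conditioned; the pooled descriptor concatenates the spatial mean
    (extent-sensitive) and the spatial max (presence-sensitive) of each
    channel, 64-d per view.
    """

    def __init__(self, c_in: int, rng: np.random.Generator):
        self.c1 = nn.Conv2d(c_in, 8, 3, rng)
        self.c2 = nn.Conv2d(8, 16, 3, rng)
        self.c3 = nn.Conv2d(16, 32, 3, rng)
        self.n1, self.n2, self.n3 = nn.InstanceNorm(8), nn.InstanceNorm(16), nn.InstanceNorm(32)
        self.r1, self.r2, self.r3 = nn.ReLU(), nn.ReLU(), nn.ReLU()
        self.p1, self.p2 = nn.MaxPool2(), nn.MaxPool2()
        self.gap = nn.GlobalAvgPool()
        self.gmp = nn.GlobalMaxPool()

    @property
    def layers(self):
        return [self.c1, self.n1, self.c2, self.n2, self.c3, self.n3]

    def forward(self, x):
        h = self.p1.forward(self.r1.forward(self.n1.forward(self.c1.forward(x))))
        h = self.p2.forward(self.r2.forward(self.n2.forward(self.c2.forward(h))))
        h = self.r3.forward(self.n3.forward(self.c3.forward(h)))
        return np.concatenate([self.gap.forward(h), self.gmp.forward(h)], axis=1)

    def backward(self, g):
        g3 = self.gap.backward(g[:, :32]) + self.gmp.backward(g[:, 32:])
        g = self.c3.backward(self.n3.backward(self.r3.backward(g3)))
        g = self.c2.backward(self.n2.backward(self.r2.backward(self.p2.backward(g))))
        return self.c1.backward(self.n1.backward(self.r1.backward(self.p1.backward(g))))


class _ClsCore:
    """Shared train/inference plumbing for the three classifier heads."""

    def __init__(self, backbones, head, input_side, cfg):
        self.backbones = backbones
        self.head = head
        self.input_side = input_side
        self.cfg = cfg
        self.loss_history: List[float] = []

    @property
    def layers(self):
        out = []
        for b in self.backbones:
            out.extend(b.layers)
        out.append(self.head)
        return out

    def _forward(self, views):  # views: list of (N,C,H,W), one per backbone
        feats = [b.forward(v) for b, v in zip(self.backbones, views)]
        self._split = [f.shape[1] for f in feats]
        return self.head.forward(np.concatenate(feats, axis=1))

    def _backward(self, g):
        g = self.head.backward(g)
        ofs = 0
        for b, width in zip(self.backbones, self._split):
            b.backward(g[:, ofs : ofs + width])
            ofs += width

    def logits(self, views):
        return self._forward([np.asarray(v, dtype=np.float32) for v in views])

    def save(self, path) -> Path:
        path = Path(path)
        extra = {
            "input_side": self.input_side,
            "seed": self.cfg.seed,
            "loss_history": np.asarray(self.loss_history, dtype=np.float64),
        }
        path.write_bytes(nn.save_params(self.layers, extra=extra))
        return path

    def _load_into(self, path):
        extra = nn.load_params(self.layers, Path(path).read_bytes())
        self.input_side = int(extra["input_side"])
        self.loss_history = list(extra["loss_history"])
        return self


class BinaryFilterModel(_ClsCore):
    """Slice-level hemorrhage / no-hemorrhage gate."""

    def __init__(self, input_side: int, cfg: ClsTrainConfig):
        rng = np.random.default_rng(cfg.seed)
        super().__init__([_TinyBackbone(1, rng)], nn.Linear(FEAT_WIDTH, 1, rng), input_side, cfg)

    def predict_proba(self, slice_: np.ndarray) -> float:
        x = np.asarray(slice_, dtype=np.float32)[None, None]
        return float(nn.sigmoid(self.logits([x]))[0, 0])

    def predict(self, slice_: np.ndarray, threshold: float = 0.5) -> bool:
        return self.predict_proba(slice_) >= threshold

    @staticmethod
    def load(path) -> "BinaryFilterModel":
        model = BinaryFilterModel(1, ClsTrainConfig(task="binary", epochs=1))
        model._load_into(path)
        return model


def train_binary_filter(
    data: Sequence[Tuple[np.ndarray, bool]], cfg: ClsTrainConfig
) -> BinaryFilterModel:
    """Train the hemorrhage gate with binary cross-entropy."""
    data = list(data)
    if not data:
        raise ValueError("empty training dataset")
    ys = np.array([float(y) for _, y in data], dtype=np.float64)
    if ys.min() == ys.max():
        raise ValueError("binary filter training needs both classes present")
    xs = np.stack([np.asarray(x, dtype=np.float32) for x, _ in data])[:, None]

    rng = np.random.default_rng(cfg.seed)
    model = BinaryFilterModel(xs.shape[-1], cfg)
    opt = nn.Adam(model.layers, lr=cfg.lr)
    n = len(data)
    for epoch in range(cfg.epochs):
        lr = nn.cosine_lr(cfg.lr, epoch, cfg.epochs)
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            z = model._forward([xs[idx]])
            p = nn.sigmoid(z.astype(np.float64))[:, 0]
            t = ys[idx]
            pt = np.clip(np.where(t > 0.5, p, 1 - p), 1e-7, 1.0)
            epoch_loss += float(-np.log(pt).mean()) * len(idx)
            model._backward(_bce_grad_logits(p, t)[:, None].astype(np.float32))
            opt.step(lr=lr)
        model.loss_history.append(epoch_loss / n)
    return model


class FusionModel(_ClsCore):
    """Global + local dual-backbone multi-label subtype classifier."""

    def __init__(self, input_side: int, cfg: ClsTrainConfig, global_only: bool = False):
        rng = np.random.default_rng(cfg.seed)
        self.global_only = global_only
        backbones = [_TinyBackbone(2, rng)]
        width = FEAT_WIDTH
        if not global_only:
            backbones.append(_TinyBackbone(2, rng))
            width = 2 * FEAT_WIDTH
        super().__init__(backbones, nn.Linear(width, _N_LABELS, rng), input_side, cfg)

    def _views(self, batch: Sequence[FusionInput]):
        g = np.stack([fi.global_view for fi in batch]).astype(np.float32)
        if self.global_only:
            return [g]
        return [g, np.stack([fi.local_view for fi in batch]).astype(np.float32)]

    def predict_proba(self, fusion_input: FusionInput) -> np.ndarray:
        return nn.sigmoid(self.logits(self._views([fusion_input])))[0]

    @staticmethod
    def load(path, global_only: bool = False) -> "FusionModel":
        model = FusionModel(1, ClsTrainConfig(task="multilabel", epochs=1), global_only)
        model._load_into(path)
        return model


def train_multilabel(
    data: Sequence[Tuple[FusionInput, SubtypeLabels]],
    cfg: ClsTrainConfig,
    global_only: bool = False,
) -> FusionModel:
    """Train the subtype classifier (or its global-only ablation)."""
    data = list(data)
    if not data:
        raise ValueError("empty training dataset")
    ys = np.stack([lab.to_array().astype(np.float64) for _, lab in data])
    side = data[0][0].global_view.shape[-1]

    rng = np.random.default_rng(cfg.seed)
    model = FusionModel(side, cfg, global_only=global_only)
    opt = nn.Adam(model.layers, lr=cfg.lr)
    inputs = [fi for fi, _ in data]
    n = len(data)
    for epoch in range(cfg.epochs):
        lr = nn.cosine_lr(cfg.lr, epoch, cfg.epochs)
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            views = model._views([inputs[i] for i in idx])
            z = model.logits(views)
            p = nn.sigmoid(z.astype(np.float64))
            t = ys[idx]
            epoch_loss += focal_loss(p, t, cfg.focal_gamma, cfg.focal_alpha) * len(idx)
            g = _focal_grad_logits(p, t, cfg.focal_gamma, cfg.focal_alpha)
            model._backward(g.astype(np.float32))
            opt.step(lr=lr)
        model.loss_history.append(epoch_loss / n)
    return model


def predict_subtypes(
    model: FusionModel, fusion_input: FusionInput, threshold: float = 0.5
) -> Tuple[SubtypeLabels, np.ndarray]:
    """Per-label sigmoid probabilities thresholded into a label vector."""
    probs = model.predict_proba(fusion_input)
    return SubtypeLabels.from_array(probs >= threshold), probs
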