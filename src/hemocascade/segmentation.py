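"""Two-stage coarse-to-fine hematoma segmentation with vote fusion.

Stage I segments the full slice to localize hemorrhage coarsely; its
binary map defines a margin-grown ROI whose crop — blown back up to the
working resolution — is segmented finely by Stage II.  Stage II is
trained on ground-truth-derived ROI crops; at inference the ROI comes
from Stage I.  The two probability maps are combined by a voting rule
(pixel-wise mean by default, union/intersection available) and
thresholded into the final mask.

Both stages share one encoder-decoder architecture.  The default
``tiny`` backbone is a 3-level UNet (~30k parameters) sized for CPU
training at 64 px; training uses Dice loss, Adam at 1e-4 and a
cosine-annealing schedule.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage

from . import nn
from .image_io import LabelMask
from .roi import ROIBox, compute_roi, crop_and_resize, backproject

DICE_EPS = 1.0  # smoothing keeps empty-mask batches finite


@dataclass
class SegTrainConfig:
    architecture: str = "unet"
    encoder: str = "tiny"
    stage: str = "I"
    lr: float = 1e-4
    epochs: int = 500
    batch_size: int = 8
    seed: int = 0

    def __post_init__(self):
        if self.architecture not in ("unet", "deeplabv3plus"):
            raise ValueError(f"unknown architecture {self.architecture!r}")
        if self.encoder not in ("tiny", "resnet50", "efficientnet_b6"):
            raise ValueError(f"unknown encoder {self.encoder!r}")
        if self.stage not in ("I", "II"):
            raise ValueError("stage must be 'I' or 'II'")
        if self.lr <= 0:
            raise ValueError("lr must be positive")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.encoder != "tiny" or self.architecture != "unet":
            raise NotImplementedError(
                "only the tiny UNet backbone ships with this build; "
                "resnet50/efficientnet_b6 and deeplabv3plus are config "
                "placeholders for GPU-scale runs"
            )


@dataclass
class AugmentPolicy:
    """Joint image/mask augmentation, each transform applied at 50%.

    Ranges follow the training recipe: flips, rotation +-45 deg, zoom
    80-120%, pan +-20% of the side, shear 0-10%.
    """

    p_apply: float = 0.5
    rotation_deg: float = 45.0
    zoom: Tuple[float, float] = (0.8, 1.2)
    translate_frac: float = 0.2
    shear_frac: Tuple[float, float] = (0.0, 0.1)
    flips: bool = True


def draw_augment_params(policy: AugmentPolicy, rng: np.random.Generator) -> dict:
    """Sample one augmentation configuration (fixed draw order)."""
    p = policy.p_apply
    return {
        "hflip": policy.flips and rng.random() < p,
        "vflip": policy.flips and rng.random() < p,
        "rot_deg": float(rng.uniform(-policy.rotation_deg, policy.rotation_deg))
        if rng.random() < p
        else 0.0,
        "zoom": float(rng.uniform(*policy.zoom)) if rng.random() < p else 1.0,
        "shear": float(rng.uniform(*policy.shear_frac)) if rng.random() < p else 0.0,
        "translate": tuple(rng.uniform(-policy.translate_frac, policy.translate_frac, 2))
        if rng.random() < p
        else (0.0, 0.0),
    }


def _apply_params(image: np.ndarray, mask: np.ndarray, params: dict):
    img, msk = image, mask
    if params["hflip"]:
        img, msk = img[:, ::-1], msk[:, ::-1]
    if params["vflip"]:
        img, msk = img[::-1, :], msk[::-1, :]
    theta = np.deg2rad(params["rot_deg"])
    z = params["zoom"]
    sh = params["shear"]
    ty, tx = (np.asarray(params["translate"]) * image.shape[0])
    fwd = (
        np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        @ np.array([[z, 0.0], [0.0, z]])
        @ np.array([[1.0, sh], [0.0, 1.0]])
    )
    if np.allclose(fwd, np.eye(2)) and tx == 0 and ty == 0:
        return np.ascontiguousarray(img), np.ascontiguousarray(msk)
    inv = np.linalg.inv(fwd)
    c = (np.asarray(image.shape, dtype=float) - 1) / 2.0
    offset = c - inv @ (c + np.array([ty, tx]))
    img = ndimage.affine_transform(
        np.ascontiguousarray(img, dtype=np.float32), inv, offset=offset, order=1, cval=0.0
    )
    msk = ndimage.affine_transform(
        np.ascontiguousarray(msk), inv, offset=offset, order=0, cval=0
    )
    return img, msk


def augment(
    image: np.ndarray,
    mask,
    policy: AugmentPolicy,
    seed: int | np.random.Generator = 0,
):
    """Apply one random joint augmentation to a slice and its mask."""
    mask_arr = mask.pixels if isinstance(mask, LabelMask) else np.asarray(mask)
    image = np.asarray(image)
    if image.shape != mask_arr.shape:
        raise ValueError("image and mask shapes must match")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    img, msk = _apply_params(image, mask_arr, draw_augment_params(policy, rng))
    if isinstance(mask, LabelMask):
        msk = LabelMask(msk.astype(mask.pixels.dtype), encoding=mask.encoding)
    return img, msk


def dice_loss(probs: np.ndarray, target, eps: float = DICE_EPS) -> float:
    """1 - (2 sum(p t) + eps) / (sum p + sum t + eps), in [0, 1]."""
    probs = np.asarray(probs, dtype=np.float64)
    t = target.binary() if isinstance(target, LabelMask) else np.asarray(target)
    t = (t > 0).astype(np.float64)
    if probs.shape != t.shape:
        raise ValueError("probs and target shapes must match")
    if probs.min() < 0 or probs.max() > 1:
        raise ValueError("probs must lie in [0, 1]")
    inter = float((probs * t).sum())
    return 1.0 - (2.0 * inter + eps) / (float(probs.sum()) + float(t.sum()) + eps)


def _batch_dice_loss_and_grad(p: np.ndarray, t: np.ndarray, eps: float = DICE_EPS):
    """Mean per-image soft-Dice loss and its gradient wrt probabilities."""
    n = p.shape[0]
    a = (p * t).sum(axis=(1, 2))  # intersection
    b = p.sum(axis=(1, 2)) + t.sum(axis=(1, 2))
    loss = 1.0 - (2.0 * a + eps) / (b + eps)
    # d/dp_i = -(2 t_i (b+eps) - (2a+eps)) / (b+eps)^2
    denom = (b + eps) ** 2
    grad = -(2.0 * t * (b + eps)[:, None, None] - (2.0 * a + eps)[:, None, None]) / denom[
        :, None, None
    ]
    return float(loss.mean()), grad / n


class _ConvBlock:
    """conv3x3 -> instance norm -> ReLU."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        self.conv = nn.Conv2d(c_in, c_out, 3, rng)
        self.norm = nn.InstanceNorm(c_out)
        self.act = nn.ReLU()

    @property
    def layers(self):
        return [self.conv, self.norm]

    def forward(self, x):
        return self.act.forward(self.norm.forward(self.conv.forward(x)))

    def backward(self, g):
        return self.conv.backward(self.norm.backward(self.act.backward(g)))


class _TinyUNet:
    """3-level UNet: 8/16/32 channels, instance norm, skip connections."""

    def __init__(self, rng: np.random.Generator):
        B = _ConvBlock
        self.e1a, self.e1b = B(1, 8, rng), B(8, 8, rng)
        self.e2a, self.e2b = B(8, 16, rng), B(16, 16, rng)
        self.ba, self.bb = B(16, 32, rng), B(32, 32, rng)
        self.d2a, self.d2b = B(48, 16, rng), B(16, 16, rng)
        self.d1a, self.d1b = B(24, 8, rng), B(8, 8, rng)
        self.head = nn.Conv2d(8, 1, 1, rng)
        self.p1, self.p2 = nn.MaxPool2(), nn.MaxPool2()
        self.u2, self.u1 = nn.Upsample2(), nn.Upsample2()

    @property
    def blocks(self):
        return [
            self.e1a, self.e1b, self.e2a, self.e2b, self.ba, self.bb,
            self.d2a, self.d2b, self.d1a, self.d1b,
        ]

    @property
    def layers(self):
        out = []
        for b in self.blocks:
            out.extend(b.layers)
        out.append(self.head)
        return out

    def forward(self, x: np.ndarray) -> np.ndarray:
        e1 = self.e1b.forward(self.e1a.forward(x))
        e2 = self.e2b.forward(self.e2a.forward(self.p1.forward(e1)))
        b = self.bb.forward(self.ba.forward(self.p2.forward(e2)))
        u2 = np.concatenate([self.u2.forward(b), e2], axis=1)
        d2 = self.d2b.forward(self.d2a.forward(u2))
        u1 = np.concatenate([self.u1.forward(d2), e1], axis=1)
        d1 = self.d1b.forward(self.d1a.forward(u1))
        self._c2 = b.shape[1]
        self._c1 = d2.shape[1]
        return self.head.forward(d1)[:, 0]  # logits (N,H,W)

    def backward(self, gz: np.ndarray):
        g = self.head.backward(gz[:, None])
        g = self.d1a.backward(self.d1b.backward(g))
        g_u1, g_e1_skip = g[:, : self._c1], g[:, self._c1 :]
        g = self.u1.backward(g_u1)
        g = self.d2a.backward(self.d2b.backward(g))
        g_u2, g_e2_skip = g[:, : self._c2], g[:, self._c2 :]
        g = self.u2.backward(g_u2)
        g = self.ba.backward(self.bb.backward(g))
        g = self.p2.backward(g) + g_e2_skip
        g = self.e2a.backward(self.e2b.backward(g))
        g = self.p1.backward(g) + g_e1_skip
        self.e1a.backward(self.e1b.backward(g))


class SegModel:
    """Trained segmentation stage: deterministic per-pixel probabilities."""

    def __init__(self, net: _TinyUNet, input_side: int, cfg: SegTrainConfig):
        self.net = net
        self.input_side = input_side
        self.cfg = cfg
        self.loss_history: List[float] = []

    def predict(self, slice_: np.ndarray) -> np.ndarray:
        return self.predict_batch(np.asarray(slice_)[None])[0]

    def predict_batch(self, slices: np.ndarray) -> np.ndarray:
        slices = np.asarray(slices, dtype=np.float32)
        if slices.shape[1:] != (self.input_side, self.input_side):
            raise ValueError(
                f"expected {self.input_side}x{self.input_side} slices, got {slices.shape[1:]}"
            )
        return nn.sigmoid(self.net.forward(slices[:, None]))

    def save(self, path) -> Path:
        path = Path(path)
        blob = nn.save_params(
            self.net.layers,
            extra={
                "input_side": self.input_side,
                "seed": self.cfg.seed,
                "stage": 0 if self.cfg.stage == "I" else 1,
                "loss_history": np.asarray(self.loss_history, dtype=np.float64),
            },
        )
        path.write_bytes(blob)
        return path

    @staticmethod
    def load(path) -> "SegModel":
        blob = Path(path).read_bytes()
        net = _TinyUNet(np.random.default_rng(0))
        extra = nn.load_params(net.layers, blob)
        cfg = SegTrainConfig(
            stage="I" if int(extra["stage"]) == 0 else "II", seed=int(extra["seed"]),
            epochs=1,
        )
        model = SegModel(net, int(extra["input_side"]), cfg)
        model.loss_history = list(extra["loss_history"])
        return model


def _as_arrays(data) -> Tuple[np.ndarray, np.ndarray]:
    xs, ts = [], []
    for img, msk in data:
        xs.append(np.asarray(img, dtype=np.float32))
        m = msk.binary() if isinstance(msk, LabelMask) else (np.asarray(msk) > 0)
        ts.append(m.astype(np.float32))
    return np.stack(xs), np.stack(ts)


def train_stage(
    data: Sequence,
    cfg: SegTrainConfig,
    augment_policy: Optional[AugmentPolicy] = None,
) -> SegModel:
    """Train one segmentation stage on (slice, mask) pairs.

    Stage I expects full slices and full masks; Stage II expects
    ground-truth ROI crops (see :func:`make_stage2_dataset`).
    """
    data = list(data)
    if not data:
        raise ValueError("empty training dataset")
    xs, ts = _as_arrays(data)
    side = xs.shape[1]
    rng = np.random.default_rng(cfg.seed)
    net = _TinyUNet(rng)
    opt = nn.Adam(net.layers, lr=cfg.lr)
    model = SegModel(net, side, cfg)

    n = len(data)
    for epoch in range(cfg.epochs):
        lr = nn.cosine_lr(cfg.lr, epoch, cfg.epochs)
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            xb, tb = xs[idx], ts[idx]
            if augment_policy is not None:
                xb = xb.copy()
                tb = tb.copy()
                for j in range(len(idx)):
                    xi, ti = _apply_params(
                        xb[j], tb[j], draw_augment_params(augment_policy, rng)
                    )
                    xb[j], tb[j] = xi, ti
            z = net.forward(xb[:, None])
            p = nn.sigmoid(z)
            loss, gp = _batch_dice_loss_and_grad(
                p.astype(np.float64), tb.astype(np.float64)
            )
            net.backward((gp * p * (1.0 - p)).astype(np.float32))
            opt.step(lr=lr)
            epoch_loss += loss * len(idx)
        model.loss_history.append(epoch_loss / n)
    return model


def make_stage2_dataset(
    slices: Sequence[np.ndarray],
    masks: Sequence[LabelMask],
    margin: int = 20,
    out_side: Optional[int] = None,
) -> List[Tuple[np.ndarray, np.ndarray]]:
    """Build Stage II training pairs from ground-truth ROIs.

    Slices with empty masks are skipped — Stage II only ever sees
    hemorrhage-bearing crops.
    """
    out = []
    for img, msk in zip(slices, masks):
        if msk.is_empty():
            continue
        roi = compute_roi(msk.binary(), margin=margin)
        side = out_side if out_side is not None else roi.source_side
        out.append(
            (
                crop_and_resize(img, roi, side, is_mask=False),
                crop_and_resize(msk.binary(), roi, side, is_mask=True),
            )
        )
    return out


def vote(
    probs_a: np.ndarray,
    probs_b: np.ndarray,
    threshold: float = 0.5,
    strategy: str = "mean",
) -> LabelMask:
    """Fuse two probability maps into the final binary mask."""
    a = np.asarray(probs_a, dtype=np.float64)
    b = np.asarray(probs_b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError("probability maps must share a shape")
    for m in (a, b):
        if m.min() < 0 or m.max() > 1:
            raise ValueError("probabilities must lie in [0, 1]")
    if strategy == "mean":
        out = (a + b) / 2.0 >= threshold
    elif strategy == "union":
        out = (a >= threshold) | (b >= threshold)
    elif strategy == "intersection":
        out = (a >= threshold) & (b >= threshold)
    else:
        raise ValueError(f"unknown voting strategy {strategy!r}")
    return LabelMask(out.astype(np.uint8), encoding="binary")


def cascade_predict(
    stage1: SegModel,
    stage2: SegModel,
    slice_: np.ndarray,
    threshold: float = 0.5,
    margin: int = 20,
    vote_strategy: str = "mean",
) -> Tuple[LabelMask, Optional[ROIBox]]:
    """Full coarse-to-fine prediction for one slice.

    Stage I probabilities are thresholded; if nothing survives, the
    empty mask is returned and Stage II is never invoked.  Otherwise the
    Stage-I-derived ROI crop goes through Stage II, its probabilities
    are back-projected, and the two maps are vote-fused.
    """
    slice_ = np.asarray(slice_, dtype=np.float32)
    p1 = stage1.predict(slice_)
    coarse = p1 >= threshold
    if not coarse.any():
        return LabelMask(np.zeros_like(coarse, dtype=np.uint8)), None
    roi = compute_roi(coarse.astype(np.uint8), margin=margin).with_resized_side(
        stage2.input_side
    )
    crop = crop_and_resize(slice_, roi, stage2.input_side, is_mask=False)
    p2 = backproject(stage2.predict(crop), roi)
    return vote(p1, p2, threshold=threshold, strategy=vote_strategy), roi
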