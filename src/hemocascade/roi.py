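"""ROI geometry: bounding square, margin growth, crop/resize, back-projection.

The coarse-to-fine cascade localizes all lesion pixels of a slice with a
single axis-aligned box: the tight bounding box of the foreground is
expanded to a square (so the fine-stage crop keeps the lesion aspect
ratio), grown by a fixed margin — surrounding tissue context helps the
fine segmenter — and clamped to the slice bounds.  The same box is later
used to paste fine-stage predictions back into original coordinates.

All boxes use row-major, 0-based, half-open ``[min, max)`` coordinates.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

from .image_io import resize_to_standard

DEFAULT_MARGIN = 20


class EmptyMaskError(ValueError):
    """compute_roi was handed a mask with no foreground pixels."""


@dataclass(frozen=True)
class ROIBox:
    """Axis-aligned crop window in original-slice coordinates.

    ``row_min``..``col_max`` are the clamped, usable extents.  The
    pre-clamp square extents are kept so provenance logs can tell when a
    window was cut by the image border (the clamped box may then be
    rectangular).  ``resized_side`` records the side length the crop was
    resized to, which back-projection needs to undo the resize.
    """

    row_min: int
    row_max: int
    col_min: int
    col_max: int
    source_side: int
    resized_side: Optional[int] = None
    # pre-clamp extents of the margin-grown square
    row_min_unclamped: Optional[int] = None
    row_max_unclamped: Optional[int] = None
    col_min_unclamped: Optional[int] = None
    col_max_unclamped: Optional[int] = None

    def __post_init__(self):
        if not (0 <= self.row_min < self.row_max <= self.source_side):
            raise ValueError(f"invalid row extent [{self.row_min},{self.row_max})")
        if not (0 <= self.col_min < self.col_max <= self.source_side):
            raise ValueError(f"invalid col extent [{self.col_min},{self.col_max})")

    @property
    def height(self) -> int:
        return self.row_max - self.row_min

    @property
    def width(self) -> int:
        return self.col_max - self.col_min

    @property
    def was_clamped(self) -> bool:
        return (self.row_min, self.row_max, self.col_min, self.col_max) != (
            self.row_min_unclamped,
            self.row_max_unclamped,
            self.col_min_unclamped,
            self.col_max_unclamped,
        )

    def with_resized_side(self, side: int) -> "ROIBox":
        return replace(self, resized_side=int(side))

    def to_json(self) -> str:
        return json.dumps(
            {
                "row_min": self.row_min,
                "row_max": self.row_max,
                "col_min": self.col_min,
                "col_max": self.col_max,
                "source_side": self.source_side,
                "resized_side": self.resized_side,
                "row_min_unclamped": self.row_min_unclamped,
                "row_max_unclamped": self.row_max_unclamped,
                "col_min_unclamped": self.col_min_unclamped,
                "col_max_unclamped": self.col_max_unclamped,
            }
        )

    @staticmethod
    def from_json(text: str) -> "ROIBox":
        return ROIBox(**json.loads(text))


def compute_roi(mask, margin: int = DEFAULT_MARGIN) -> ROIBox:
    """Minimal bounding square over all foreground pixels, plus margin.

    Steps: (a) tight bounding box of every foreground pixel; (b) expand
    to a square of side max(height, width) centered on the tight box,
    with any odd leftover pixel assigned to the high-index side; (c)
    grow by ``margin`` on every side; (d) clamp to image bounds.
    """
    pixels = mask.pixels if hasattr(mask, "pixels") else np.asarray(mask)
    if pixels.shape[0] != pixels.shape[1]:
        raise ValueError("compute_roi expects a square slice raster")
    side = pixels.shape[0]
    rows, cols = np.nonzero(pixels)
    if rows.size == 0:
        raise EmptyMaskError("mask has no foreground pixels")
    r0, r1 = int(rows.min()), int(rows.max()) + 1
    c0, c1 = int(cols.min()), int(cols.max()) + 1

    # (b) square expansion, odd pixel to the high-index side
    h, w = r1 - r0, c1 - c0
    s = max(h, w)
    dr, dc = s - h, s - w
    r0s, r1s = r0 - dr // 2, r1 + (dr - dr // 2)
    c0s, c1s = c0 - dc // 2, c1 + (dc - dc // 2)

    # (c) margin growth
    r0m, r1m = r0s - margin, r1s + margin
    c0m, c1m = c0s - margin, c1s + margin

    # (d) clamp
    return ROIBox(
        row_min=max(0, r0m),
        row_max=min(side, r1m),
        col_min=max(0, c0m),
        col_max=min(side, c1m),
        source_side=side,
        row_min_unclamped=r0m,
        row_max_unclamped=r1m,
        col_min_unclamped=c0m,
        col_max_unclamped=c1m,
    )


def crop_and_resize(
    slice_: np.ndarray, roi: ROIBox, out_side: Optional[int] = None, is_mask: bool = False
) -> np.ndarray:
    """Crop the ROI window and resize it to ``out_side`` squared.

    ``out_side`` defaults to the source slice side, i.e. the crop is
    blown back up to the original pixel size.
    """
    slice_ = np.asarray(slice_)
    if slice_.shape[0] < roi.row_max or slice_.shape[1] < roi.col_max:
        raise ValueError("ROI exceeds slice bounds")
    if out_side is None:
        out_side = roi.source_side
    crop = slice_[roi.row_min : roi.row_max, roi.col_min : roi.col_max]
    return resize_to_standard(crop, out_side, is_mask=is_mask)


def backproject(pred: np.ndarray, roi: ROIBox) -> np.ndarray:
    """Paste a resized ROI prediction back into full-slice coordinates.

    The prediction is resized to the ROI's (possibly rectangular,
    clamped) extent — nearest-neighbour for integer masks, bilinear for
    probability rasters — and placed in a zero raster of the source
    slice size.
    """
    pred = np.asarray(pred)
    if roi.resized_side is None:
        raise ValueError("ROI has no resized_side recorded; crop first")
    if pred.shape != (roi.resized_side, roi.resized_side):
        raise ValueError(
            f"prediction shape {pred.shape} != resized_side {roi.resized_side}"
        )
    is_mask = np.issubdtype(pred.dtype, np.integer)
    from skimage.transform import resize as _sk_resize

    patch = _sk_resize(
        pred.astype(np.float32 if not is_mask else pred.dtype),
        (roi.height, roi.width),
        order=0 if is_mask else 1,
        preserve_range=True,
        anti_aliasing=False,
    )
    out = np.zeros(
        (roi.source_side, roi.source_side),
        dtype=pred.dtype if is_mask else np.float32,
    )
    out[roi.row_min : roi.row_max, roi.col_min : roi.col_max] = patch.astype(out.dtype)
    return out
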