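"""Core imaging types and series I/O.

A head-CT study enters the pipeline as a :class:`CTSeries` — an ordered
stack of axial slices with pixel spacing and slice thickness, which the
volumetry step needs to convert voxel counts to millilitres.  Hematoma
annotations ride along as :class:`LabelMask` rasters, either binary
(0 = background, 1 = hemorrhage) or subtype-coded (1–5 for the five ICH
subtypes in fixed alphabetical order EDH, IPH, IVH, SAH, SDH).

NIfTI is the canonical on-disk format for series and mask volumes;
single slices may also live as 8-bit PNGs next to a JSON sidecar
carrying the spacing metadata.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
from PIL import Image
from skimage.transform import resize as _sk_resize

SUBTYPE_NAMES = ("edh", "iph", "ivh", "sah", "sdh")
SUBTYPE_CODES = {name: i + 1 for i, name in enumerate(SUBTYPE_NAMES)}

# brain window used to map Hounsfield units to [0, 1]
BRAIN_WINDOW_CENTER_HU = 40.0
BRAIN_WINDOW_WIDTH_HU = 80.0


class FormatError(ValueError):
    """Raised when on-disk data violates the expected layout."""


@dataclass(frozen=True)
class SubtypeLabels:
    """5-way multi-label hemorrhage subtype vector (order fixed)."""

    edh: bool = False
    iph: bool = False
    ivh: bool = False
    sah: bool = False
    sdh: bool = False

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in SUBTYPE_NAMES], dtype=bool)

    @staticmethod
    def from_array(a: Sequence[bool]) -> "SubtypeLabels":
        a = list(a)
        if len(a) != 5:
            raise ValueError("subtype vector must have exactly 5 entries")
        return SubtypeLabels(**{n: bool(v) for n, v in zip(SUBTYPE_NAMES, a)})

    def any(self) -> bool:
        return any(self.to_array())

    def __or__(self, other: "SubtypeLabels") -> "SubtypeLabels":
        return SubtypeLabels.from_array(self.to_array() | other.to_array())


@dataclass
class LabelMask:
    """Per-pixel hematoma annotation aligned to one slice.

    ``encoding='binary'`` restricts values to {0, 1}; ``'subtype'``
    allows 0–5 where nonzero codes follow :data:`SUBTYPE_CODES`.
    """

    pixels: np.ndarray
    encoding: str = "binary"

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError("mask must be a 2-D raster")
        if not np.issubdtype(self.pixels.dtype, np.integer):
            raise ValueError("mask raster must be integer-typed")
        hi = 1 if self.encoding == "binary" else 5
        if self.encoding not in ("binary", "subtype"):
            raise ValueError(f"unknown encoding {self.encoding!r}")
        vals = np.unique(self.pixels)
        if vals.size and (vals.min() < 0 or vals.max() > hi):
            raise ValueError(
                f"mask values {vals} outside declared {self.encoding} encoding"
            )

    @property
    def shape(self) -> tuple:
        return self.pixels.shape

    def binary(self) -> np.ndarray:
        """Binary hemorrhage view (any nonzero label is foreground)."""
        return (self.pixels > 0).astype(np.uint8)

    def is_empty(self) -> bool:
        return not bool(self.pixels.any())

    def subtype_labels(self) -> SubtypeLabels:
        """Slice-level subtype vector implied by a subtype-coded mask."""
        present = set(np.unique(self.pixels)) - {0}
        return SubtypeLabels.from_array(
            [SUBTYPE_CODES[n] in present for n in SUBTYPE_NAMES]
        )


@dataclass
class CTSeries:
    """Ordered axial slice stack with voxel geometry metadata."""

    patient_id: str
    slices: list  # list of 2-D float rasters in [0, 1]
    pixel_spacing_mm: tuple  # (row, col)
    slice_thickness_mm: float

    def __post_init__(self):
        self.slices = [np.asarray(s, dtype=np.float32) for s in self.slices]
        if not self.slices:
            raise ValueError("series must contain at least one slice")
        shape0 = self.slices[0].shape
        if any(s.shape != shape0 for s in self.slices):
            raise FormatError("all slices in a series must share dimensions")
        r, c = self.pixel_spacing_mm
        if r <= 0 or c <= 0 or self.slice_thickness_mm <= 0:
            raise ValueError("pixel spacing and slice thickness must be positive")

    def __len__(self) -> int:
        return len(self.slices)

    @property
    def slice_shape(self) -> tuple:
        return self.slices[0].shape

    def voxel_volume_mm3(self) -> float:
        r, c = self.pixel_spacing_mm
        return float(r) * float(c) * float(self.slice_thickness_mm)


def _window_to_unit(data: np.ndarray) -> np.ndarray:
    """Rescale intensities to [0,1], brain-windowing HU data first."""
    data = data.astype(np.float32)
    lo_hu = BRAIN_WINDOW_CENTER_HU - BRAIN_WINDOW_WIDTH_HU / 2
    hi_hu = BRAIN_WINDOW_CENTER_HU + BRAIN_WINDOW_WIDTH_HU / 2
    if data.min() < -0.5 or data.max() > 1.5:  # looks like HU, not unit range
        data = np.clip((data - lo_hu) / (hi_hu - lo_hu), 0.0, 1.0)
    else:
        data = np.clip(data, 0.0, 1.0)
    return data


def read_series(path) -> CTSeries:
    """Read a CT series from a NIfTI file or a PNG directory + sidecar.

    Intensities are rescaled to [0, 1]; Hounsfield-valued volumes pass
    through a brain window (center 40 HU, width 80 HU) first.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.is_dir():
        return _read_png_dir(path)
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 2:
        data = data[:, :, None]
    if data.ndim != 3:
        raise FormatError(f"expected a 3-D volume, got shape {data.shape}")
    zooms = img.header.get_zooms()[:3]
    if any(z <= 0 for z in zooms):
        raise ValueError(f"nonpositive voxel spacing in header: {zooms}")
    slices = [_window_to_unit(data[:, :, k]) for k in range(data.shape[2])]
    pid = path.name.split(".")[0]
    return CTSeries(
        patient_id=pid,
        slices=slices,
        pixel_spacing_mm=(float(zooms[0]), float(zooms[1])),
        slice_thickness_mm=float(zooms[2]),
    )


def _read_png_dir(path: Path) -> CTSeries:
    sidecar = path / "meta.json"
    if not sidecar.exists():
        raise FileNotFoundError(f"PNG series directory needs a meta.json sidecar: {path}")
    meta = json.loads(sidecar.read_text())
    pngs = sorted(path.glob("*.png"))
    if not pngs:
        raise FileNotFoundError(f"no PNG slices in {path}")
    rasters = []
    for p in pngs:
        arr = np.asarray(Image.open(p).convert("L"), dtype=np.float32) / 255.0
        rasters.append(arr)
    shapes = {r.shape for r in rasters}
    if len(shapes) > 1:
        raise FormatError(f"inconsistent slice shapes in {path}: {sorted(shapes)}")
    return CTSeries(
        patient_id=str(meta.get("patient_id", path.name)),
        slices=rasters,
        pixel_spacing_mm=tuple(meta["pixel_spacing_mm"]),
        slice_thickness_mm=float(meta["slice_thickness_mm"]),
    )


def _nifti_affine(series: CTSeries) -> np.ndarray:
    r, c = series.pixel_spacing_mm
    return np.diag([r, c, series.slice_thickness_mm, 1.0])


def write_series(series: CTSeries, path) -> Path:
    """Write intensity slices as a float32 NIfTI volume."""
    path = Path(path)
    vol = np.stack(series.slices, axis=2).astype(np.float32)
    img = nib.Nifti1Image(vol, _nifti_affine(series))
    img.header.set_zooms((*series.pixel_spacing_mm, series.slice_thickness_mm))
    nib.save(img, str(path))
    return path


def write_mask_series(masks: Sequence[LabelMask], meta: CTSeries, path) -> Path:
    """Write label masks as an integer NIfTI volume with ``meta``'s geometry."""
    masks = list(masks)
    if not masks:
        raise ValueError("empty mask list")
    if len(masks) != len(meta):
        raise ValueError(
            f"need one mask per slice: {len(masks)} masks vs {len(meta)} slices"
        )
    path = Path(path)
    vol = np.stack([m.pixels for m in masks], axis=2).astype(np.int16)
    img = nib.Nifti1Image(vol, _nifti_affine(meta))
    img.header.set_zooms((*meta.pixel_spacing_mm, meta.slice_thickness_mm))
    nib.save(img, str(path))
    return path


def read_mask_series(path, encoding: str = "binary") -> list:
    """Read an integer NIfTI mask volume back into per-slice LabelMasks."""
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj).astype(np.int64)
    if data.ndim == 2:
        data = data[:, :, None]
    return [LabelMask(data[:, :, k], encoding=encoding) for k in range(data.shape[2])]


def write_slice_png(slice_: np.ndarray, path) -> Path:
    """Write one intensity slice as 8-bit grayscale PNG."""
    path = Path(path)
    arr = np.clip(np.asarray(slice_, dtype=np.float32), 0.0, 1.0)
    Image.fromarray((arr * 255).round().astype(np.uint8), mode="L").save(path)
    return path


def write_mask_png(mask: LabelMask, path) -> Path:
    """Write a label mask as 8-bit PNG with integer labels preserved."""
    path = Path(path)
    Image.fromarray(mask.pixels.astype(np.uint8), mode="L").save(path)
    return path


def read_mask_png(path, encoding: str = "binary") -> LabelMask:
    return LabelMask(
        np.asarray(Image.open(path).convert("L"), dtype=np.int64), encoding=encoding
    )


def resize_to_standard(image: np.ndarray, out_side: int, is_mask: bool) -> np.ndarray:
    """Resize a 2-D raster to out_side x out_side.

    Intensities are interpolated bilinearly; masks use nearest-neighbour
    so labels are never blended.
    """
    image = np.asarray(image)
    if image.ndim != 2 or image.size == 0:
        raise ValueError("image must be a nonempty 2-D raster")
    if out_side < 1:
        raise ValueError("out_side must be >= 1")
    if image.shape == (out_side, out_side):
        return image.copy()
    order = 0 if is_mask else 1
    out = _sk_resize(
        image.astype(np.float32 if not is_mask else image.dtype),
        (out_side, out_side),
        order=order,
        preserve_range=True,
        anti_aliasing=False,
    )
    if is_mask:
        return out.astype(image.dtype)
    return out.astype(np.float32)
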