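"""Radiograph reading and preprocessing.

Loads DICOM/PNG/JPG radiographs into a common working frame: grayscale
intensities in [0, 1], resized to a square side (default 256), CLAHE
contrast enhancement, and a projection-histogram crop of the spine region
of interest.

Coordinate conventions used throughout the package: row-major arrays,
origin at the top-left, 0-based indices, half-open boxes.  "X" in clinical
descriptions of AP radiographs maps to the column index.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import imageio.v3 as iio
from skimage import exposure, filters, transform

__all__ = [
    "RadiographImage",
    "ROIBox",
    "ChannelCountError",
    "EmptyROIError",
    "read_radiograph",
    "to_working_frame",
    "clahe_enhance",
    "denoise",
    "binarize",
    "crop_spine_roi",
    "write_png",
]

# Rec. 709 luminance weights for color inputs
_LUMA = np.array([0.2126, 0.7152, 0.0722])

_DICOM_SUFFIXES = {".dcm", ".dicom", ".dic"}


class ChannelCountError(ValueError):
    """Raw input has more than 3 channels (the dimension filter)."""


class EmptyROIError(ValueError):
    """No projection bin reaches the ROI threshold."""


@dataclass
class RadiographImage:
    """2D grayscale radiograph with provenance.

    pixels : float array in [0, 1], exactly 2 spatial dimensions.
    source_format : 'dicom', 'png', 'jpg' or 'array'.
    original_shape : shape of the raw input before any resizing, so overlay
        coordinates can be mapped back.
    """

    pixels: np.ndarray
    source_format: str = "array"
    original_shape: tuple = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ValueError(f"expected 2D pixels, got shape {self.pixels.shape}")
        if self.pixels.size == 0:
            raise ValueError("empty image")
        lo, hi = float(self.pixels.min()), float(self.pixels.max())
        if lo < -1e-9 or hi > 1 + 1e-9:
            raise ValueError(f"intensities must lie in [0, 1], got [{lo}, {hi}]")
        if self.original_shape is None:
            self.original_shape = self.pixels.shape

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass(frozen=True)
class ROIBox:
    """Half-open pixel box [row_start, row_end) x [col_start, col_end)."""

    row_start: int
    row_end: int
    col_start: int
    col_end: int

    def __post_init__(self) -> None:
        if not (0 <= self.row_start < self.row_end and 0 <= self.col_start < self.col_end):
            raise ValueError(f"invalid ROI box {self}")

    def crop(self, pixels: np.ndarray) -> np.ndarray:
        return pixels[self.row_start : self.row_end, self.col_start : self.col_end]


def _rescale_raw(arr: np.ndarray) -> np.ndarray:
    """Map a raw pixel array to [0, 1] by the maximum of its dtype."""
    if np.issubdtype(arr.dtype, np.integer):
        info = np.iinfo(arr.dtype)
        lo = float(info.min)
        return (arr.astype(float) - lo) / (float(info.max) - lo)
    arr = arr.astype(float)
    return np.clip(arr, 0.0, 1.0)


def _collapse_channels(arr: np.ndarray) -> np.ndarray:
    if arr.ndim == 2:
        return arr
    if arr.ndim == 3:
        nch = arr.shape[2]
        if nch > 3:
            raise ChannelCountError(
                f"input has {nch} channels; at most 3 are accepted"
            )
        if nch == 1:
            return arr[:, :, 0]
        if nch == 2:  # gray + alpha
            return arr[:, :, 0]
        return arr @ _LUMA
    raise ChannelCountError(f"cannot interpret array of shape {arr.shape} as an image")


def read_radiograph(path) -> RadiographImage:
    """Read a DICOM, PNG or JPG file as a grayscale [0, 1] radiograph.

    Multi-channel inputs with <= 3 channels are collapsed by Rec. 709
    luminance weighting; integer bit depths are rescaled by the dtype
    maximum.  More than 3 channels is rejected.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    suffix = path.suffix.lower()
    if suffix in _DICOM_SUFFIXES:
        import pydicom

        ds = pydicom.dcmread(path)
        raw = ds.pixel_array
        fmt = "dicom"
    else:
        try:
            raw = np.asarray(iio.imread(path))
        except Exception as exc:  # unreadable / corrupt file
            raise ValueError(f"cannot read image file {path}: {exc}") from exc
        fmt = "jpg" if suffix in {".jpg", ".jpeg"} else "png"
    gray = _collapse_channels(_rescale_raw(np.asarray(raw)))
    return RadiographImage(
        pixels=gray,
        source_format=fmt,
        original_shape=tuple(np.asarray(raw).shape),
    )


def to_working_frame(img: RadiographImage, side: int = 256) -> RadiographImage:
    """Bilinear resize to side x side; identity if already that size."""
    if side < 16:
        raise ValueError(f"working side must be >= 16, got {side}")
    if img.pixels.shape == (side, side):
        return replace(img, pixels=img.pixels.copy())
    out = transform.resize(
        img.pixels, (side, side), order=1, mode="edge",
        anti_aliasing=False, preserve_range=True,
    )
    return RadiographImage(
        pixels=np.clip(out, 0.0, 1.0),
        source_format=img.source_format,
        original_shape=img.original_shape,
    )


def clahe_enhance(
    img: RadiographImage, clip_limit: float = 0.01, tiles: int = 8
) -> RadiographImage:
    """Contrast-limited adaptive histogram equalization (CLAHE).

    Deterministic for fixed parameters; a constant image passes through
    unchanged (there is no contrast to equalize).
    """
    px = img.pixels
    if px.max() == px.min():
        return replace(img, pixels=px.copy())
    kernel = max(img.height // tiles, 1), max(img.width // tiles, 1)
    out = exposure.equalize_adapthist(px, kernel_size=kernel, clip_limit=clip_limit)
    return replace(img, pixels=out)


def denoise(img: RadiographImage, sigma: float = 1.0) -> RadiographImage:
    """Gaussian smoothing; sigma <= 0 is the identity."""
    if sigma <= 0:
        return replace(img, pixels=img.pixels.copy())
    out = filters.gaussian(img.pixels, sigma=sigma, mode="nearest")
    return replace(img, pixels=np.clip(out, 0.0, 1.0))


def binarize(img: RadiographImage, min_contrast: float = 0.15) -> RadiographImage:
    """Otsu normalization to a two-level image {0, 1}.

    Radiographs are reduced to foreground/background levels ahead of LCM
    segmentation so homogeneous regions are exactly flat and the cumulative
    edge energy concentrates at anatomical boundaries.  A crop whose dynamic
    range is below ``min_contrast`` holds no background to separate (e.g.
    the ROI collapsed onto the spine itself) and is returned all-foreground
    rather than letting Otsu split residual texture.
    """
    px = img.pixels
    if px.max() - px.min() < min_contrast:
        return replace(img, pixels=np.ones_like(px))
    t = filters.threshold_otsu(px)
    return replace(img, pixels=(px > t).astype(float))


def crop_spine_roi(
    img: RadiographImage, proj_threshold: float = 0.25
) -> tuple[RadiographImage, ROIBox]:
    """Crop by row/column intensity projections.

    The ROI is the bounding box of rows and columns whose summed intensity
    reaches ``proj_threshold`` times the maximum projection on that axis.
    An all-zero image has no qualifying bin and raises EmptyROIError.
    """
    px = img.pixels
    row_proj = px.sum(axis=1)
    col_proj = px.sum(axis=0)
    if row_proj.max() <= 0 or col_proj.max() <= 0:
        raise EmptyROIError("no projection bin exceeds the threshold")
    rows = np.nonzero(row_proj >= proj_threshold * row_proj.max())[0]
    cols = np.nonzero(col_proj >= proj_threshold * col_proj.max())[0]
    box = ROIBox(int(rows[0]), int(rows[-1]) + 1, int(cols[0]), int(cols[-1]) + 1)
    cropped = replace(img, pixels=box.crop(px).copy())
    return cropped, box


def write_png(path, pixels: np.ndarray) -> None:
    """Write a [0, 1] float image as 16-bit PNG (lossless for 8-bit inputs)."""
    arr = np.clip(np.asarray(pixels, dtype=float), 0.0, 1.0)
    iio.imwrite(Path(path), np.round(arr * 65535).astype(np.uint16))
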