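"""Segmentation primitives for cocoon images.

The shape/size station isolates a single cocoon lying in its cradle from an
RGB frame.  The chain is: RGB -> HSB (all three channels rescaled to 0-255),
a log-luminance edge-emphasis map built from the HSB channels with the
BT.601 weights, max-normalization and 8-bit quantization, Otsu binarization,
largest-connected-component selection with hole filling, and finally a
pixel-count size gate with strict lower/upper bounds.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy import ndimage
from skimage import color as _skcolor
from skimage.filters import threshold_otsu
from skimage.measure import label

from .errors import DegenerateImageError, NoObjectError, ValidationError

#: BT.601 luma weights, applied here to the H, S, B channels.
LUMA_WEIGHTS = (0.2989, 0.5870, 0.1140)

#: Default guard added inside log(|.|) so black pixels stay finite.
DEFAULT_EPS = 1e-6

SizeVerdict = Literal["undersized", "ok", "oversized"]


def _check_rgb(img: np.ndarray) -> np.ndarray:
    arr = np.asarray(img)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValidationError(f"expected H x W x 3 RGB raster, got shape {arr.shape}")
    if arr.shape[0] < 1 or arr.shape[1] < 1:
        raise ValidationError("image must be at least 1 x 1")
    if arr.min() < 0 or arr.max() > 255:
        raise ValidationError("RGB values must lie in [0, 255]")
    return arr


def rgb_to_hsb(img: np.ndarray) -> np.ndarray:
    """Convert an 8-bit RGB raster to HSB with every channel on 0-255.

    Hue, saturation and brightness follow the standard hexcone model; each
    channel is then linearly rescaled from its unit range to 0-255 and kept
    as float64 so no precision is lost before thresholding.
    """
    arr = _check_rgb(img)
    hsv = _skcolor.rgb2hsv(arr.astype(np.float64) / 255.0)
    return hsv * 255.0


def hsb_to_rgb(hsb: np.ndarray) -> np.ndarray:
    """Inverse of :func:`rgb_to_hsb`; returns a uint8 raster."""
    arr = np.asarray(hsb, dtype=np.float64)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValidationError(f"expected H x W x 3 HSB raster, got shape {arr.shape}")
    rgb = _skcolor.hsv2rgb(arr / 255.0)
    return np.clip(np.rint(rgb * 255.0), 0, 255).astype(np.uint8)


@dataclass(frozen=True)
class EdgeMap:
    """Log-luminance edge-emphasis map M and its 8-bit normalization."""

    values: np.ndarray
    normalized8: np.ndarray
    degenerate: bool


def edge_map(hsb: np.ndarray, eps: float = DEFAULT_EPS) -> EdgeMap:
    """Compute M = log(|0.2989 H + 0.5870 S + 0.1140 B| + eps).

    M is then normalized to its maximum and quantized to uint8.  Negative
    values of M (weighted HSB sum below 1) clip to 0 after normalization;
    they carry no edge information at 8-bit depth anyway.  A constant map,
    or one whose maximum is not positive, is flagged degenerate so the
    binarizer can reject it.
    """
    if eps <= 0:
        raise ValidationError("eps must be positive")
    arr = np.asarray(hsb, dtype=np.float64)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValidationError(f"expected H x W x 3 HSB raster, got shape {arr.shape}")
    wsum = (
        LUMA_WEIGHTS[0] * arr[..., 0]
        + LUMA_WEIGHTS[1] * arr[..., 1]
        + LUMA_WEIGHTS[2] * arr[..., 2]
    )
    m = np.log(np.abs(wsum) + eps)
    mx = float(m.max())
    if mx <= 0 or not np.isfinite(mx):
        return EdgeMap(m, np.zeros(m.shape, dtype=np.uint8), True)
    norm = np.clip(m, 0.0, None) / mx
    quant = np.rint(norm * 255.0).astype(np.uint8)
    degenerate = quant.max() == quant.min()
    return EdgeMap(m, quant, degenerate)


def otsu_binarize(
    edge: EdgeMap,
    foreground: Literal["center", "above", "below"] = "center",
) -> np.ndarray:
    """Binarize the normalized edge map at the Otsu threshold.

    The threshold maximizes the between-class variance of the 8-bit
    histogram.  ``foreground`` selects which side of the threshold is the
    cocoon: ``"above"``/``"below"`` are fixed polarities, while the default
    ``"center"`` takes the class containing the image-center pixel (the
    cradle centers the cocoon in the frame).
    """
    if edge.degenerate:
        raise DegenerateImageError("edge map is constant; cannot binarize")
    img = edge.normalized8
    if np.unique(img).size < 2:
        raise DegenerateImageError("edge map has a single gray level")
    thresh = threshold_otsu(img)
    above = img > thresh
    if foreground == "above":
        return above
    if foreground == "below":
        return ~above
    if foreground == "center":
        center = above[img.shape[0] // 2, img.shape[1] // 2]
        return above if center else ~above
    raise ValidationError(f"unknown foreground polarity {foreground!r}")


def otsu_threshold_bruteforce(img: np.ndarray) -> int:
    """Exhaustive-search Otsu threshold (independent oracle).

    Evaluates every candidate threshold t over the range of gray levels
    present, splitting pixels into {<= t} and {> t}, and returns the first t
    maximizing the between-class variance.
    """
    img = np.asarray(img)
    lo, hi = int(img.min()), int(img.max())
    counts = np.bincount(img.ravel().astype(np.int64) - lo, minlength=hi - lo + 1)
    levels = np.arange(lo, hi + 1, dtype=np.float64)
    w0 = np.cumsum(counts)
    w1 = w0[-1] - w0
    csum = np.cumsum(counts * levels)
    total = csum[-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        mu0 = csum / w0
        mu1 = (total - csum) / w1
        var_between = w0 * w1 * (mu0 - mu1) ** 2
    var_between = np.nan_to_num(var_between[:-1], nan=-1.0)
    if var_between.size == 0:
        raise DegenerateImageError("constant image has no Otsu threshold")
    return int(levels[int(np.argmax(var_between))])


def select_cocoon_region(mask: np.ndarray, connectivity: int = 2) -> np.ndarray:
    """Keep the largest connected foreground component and fill its holes.

    One cocoon sits in each cradle, so the dominant blob is the cocoon and
    smaller blobs are glare or debris.  Components use 8-connectivity by
    default (``connectivity=2`` in raster terms).
    """
    mask = np.asarray(mask, dtype=bool)
    labels = label(mask, connectivity=connectivity)
    n = labels.max()
    if n == 0:
        raise NoObjectError("mask contains no foreground object")
    areas = np.bincount(labels.ravel())[1:]
    keep = int(np.argmax(areas)) + 1
    region = labels == keep
    return ndimage.binary_fill_holes(region)


@dataclass(frozen=True)
class SizeThresholds:
    """Pixel-area gate. Bounds are exclusive: a cocoon passes only if
    min_px2 < area < max_px2 (boundary areas are rejected)."""

    min_px2: int
    max_px2: int
    px2_per_mm2: float | None = None

    def __post_init__(self) -> None:
        if not (0 < self.min_px2 < self.max_px2):
            raise ValidationError("size thresholds require 0 < min_px2 < max_px2")

    @classmethod
    def from_mm2(
        cls, min_mm2: float, max_mm2: float, px2_per_mm2: float
    ) -> "SizeThresholds":
        return cls(
            min_px2=int(round(min_mm2 * px2_per_mm2)),
            max_px2=int(round(max_mm2 * px2_per_mm2)),
            px2_per_mm2=px2_per_mm2,
        )


#: Production gate: 81,900 px^2 < area < 124,500 px^2 at the machine's
#: optics, equivalent to roughly 300-450 mm^2 at ~273 px^2 per mm^2.
DEFAULT_SIZE_THRESHOLDS = SizeThresholds(min_px2=81_900, max_px2=124_500, px2_per_mm2=273.0)


def measure_and_gate_size(
    mask: np.ndarray, thresholds: SizeThresholds = DEFAULT_SIZE_THRESHOLDS
) -> tuple[int, SizeVerdict]:
    """Count foreground pixels and gate the area with strict inequalities."""
    mask = np.asarray(mask, dtype=bool)
    area = int(mask.sum())
    if area == 0:
        raise NoObjectError("mask contains no foreground object")
    if area <= thresholds.min_px2:
        return area, "undersized"
    if area >= thresholds.max_px2:
        return area, "oversized"
    return area, "ok"
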