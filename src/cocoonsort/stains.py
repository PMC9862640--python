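"""Outside-stain detection by fixed HSB thresholds and an object-area rule.

Each cocoon is imaged from above and below.  Every pixel whose H, S and B
values all fall inside a per-camera interval profile is flagged, flagged
pixels are grouped into 8-connected components, and the cocoon counts as
stained if any single component covers strictly more than 144 px^2.  The two
views are OR-combined so a spot visible to only one camera is still caught.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.measure import label, regionprops

from .errors import PairingError, ValidationError

DEFAULT_MIN_OBJECT_AREA_PX2 = 144


@dataclass(frozen=True)
class StainProfile:
    """Per-camera HSB interval filter, all bounds inclusive on the 0-255 scale."""

    camera_id: str
    h_range: tuple[int, int]
    s_range: tuple[int, int]
    b_range: tuple[int, int]
    min_object_area_px2: int = DEFAULT_MIN_OBJECT_AREA_PX2

    def __post_init__(self) -> None:
        for name, (lo, hi) in (
            ("h", self.h_range),
            ("s", self.s_range),
            ("b", self.b_range),
        ):
            if not (0 <= lo <= hi <= 255):
                raise ValidationError(
                    f"{name}_range must satisfy 0 <= low <= high <= 255, got {(lo, hi)}"
                )
        if self.min_object_area_px2 <= 0:
            raise ValidationError("min_object_area_px2 must be positive")


#: Top camera (coaxial white LED): stains are low-hue, moderately saturated.
TOP_PROFILE = StainProfile("top", h_range=(0, 80), s_range=(60, 255), b_range=(0, 255))
#: Bottom camera (warm LED strips): only near-saturated pixels are stains.
BOTTOM_PROFILE = StainProfile(
    "bottom", h_range=(0, 255), s_range=(220, 255), b_range=(0, 255)
)


@dataclass(frozen=True)
class StainVerdict:
    stained: bool
    flagged_objects: list  # (area_px2, (x, y) centroid) per component
    view: str
    cocoon_id: int | None = None


def stain_filter(
    hsb: np.ndarray, profile: StainProfile, roi: np.ndarray | None = None
) -> np.ndarray:
    """Flag pixels whose H, S and B each fall inside the profile intervals.

    ``roi`` (normally the segmented cocoon mask) restricts the filter so
    cradle or background pixels cannot trip the bottom camera's
    saturation-only profile.
    """
    arr = np.asarray(hsb, dtype=np.float64)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValidationError(f"expected H x W x 3 HSB raster, got {arr.shape}")
    mask = np.ones(arr.shape[:2], dtype=bool)
    for ch, (lo, hi) in enumerate((profile.h_range, profile.s_range, profile.b_range)):
        mask &= (arr[..., ch] >= lo) & (arr[..., ch] <= hi)
    if roi is not None:
        roi = np.asarray(roi, dtype=bool)
        if roi.shape != mask.shape:
            raise ValidationError("roi shape does not match the image")
        mask &= roi
    return mask


def stain_verdict(
    mask: np.ndarray,
    profile: StainProfile,
    cocoon_id: int | None = None,
    connectivity: int = 2,
) -> StainVerdict:
    """Stained iff any single 8-connected flagged component exceeds the
    per-object area rule (strictly greater than ``min_object_area_px2``)."""
    labels = label(np.asarray(mask, dtype=bool), connectivity=connectivity)
    objects = [
        (int(rp.area), (float(rp.centroid[1]), float(rp.centroid[0])))
        for rp in regionprops(labels)
    ]
    stained = any(area > profile.min_object_area_px2 for area, _ in objects)
    return StainVerdict(
        stained=stained, flagged_objects=objects, view=profile.camera_id,
        cocoon_id=cocoon_id,
    )


def combine_views(top: StainVerdict, bottom: StainVerdict) -> bool:
    """OR-combination of the two per-view verdicts for one cocoon."""
    if (
        top.cocoon_id is not None
        and bottom.cocoon_id is not None
        and top.cocoon_id != bottom.cocoon_id
    ):
        raise PairingError(
            f"view verdicts belong to different cocoons: {top.cocoon_id} vs {bottom.cocoon_id}"
        )
    return top.stained or bottom.stained
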