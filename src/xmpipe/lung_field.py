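"""Lung-field masking and cropping with a deterministic classical method.

Lungs are found as the darker regions of the ingested image (Otsu threshold
plus morphological cleanup and component selection).  A centered-rectangle
fallback guarantees a nonempty mask on degenerate inputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.morphology import closing, disk, opening

from .xray_io import NormImage

DEFAULT_MARGIN_FRAC = 0.05

# component must cover at least this fraction of the image to count as lung
_MIN_COMPONENT_FRAC = 0.05
_FALLBACK_FRAC = 0.6  # centered fallback rectangle side, per dimension
_CENTRAL_COLUMN_FRAC = 0.8


@dataclass(frozen=True)
class LungMask:
    """Binary lung mask with its tight bounding box (half-open)."""

    mask: np.ndarray
    bbox: tuple[int, int, int, int]
    area_fraction: float

    def __post_init__(self):
        m = np.asarray(self.mask, dtype=bool)
        if m.ndim != 2 or not m.any():
            raise ValueError("lung mask must be 2-D and nonempty")
        object.__setattr__(self, "mask", m)
        if not 0.0 < self.area_fraction <= 1.0:
            raise ValueError(f"area_fraction must be in (0, 1], got {self.area_fraction}")

    @classmethod
    def from_mask(cls, mask: np.ndarray) -> "LungMask":
        mask = np.asarray(mask, dtype=bool)
        if not mask.any():
            raise ValueError("lung mask must be nonempty")
        rows = np.flatnonzero(mask.any(axis=1))
        cols = np.flatnonzero(mask.any(axis=0))
        bbox = (int(rows[0]), int(cols[0]), int(rows[-1]) + 1, int(cols[-1]) + 1)
        return cls(mask=mask, bbox=bbox, area_fraction=float(mask.mean()))


def _fallback_mask(shape: tuple[int, int]) -> LungMask:
    h, w = shape
    mask = np.zeros(shape, dtype=bool)
    dh = int(round(h * _FALLBACK_FRAC))
    dw = int(round(w * _FALLBACK_FRAC))
    r0 = (h - dh) // 2
    c0 = (w - dw) // 2
    mask[r0 : r0 + dh, c0 : c0 + dw] = True
    return LungMask.from_mask(mask)


def segment_lungs(img: NormImage, dark_lungs: bool = True) -> LungMask:
    """Segment candidate lung fields by thresholding + morphology.

    Keeps the largest one or two dark components whose centroids lie within
    the central 80% of columns.  Falls back to a centered rectangle covering
    60% of each dimension when nothing plausible is found.
    """
    px = img.pixels
    if np.ptp(px) < 1e-9:
        return _fallback_mask(px.shape)
    # denoise, then threshold in the log domain: power-law (gamma) contrast
    # changes become affine there, and Otsu is invariant under affine maps
    smooth = ndimage.gaussian_filter(px, sigma=max(1.0, 0.01 * min(px.shape)))
    logpx = np.log(smooth + 1e-3)
    thresh = threshold_otsu(logpx, nbins=256)
    cand = logpx < thresh if dark_lungs else logpx > thresh
    radius = max(1, int(round(0.01 * min(px.shape))))
    selem = disk(radius)
    cand = closing(opening(cand, selem), selem)

    labels, n = ndimage.label(cand)
    if n == 0:
        return _fallback_mask(px.shape)
    w = px.shape[1]
    lo_col = (1 - _CENTRAL_COLUMN_FRAC) / 2 * w
    hi_col = (1 + _CENTRAL_COLUMN_FRAC) / 2 * w
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=range(1, n + 1))
    centroids = ndimage.center_of_mass(cand, labels, index=range(1, n + 1))
    candidates = [
        (int(sizes[i]), i + 1)
        for i in range(n)
        if lo_col <= centroids[i][1] <= hi_col
    ]
    candidates.sort(reverse=True)
    keep = [lab for _, lab in candidates[:2]]
    if not keep or max(s for s, _ in candidates[:2]) < _MIN_COMPONENT_FRAC * px.size:
        return _fallback_mask(px.shape)
    mask = np.isin(labels, keep)
    return LungMask.from_mask(mask)


def crop_to_lungs(
    img: NormImage, mask: LungMask, margin_frac: float = DEFAULT_MARGIN_FRAC
) -> tuple[NormImage, LungMask]:
    """Crop image and mask to the mask's bounding box, expanded by a margin.

    The margin is ``margin_frac`` of the bbox height/width on each side,
    clipped to the image bounds.
    """
    if not 0.0 <= margin_frac <= 0.5:
        raise ValueError(f"margin_frac must be in [0, 0.5], got {margin_frac}")
    r0, c0, r1, c1 = mask.bbox
    dr = int(round((r1 - r0) * margin_frac))
    dc = int(round((c1 - c0) * margin_frac))
    r0 = max(0, r0 - dr)
    c0 = max(0, c0 - dc)
    r1 = min(img.height, r1 + dr)
    c1 = min(img.width, c1 + dc)
    cropped = NormImage(img.pixels[r0:r1, c0:c1])
    cropped_mask = LungMask.from_mask(mask.mask[r0:r1, c0:c1])
    return cropped, cropped_mask
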