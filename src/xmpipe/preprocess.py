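"""Pre-processing operators: HE, CLAHE, UM, XM histogram modification, resize.

All operators take and return :class:`~xmpipe.xray_io.NormImage` and map
[0, 1] into [0, 1].  HE and CLAHE are computed on a 256-level quantization
of the float image (classic formulation) and rescaled back to [0, 1].
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage.transform import resize as _sk_resize

from .lung_field import LungMask, crop_to_lungs, segment_lungs
from .xray_io import NormImage

_N_LEVELS = 256


class PreprocessMethod(enum.Enum):
    NONE = "none"
    HE = "he"
    CLAHE = "clahe"
    UM = "um"
    XM = "xm"

    @classmethod
    def from_string(cls, name: str) -> "PreprocessMethod":
        try:
            return cls(name.lower())
        except ValueError:
            raise ValueError(
                f"unknown preprocessing method {name!r}; expected one of "
                f"{[m.value for m in cls]}"
            ) from None


@dataclass(frozen=True)
class HistModParams:
    """Parameters of the iterative histogram clip-and-stretch."""

    clip_frac: float = 0.01
    tol: float = 1.0 / 1024
    max_iter: int = 20
    n_bins: int = 1024

    def __post_init__(self):
        if not 0.0 < self.clip_frac <= 0.05:
            raise ValueError(f"clip_frac must be in (0, 0.05], got {self.clip_frac}")
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.n_bins < 64:
            raise ValueError("n_bins must be >= 64")


def _quantize(px: np.ndarray) -> np.ndarray:
    return np.clip(np.rint(px * (_N_LEVELS - 1)), 0, _N_LEVELS - 1).astype(np.intp)


def hist_equalize(img: NormImage) -> NormImage:
    """Global histogram equalization through the empirical CDF."""
    q = _quantize(img.pixels)
    hist = np.bincount(q.ravel(), minlength=_N_LEVELS)
    cdf = np.cumsum(hist) / q.size
    return NormImage(cdf[q])


def _clipped_cdf(hist: np.ndarray, npix: int, clip_limit: float) -> np.ndarray:
    clip_count = clip_limit * npix / _N_LEVELS
    excess = np.maximum(hist - clip_count, 0.0).sum()
    clipped = np.minimum(hist, clip_count) + excess / _N_LEVELS
    return np.cumsum(clipped) / npix


def clahe(
    img: NormImage, clip_limit: float = 4.0, tiles: tuple[int, int] = (8, 8)
) -> NormImage:
    """Contrast-limited adaptive histogram equalization.

    ``clip_limit`` is a multiple of the uniform bin height (OpenCV
    convention); the clipped excess is redistributed uniformly.  Tile
    mappings are blended with bilinear interpolation between tile centers.
    """
    if clip_limit <= 0:
        raise ValueError("clip_limit must be positive")
    ty, tx = tiles
    h, w = img.shape
    if ty < 1 or tx < 1:
        raise ValueError("tiles must be >= (1, 1)")
    if ty > h or tx > w:
        raise ValueError(f"tile grid {tiles} larger than image {img.shape}")

    q = _quantize(img.pixels)
    row_edges = np.linspace(0, h, ty + 1).astype(int)
    col_edges = np.linspace(0, w, tx + 1).astype(int)
    luts = np.empty((ty, tx, _N_LEVELS))
    for i in range(ty):
        for j in range(tx):
            tile = q[row_edges[i] : row_edges[i + 1], col_edges[j] : col_edges[j + 1]]
            hist = np.bincount(tile.ravel(), minlength=_N_LEVELS).astype(float)
            luts[i, j] = _clipped_cdf(hist, tile.size, clip_limit)

    cy = (row_edges[:-1] + row_edges[1:]) / 2.0 - 0.5
    cx = (col_edges[:-1] + col_edges[1:]) / 2.0 - 0.5
    ry = np.interp(np.arange(h), cy, np.arange(ty)) if ty > 1 else np.zeros(h)
    rx = np.interp(np.arange(w), cx, np.arange(tx)) if tx > 1 else np.zeros(w)
    iy0 = np.clip(np.floor(ry).astype(int), 0, ty - 1)
    ix0 = np.clip(np.floor(rx).astype(int), 0, tx - 1)
    iy1 = np.minimum(iy0 + 1, ty - 1)
    ix1 = np.minimum(ix0 + 1, tx - 1)
    fy = (ry - iy0)[:, None]
    fx = (rx - ix0)[None, :]

    IY0, IX0 = iy0[:, None], ix0[None, :]
    IY1, IX1 = iy1[:, None], ix1[None, :]
    out = (
        (1 - fy) * (1 - fx) * luts[IY0, IX0, q]
        + (1 - fy) * fx * luts[IY0, IX1, q]
        + fy * (1 - fx) * luts[IY1, IX0, q]
        + fy * fx * luts[IY1, IX1, q]
    )
    return NormImage(np.clip(out, 0.0, 1.0))


def unsharp_mask(img: NormImage, blur_sigma: float = 10.0, amount: float = 1.0) -> NormImage:
    """Sharpen by adding a scaled difference from a Gaussian-blurred copy."""
    if blur_sigma <= 0:
        raise ValueError("blur_sigma must be positive")
    if amount < 0:
        raise ValueError("amount must be >= 0")
    px = img.pixels
    blurred = gaussian_filter(px, sigma=blur_sigma, mode="nearest")
    return NormImage(np.clip(px + amount * (px - blurred), 0.0, 1.0))


def _hist_quantile(y: np.ndarray, frac: float, n_bins: int) -> float:
    """Quantile of values in [0, 1] from an n_bins histogram, linear in-bin."""
    hist, edges = np.histogram(y, bins=n_bins, range=(0.0, 1.0))
    cum = np.cumsum(hist) / y.size
    idx = int(np.searchsorted(cum, frac))
    if idx >= n_bins:
        return 1.0
    prev = cum[idx - 1] if idx > 0 else 0.0
    binmass = cum[idx] - prev
    t = 0.0 if binmass <= 0 else (frac - prev) / binmass
    return float(edges[idx] + t * (edges[idx + 1] - edges[idx]))


def iterative_clip_bounds(
    img: NormImage, params: HistModParams = HistModParams()
) -> tuple[float, float]:
    """Converged stretch bounds (in original intensity units) of the
    iterative per-tail clip-and-restretch process.

    Each iteration clips ``clip_frac`` of the pixel mass from each tail of
    the current stretched histogram and re-stretches to [0, 1]; iteration
    stops once both bounds move by less than ``tol`` (in the current
    normalized scale) or ``max_iter`` is reached.
    """
    x = img.pixels
    lo, hi = float(x.min()), float(x.max())
    if hi - lo < 1e-12:
        return lo, hi
    for _ in range(params.max_iter):
        y = np.clip((x - lo) / (hi - lo), 0.0, 1.0)
        q_lo = _hist_quantile(y, params.clip_frac, params.n_bins)
        q_hi = _hist_quantile(y, 1.0 - params.clip_frac, params.n_bins)
        if q_hi - q_lo < 1e-12:
            break
        new_lo = lo + q_lo * (hi - lo)
        new_hi = lo + q_hi * (hi - lo)
        moved_lo = q_lo          # distance from 0 in current scale
        moved_hi = 1.0 - q_hi    # distance from 1 in current scale
        lo, hi = new_lo, new_hi
        if moved_lo < params.tol and moved_hi < params.tol:
            break
    return lo, hi


def xm_histogram_modify(
    img: NormImage, mask: LungMask, params: HistModParams = HistModParams()
) -> NormImage:
    """Histogram modification: iterative clip-stretch + lung-minimum clamp.

    After the clip-and-stretch process converges, the lower bound of the
    final linear map is set to the minimum intensity inside the lung mask,
    so the post-clamp lung minimum maps to 0 and the global maximum to 1.
    """
    px = img.pixels
    if np.ptp(px) < 1e-12:
        return NormImage(px.copy())
    lo, hi = iterative_clip_bounds(img, params)
    if hi - lo < 1e-12:
        return NormImage(px.copy())
    y = np.clip((px - lo) / (hi - lo), 0.0, 1.0)
    lung_min = float(y[mask.mask].min())
    denom = float(y.max()) - lung_min
    if denom < 1e-12:
        return NormImage(np.zeros_like(y))
    return NormImage(np.clip((y - lung_min) / denom, 0.0, 1.0))


def resize_to(img: NormImage, size: int) -> NormImage:
    """Bilinear resize to ``size`` x ``size`` (anti-aliased when shrinking)."""
    if img.shape == (size, size):
        return img
    shrinking = size < min(img.shape)
    out = _sk_resize(
        img.pixels, (size, size), order=1, anti_aliasing=shrinking, preserve_range=True
    )
    return NormImage(np.clip(out, 0.0, 1.0))


def resize_512(img: NormImage) -> NormImage:
    return resize_to(img, 512)


def preprocess_dispatch(
    img: NormImage,
    mask: LungMask | None = None,
    method: PreprocessMethod = PreprocessMethod.NONE,
    *,
    out_size: int = 512,
    margin_frac: float = 0.05,
    hist_params: HistModParams = HistModParams(),
    clahe_clip: float = 4.0,
    clahe_tiles: tuple[int, int] = (8, 8),
    um_sigma_512: float = 10.0,
    um_amount: float = 1.0,
) -> NormImage:
    """Full pre-processing pipeline: lung crop -> method -> resize.

    ``um_sigma_512`` is the unsharp-mask blur sigma expressed at the 512-px
    scale; it is rescaled to the native crop resolution before application.
    """
    if not isinstance(method, PreprocessMethod):
        method = PreprocessMethod.from_string(str(method))
    if mask is None:
        mask = segment_lungs(img)
    cropped, cropped_mask = crop_to_lungs(img, mask, margin_frac=margin_frac)
    if method is PreprocessMethod.NONE:
        out = cropped
    elif method is PreprocessMethod.HE:
        out = hist_equalize(cropped)
    elif method is PreprocessMethod.CLAHE:
        th = min(clahe_tiles[0], cropped.height)
        tw = min(clahe_tiles[1], cropped.width)
        out = clahe(cropped, clip_limit=clahe_clip, tiles=(th, tw))
    elif method is PreprocessMethod.UM:
        sigma = max(um_sigma_512 * min(cropped.shape) / 512.0, 0.5)
        out = unsharp_mask(cropped, blur_sigma=sigma, amount=um_amount)
    elif method is PreprocessMethod.XM:
        out = xm_histogram_modify(cropped, cropped_mask, hist_params)
    else:  # pragma: no cover - enum is exhaustive
        raise ValueError(f"unknown method {method}")
    return resize_to(out, out_size)
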