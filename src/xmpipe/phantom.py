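"""Synthetic chest-phantom generator with ground-truth lung masks.

Phantoms are stylized, not anatomical: a bright mediastinum band, two dark
elliptical lung fields with sinusoidal rib banding, smooth per-phantom
texture, and an optional lesion (Gaussian nodule or half-lung haze).
Machine profiles corrupt phantoms along contrast / sharpness / noise axes
the way different acquisition hardware would.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .augment import add_gaussian_noise, gamma_contrast
from .lung_field import LungMask
from .xray_io import NormImage, write_image


class LesionKind(enum.Enum):
    NODULE = "nodule"
    CONSOLIDATION = "consolidation"


@dataclass(frozen=True)
class PhantomSpec:
    size: int = 128
    abnormal: bool = False
    lesion_kind: LesionKind = LesionKind.NODULE
    lesion_contrast: float = 0.2
    seed: int = 0

    def __post_init__(self):
        if self.size < 64:
            raise ValueError(f"size must be >= 64, got {self.size}")
        if not 0.0 < self.lesion_contrast <= 0.5:
            raise ValueError(
                f"lesion_contrast must be in (0, 0.5], got {self.lesion_contrast}"
            )


@dataclass(frozen=True)
class MachineProfile:
    """Hardware-like corruption: gamma, blur, intensity offset, noise."""

    name: str
    gamma: float = 1.0
    blur_sigma: float = 0.0
    noise_sigma: float = 0.0
    intensity_offset: float = 0.0

    def __post_init__(self):
        for v in (self.gamma, self.blur_sigma, self.noise_sigma, self.intensity_offset):
            if not np.isfinite(v):
                raise ValueError("profile parameters must be finite")
        if self.gamma <= 0 or self.blur_sigma < 0 or self.noise_sigma < 0:
            raise ValueError("invalid machine profile parameters")

    @property
    def is_identity(self) -> bool:
        return (
            self.gamma == 1.0
            and self.blur_sigma == 0.0
            and self.noise_sigma == 0.0
            and self.intensity_offset == 0.0
        )


IDENTITY_PROFILE = MachineProfile("IDENTITY")

MACHINE_PROFILES: dict[str, MachineProfile] = {
    "IDENTITY": IDENTITY_PROFILE,
    "DR_STATIONARY": MachineProfile("DR_STATIONARY", gamma=1.0, blur_sigma=0.0, noise_sigma=0.01),
    "CR": MachineProfile("CR", gamma=1.3, blur_sigma=1.5, noise_sigma=0.03),
    "CR_MOBILE": MachineProfile("CR_MOBILE", gamma=1.3, blur_sigma=1.5, noise_sigma=0.06),
}


@dataclass(frozen=True)
class PhantomRender:
    image: NormImage
    lung_mask: LungMask
    label: int
    lesion_footprint: np.ndarray  # boolean, empty for normal phantoms


def render_phantom(spec: PhantomSpec) -> PhantomRender:
    """Render one phantom with ground truth; deterministic per seed.

    The lesion geometry is drawn from the rng stream regardless of the
    ``abnormal`` flag, so a normal/abnormal pair sharing a seed differs only
    by the lesion itself (matched pairs for contrast measurements).
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.size
    y, x = np.mgrid[0:n, 0:n] / (n - 1)

    body = 0.65 + rng.uniform(-0.03, 0.03) + 0.03 * (y - 0.5)
    img = body + 0.20 * np.exp(-(((x - 0.5) / 0.09) ** 2))

    lung_level = 0.25 + rng.uniform(-0.03, 0.03)
    rib_amp = 0.04
    rib_freq = rng.uniform(6.0, 8.0)
    rib_phase = rng.uniform(0.0, 2 * np.pi)
    cy = 0.47 + rng.uniform(-0.02, 0.02)
    lung_mask = np.zeros((n, n), dtype=bool)
    lung_params = []
    for side in (-1.0, 1.0):
        cx = 0.5 + side * (0.22 + rng.uniform(-0.01, 0.01))
        ax = 0.16 * (1 + rng.uniform(-0.05, 0.05))
        ay = 0.28 * (1 + rng.uniform(-0.05, 0.05))
        inside = ((x - cx) / ax) ** 2 + ((y - cy) / ay) ** 2 <= 1.0
        lung_mask |= inside
        lung_params.append((cx, cy, ax, ay))
    ribs = rib_amp * np.sin(2 * np.pi * rib_freq * y + rib_phase)
    img = np.where(lung_mask, lung_level + ribs, img)

    # smooth per-phantom texture so phantoms are not trivially identical
    texture = gaussian_filter(rng.normal(0.0, 1.0, (n, n)), sigma=n / 16.0)
    img = img + 0.02 * texture / max(texture.std(), 1e-9)

    # lesion geometry always drawn to keep streams aligned across labels
    side_idx = int(rng.integers(0, 2))
    cx, cyl, ax, ay = lung_params[side_idx]
    u, v = rng.uniform(-0.5, 0.5), rng.uniform(-0.4, 0.4)
    lx, ly = cx + u * ax, cyl + v * ay
    r = 0.25 * min(ax, ay) * (2.0 + rng.uniform(-0.4, 0.4))

    footprint = np.zeros((n, n), dtype=bool)
    if spec.abnormal:
        if spec.lesion_kind is LesionKind.NODULE:
            rho2 = (x - lx) ** 2 + (y - ly) ** 2
            footprint = rho2 <= r**2
            sigma = r / 1.2
            img = img + spec.lesion_contrast * np.exp(-rho2 / (2 * sigma**2))
        else:  # CONSOLIDATION: haze over the lower half of one lung
            inside = ((x - cx) / ax) ** 2 + ((y - cyl) / ay) ** 2 <= 1.0
            footprint = inside & (y > cyl)
            weight = gaussian_filter(footprint.astype(float), sigma=n / 64.0)
            img = img + spec.lesion_contrast * weight

    img = gaussian_filter(img, sigma=max(n / 256.0, 0.5))
    img = np.clip(img, 0.0, 1.0)
    return PhantomRender(
        image=NormImage(img),
        lung_mask=LungMask.from_mask(lung_mask),
        label=int(spec.abnormal),
        lesion_footprint=footprint,
    )


def generate_phantom(spec: PhantomSpec) -> tuple[NormImage, LungMask, int]:
    r = render_phantom(spec)
    return r.image, r.lung_mask, r.label


def apply_machine_profile(
    img: NormImage, profile: MachineProfile, seed: int = 0
) -> NormImage:
    """Corrupt an image with a machine profile: gamma, blur, offset, noise."""
    if profile.is_identity:
        return img
    out = gamma_contrast(img, profile.gamma)
    px = out.pixels
    if profile.blur_sigma > 0:
        px = gaussian_filter(px, sigma=profile.blur_sigma, mode="nearest")
    if profile.intensity_offset != 0.0:
        px = px + profile.intensity_offset
    out = NormImage(np.clip(px, 0.0, 1.0))
    return add_gaussian_noise(out, profile.noise_sigma, seed)


@dataclass(frozen=True)
class PhantomDataset:
    images: list
    masks: list
    labels: np.ndarray
    manifest: pd.DataFrame
    footprints: list


def generate_dataset(
    n: int,
    abnormal_frac: float,
    profile: MachineProfile = IDENTITY_PROFILE,
    seed: int = 0,
    *,
    size: int = 128,
    lesion_contrast: float = 0.2,
    lesion_kind: LesionKind = LesionKind.NODULE,
    out_dir=None,
) -> PhantomDataset:
    """Generate a labeled phantom dataset; exactly round(n * abnormal_frac)
    abnormal cases, reproducible per seed.

    When ``out_dir`` is given, 16-bit PNGs plus a ``manifest.csv`` with
    columns ``path,label`` are written there.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    if not 0.0 < abnormal_frac < 1.0:
        raise ValueError("abnormal_frac must be in (0, 1)")
    n_abn = int(round(n * abnormal_frac))
    if n_abn == 0 or n_abn == n:
        raise ValueError(
            f"abnormal_frac {abnormal_frac} rounds to {n_abn} of {n} abnormal cases"
        )
    rng = np.random.default_rng(seed)
    labels = np.zeros(n, dtype=int)
    labels[:n_abn] = 1
    labels = labels[rng.permutation(n)]
    image_seeds = rng.integers(0, 2**31 - 1, size=n)

    images, masks, footprints, rows = [], [], [], []
    for i in range(n):
        spec = PhantomSpec(
            size=size,
            abnormal=bool(labels[i]),
            lesion_kind=lesion_kind,
            lesion_contrast=lesion_contrast,
            seed=int(image_seeds[i]),
        )
        r = render_phantom(spec)
        img = apply_machine_profile(r.image, profile, seed=int(image_seeds[i]) + 1)
        images.append(img)
        masks.append(r.lung_mask)
        footprints.append(r.lesion_footprint)
        rows.append({"path": f"phantom_{i:04d}.png", "label": int(labels[i])})
    manifest = pd.DataFrame(rows)

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for img, row in zip(images, manifest.itertuples()):
            write_image(img, out_dir / row.path, bit_depth=16)
        manifest.to_csv(out_dir / "manifest.csv", index=False)
    return PhantomDataset(
        images=images, masks=masks, labels=labels, manifest=manifest, footprints=footprints
    )
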