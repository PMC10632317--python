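"""Augmentation operators: rotation/flip plus contrast, sharpness, noise.

The contrast/sharpness/noise triple is represented by :class:`PerturbSpec`,
whose identity element is (gamma=1, sharp=0, noise_sigma=0).  The same
operators back both randomized training augmentation and the deterministic
robustness sweeps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage.transform import rotate as _sk_rotate

from .xray_io import NormImage

SHARP_MAX = 12.0
_SHARP_BLUR_SIGMA = 3.0  # unsharp blur sigma for s > 0, at 512-px scale
_BLUR_SIGMA_PER_UNIT = 0.25  # s < 0 -> gaussian blur sigma |s| / 4

ALL_OPERATORS = frozenset({"gamma", "sharp", "noise", "rotate", "flip"})


@dataclass(frozen=True)
class PerturbSpec:
    """One (gamma, s, sigma) perturbation triple."""

    gamma: float = 1.0
    sharp: float = 0.0
    noise_sigma: float = 0.0

    def __post_init__(self):
        if self.gamma <= 0:
            raise ValueError(f"gamma must be positive, got {self.gamma}")
        if self.noise_sigma < 0:
            raise ValueError(f"noise_sigma must be >= 0, got {self.noise_sigma}")

    @property
    def is_identity(self) -> bool:
        return self.gamma == 1.0 and self.sharp == 0.0 and self.noise_sigma == 0.0


@dataclass(frozen=True)
class AugmentParams:
    """Ranges for randomized training-time augmentation."""

    gamma_range: tuple[float, float] = (0.5, 2.0)
    sharp_range: tuple[float, float] = (-6.0, 6.0)
    noise_range: tuple[float, float] = (0.0, 0.05)
    rot_deg_range: tuple[float, float] = (-15.0, 15.0)
    flip_prob: float = 0.5
    enabled: frozenset = field(default_factory=lambda: ALL_OPERATORS)

    def __post_init__(self):
        object.__setattr__(self, "enabled", frozenset(self.enabled))
        unknown = self.enabled - ALL_OPERATORS
        if unknown:
            raise ValueError(f"unknown operators {sorted(unknown)}")
        for name, rng in (
            ("gamma_range", self.gamma_range),
            ("sharp_range", self.sharp_range),
            ("noise_range", self.noise_range),
            ("rot_deg_range", self.rot_deg_range),
        ):
            if rng[0] > rng[1]:
                raise ValueError(f"{name} is not well-ordered: {rng}")
        if not 0.0 <= self.flip_prob <= 1.0:
            raise ValueError("flip_prob must be in [0, 1]")
        # identity must be reachable for every enabled operator
        if "gamma" in self.enabled and not self.gamma_range[0] <= 1.0 <= self.gamma_range[1]:
            raise ValueError("gamma_range must contain the identity value 1")
        if "sharp" in self.enabled and not self.sharp_range[0] <= 0.0 <= self.sharp_range[1]:
            raise ValueError("sharp_range must contain the identity value 0")
        if "noise" in self.enabled and self.noise_range[0] != 0.0:
            raise ValueError("noise_range must start at 0")
        if "rotate" in self.enabled and not self.rot_deg_range[0] <= 0.0 <= self.rot_deg_range[1]:
            raise ValueError("rot_deg_range must contain 0")

    @classmethod
    def conventional(cls) -> "AugmentParams":
        """Rotation + horizontal flip only."""
        return cls(enabled=frozenset({"rotate", "flip"}))

    @classmethod
    def xm(cls) -> "AugmentParams":
        """Rotation/flip plus contrast, sharpness, and noise augmentation."""
        return cls(enabled=ALL_OPERATORS)

    @classmethod
    def xm_stress(cls) -> "AugmentParams":
        """All five operators with ranges matching the stress-sweep extremes."""
        return cls(
            gamma_range=(0.2, 5.0),
            sharp_range=(-12.0, 12.0),
            noise_range=(0.0, 0.1),
            enabled=ALL_OPERATORS,
        )

    @classmethod
    def none(cls) -> "AugmentParams":
        return cls(enabled=frozenset())


def gamma_contrast(img: NormImage, gamma: float) -> NormImage:
    """Power-law contrast change, out = img ** gamma."""
    if gamma <= 0:
        raise ValueError(f"gamma must be positive, got {gamma}")
    if gamma == 1.0:
        return img
    return NormImage(np.power(img.pixels, gamma))


def adjust_sharpness(img: NormImage, s: float) -> NormImage:
    """Signed sharpness change.

    s = 0 is the identity; s > 0 applies unsharp-style enhancement with
    amount s / 12; s < 0 applies a Gaussian blur with sigma |s| / 4 px.
    """
    if s == 0.0:
        return img
    px = img.pixels
    if s > 0:
        blurred = gaussian_filter(px, sigma=_SHARP_BLUR_SIGMA, mode="nearest")
        out = px + (s / SHARP_MAX) * (px - blurred)
    else:
        out = gaussian_filter(px, sigma=-s * _BLUR_SIGMA_PER_UNIT, mode="nearest")
    return NormImage(np.clip(out, 0.0, 1.0))


def add_gaussian_noise(img: NormImage, sigma: float, seed: int) -> NormImage:
    """Add i.i.d. Gaussian noise on the [0, 1] scale, clipped."""
    if sigma < 0:
        raise ValueError(f"sigma must be >= 0, got {sigma}")
    if sigma == 0.0:
        return img
    rng = np.random.default_rng(seed)
    noisy = img.pixels + rng.normal(0.0, sigma, size=img.shape)
    return NormImage(np.clip(noisy, 0.0, 1.0))


def rotate_flip(img: NormImage, degrees: float = 0.0, flip: bool = False) -> NormImage:
    """Rotate about the center (bilinear, constant 0 fill) then mirror columns."""
    if abs(degrees) > 45:
        raise ValueError(f"|degrees| must be <= 45, got {degrees}")
    px = img.pixels
    if degrees != 0.0:
        px = _sk_rotate(px, degrees, resize=False, order=1, mode="constant", cval=0.0)
        px = np.clip(px, 0.0, 1.0)
    if flip:
        px = px[:, ::-1]
    return NormImage(px.copy() if px is not img.pixels else px)


def sample_augmentation(
    params: AugmentParams, rng_seed: int
) -> tuple[PerturbSpec, float, bool]:
    """Draw one (PerturbSpec, rotation degrees, flip) augmentation.

    Every component is uniform over its range (flip is Bernoulli); disabled
    operators return their identity values.  Deterministic per seed.
    """
    rng = np.random.default_rng(rng_seed)
    gamma = rng.uniform(*params.gamma_range) if "gamma" in params.enabled else 1.0
    sharp = rng.uniform(*params.sharp_range) if "sharp" in params.enabled else 0.0
    sigma = rng.uniform(*params.noise_range) if "noise" in params.enabled else 0.0
    degrees = rng.uniform(*params.rot_deg_range) if "rotate" in params.enabled else 0.0
    flip = bool(rng.random() < params.flip_prob) if "flip" in params.enabled else False
    return PerturbSpec(gamma=gamma, sharp=sharp, noise_sigma=sigma), degrees, flip


def apply_perturbation(img: NormImage, spec: PerturbSpec, seed: int = 0) -> NormImage:
    """Apply gamma, then sharpness, then noise, in that fixed order."""
    out = gamma_contrast(img, spec.gamma)
    out = adjust_sharpness(out, spec.sharp)
    out = add_gaussian_noise(out, spec.noise_sigma, seed)
    return out
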