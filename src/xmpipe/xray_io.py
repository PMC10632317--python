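"""Reading and writing x-ray images as raw stored intensities.

DICOM files are read without applying any window/level (VOI LUT) display
mapping: only the stored pixel values, plus rescale slope/intercept when
present, are used.  PNG inputs are treated as MONOCHROME2 (larger value
renders brighter) since PNG carries no photometric tag.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from . import _dicom


class FormatError(ValueError):
    """File exists but is not a readable x-ray image."""


class UnsupportedImageError(FormatError):
    """Readable file, but color/multi-frame/otherwise out of scope."""


class Photometric(enum.Enum):
    MONO1 = "MONOCHROME1"  # low stored value is displayed bright
    MONO2 = "MONOCHROME2"


class SourceFormat(enum.Enum):
    DICOM = "dicom"
    PNG = "png"


@dataclass(frozen=True)
class RawImage:
    """Stored pixel matrix before any normalization."""

    pixels: np.ndarray
    bit_depth: int
    photometric: Photometric
    source_format: SourceFormat

    def __post_init__(self):
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.shape[0] < 32 or px.shape[1] < 32:
            raise ValueError(f"pixel matrix must be 2-D with both dims >= 32, got {px.shape}")
        if not np.issubdtype(px.dtype, np.integer):
            raise ValueError("RawImage pixels must be integer-valued")
        hi = (1 << self.bit_depth) - 1
        if px.min() < 0 or px.max() > hi:
            raise ValueError(f"pixel values outside [0, {hi}] for bit depth {self.bit_depth}")


@dataclass(frozen=True)
class NormImage:
    """Floating intensity image on [0, 1]; higher value = more radiolucent."""

    pixels: np.ndarray

    def __post_init__(self):
        px = np.asarray(self.pixels, dtype=np.float64)
        if px.ndim != 2 or px.size == 0:
            raise ValueError(f"pixels must be a nonempty 2-D matrix, got shape {px.shape}")
        if not np.all(np.isfinite(px)):
            raise ValueError("NormImage contains NaN or Inf")
        if px.min() < 0.0 or px.max() > 1.0:
            raise ValueError(
                f"NormImage values outside [0, 1]: min={px.min():.6g} max={px.max():.6g}"
            )
        object.__setattr__(self, "pixels", px)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


def _is_dicom(path: Path) -> bool:
    if path.suffix.lower() in (".dcm", ".dicom"):
        return True
    try:
        with open(path, "rb") as fh:
            head = fh.read(132)
        return len(head) == 132 and head[128:132] == _dicom.MAGIC
    except OSError:
        return False


def read_image(path) -> RawImage:
    """Read a DICOM or 8/16-bit grayscale PNG into a :class:`RawImage`.

    DICOM rescale slope/intercept are applied and the result re-quantized to
    integers within the stored bit range; window/level metadata is ignored.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if _is_dicom(path):
        try:
            dcm = _dicom.read_dicom(path)
        except _dicom.DicomError as exc:
            msg = str(exc)
            if "not supported" in msg:
                raise UnsupportedImageError(msg) from exc
            raise FormatError(msg) from exc
        px = dcm.pixels.astype(np.float64)
        if dcm.rescale_slope != 1.0 or dcm.rescale_intercept != 0.0:
            px = px * dcm.rescale_slope + dcm.rescale_intercept
        hi = (1 << dcm.bits_stored) - 1
        px = np.clip(np.rint(px), 0, hi).astype(np.int64)
        return RawImage(
            pixels=px,
            bit_depth=dcm.bits_stored,
            photometric=Photometric(dcm.photometric),
            source_format=SourceFormat.DICOM,
        )
    # PNG path
    try:
        arr = iio.imread(path)
    except Exception as exc:
        raise FormatError(f"{path}: cannot decode image ({exc})") from exc
    if arr.ndim == 3:
        raise UnsupportedImageError(f"{path}: color images are not supported")
    if arr.ndim != 2:
        raise UnsupportedImageError(f"{path}: expected a single 2-D grayscale frame")
    if arr.dtype == np.uint8:
        depth = 8
    elif arr.dtype == np.uint16:
        depth = 16
    else:
        raise UnsupportedImageError(f"{path}: unsupported PNG dtype {arr.dtype}")
    return RawImage(
        pixels=arr.astype(np.int64),
        bit_depth=depth,
        photometric=Photometric.MONO2,
        source_format=SourceFormat.PNG,
    )


def to_normalized(img: RawImage) -> NormImage:
    """Scale stored values to [0, 1]; MONOCHROME1 sources are inverted."""
    hi = (1 << img.bit_depth) - 1
    px = np.asarray(img.pixels, dtype=np.float64) / hi
    if img.photometric is Photometric.MONO1:
        px = 1.0 - px
    return NormImage(px)


def write_image(img: NormImage, path, bit_depth: int = 16) -> None:
    """Re-quantize and write a PNG (default) or DICOM depending on suffix."""
    if bit_depth not in (8, 16):
        raise ValueError(f"bit_depth must be 8 or 16, got {bit_depth}")
    path = Path(path)
    hi = (1 << bit_depth) - 1
    quant = np.rint(img.pixels * hi).astype(np.uint16 if bit_depth == 16 else np.uint8)
    if path.suffix.lower() in (".dcm", ".dicom"):
        _dicom.write_dicom(path, quant.astype(np.int64), bits_stored=bit_depth)
    else:
        iio.imwrite(path, quant, extension=path.suffix or ".png")


def read_manifest(path) -> pd.DataFrame:
    """Read a `path,label` CSV manifest; labels must be binary 0/1."""
    df = pd.read_csv(path)
    missing = {"path", "label"} - set(df.columns)
    if missing:
        raise FormatError(f"manifest missing columns: {sorted(missing)}")
    labels = df["label"].to_numpy()
    if not np.isin(labels, (0, 1)).all():
        raise FormatError("manifest labels must be 0 or 1")
    return df
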