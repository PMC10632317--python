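"""Minimal DICOM codec for single-frame grayscale images.

Supports reading Explicit and Implicit VR Little Endian transfer syntaxes
(uncompressed) and writing Explicit VR Little Endian.  This deliberately
covers only the subset needed for raw chest-radiograph pixel access:
Rows/Columns, BitsAllocated/BitsStored, PhotometricInterpretation,
PixelRepresentation, RescaleSlope/Intercept, and PixelData.
"""

from __future__ import annotations

import os
import struct
from dataclasses import dataclass, field

import numpy as np

MAGIC = b"DICM"
PREAMBLE = b"\x00" * 128

TS_IMPLICIT_LE = "1.2.840.10008.1.2"
TS_EXPLICIT_LE = "1.2.840.10008.1.2.1"
SOP_SECONDARY_CAPTURE = "1.2.840.10008.5.1.4.1.1.7"

# VRs whose explicit encoding uses a 2-byte reserved field + 4-byte length
_LONG_VRS = {b"OB", b"OW", b"OF", b"OD", b"OL", b"SQ", b"UC", b"UR", b"UT", b"UN"}

TAG_TRANSFER_SYNTAX = (0x0002, 0x0010)
TAG_SOP_CLASS = (0x0008, 0x0016)
TAG_SOP_INSTANCE = (0x0008, 0x0018)
TAG_SAMPLES_PER_PIXEL = (0x0028, 0x0002)
TAG_PHOTOMETRIC = (0x0028, 0x0004)
TAG_NUMBER_OF_FRAMES = (0x0028, 0x0008)
TAG_ROWS = (0x0028, 0x0010)
TAG_COLUMNS = (0x0028, 0x0011)
TAG_BITS_ALLOCATED = (0x0028, 0x0100)
TAG_BITS_STORED = (0x0028, 0x0101)
TAG_HIGH_BIT = (0x0028, 0x0102)
TAG_PIXEL_REPRESENTATION = (0x0028, 0x0103)
TAG_RESCALE_INTERCEPT = (0x0028, 0x1052)
TAG_RESCALE_SLOPE = (0x0028, 0x1053)
TAG_PIXEL_DATA = (0x7FE0, 0x0010)


class DicomError(ValueError):
    """Malformed or unsupported DICOM stream."""


@dataclass
class DicomImage:
    pixels: np.ndarray
    bits_stored: int
    photometric: str
    rescale_slope: float = 1.0
    rescale_intercept: float = 0.0
    extra: dict = field(default_factory=dict)


def _read_exact(fh, n: int) -> bytes:
    buf = fh.read(n)
    if len(buf) != n:
        raise DicomError("truncated DICOM stream")
    return buf


def _parse_elements(fh, explicit: bool, stop_at_group=None):
    """Yield (tag, vr, value_bytes) until EOF or a group boundary."""
    while True:
        head = fh.read(8)
        if len(head) == 0:
            return
        if len(head) < 8:
            raise DicomError("truncated element header")
        group, elem = struct.unpack("<HH", head[:4])
        if stop_at_group is not None and group != stop_at_group:
            fh.seek(-8, os.SEEK_CUR)
            return
        if explicit:
            vr = head[4:6]
            if vr in _LONG_VRS:
                (length,) = struct.unpack("<I", _read_exact(fh, 4))
            else:
                (length,) = struct.unpack("<H", head[6:8])
        else:
            vr = b"UN"
            (length,) = struct.unpack("<I", head[4:8])
        if length == 0xFFFFFFFF:
            raise DicomError("undefined-length elements (sequences) are not supported")
        value = _read_exact(fh, length)
        yield (group, elem), vr, value


def _decode_str(value: bytes) -> str:
    return value.decode("ascii", errors="replace").rstrip(" \x00")


def _decode_us(value: bytes) -> int:
    return struct.unpack("<H", value[:2])[0]


def read_dicom(path) -> DicomImage:
    """Read a single-frame grayscale uncompressed DICOM file."""
    with open(path, "rb") as fh:
        preamble = fh.read(132)
        if len(preamble) < 132 or preamble[128:132] != MAGIC:
            raise DicomError(f"{path}: not a DICOM part-10 file (missing DICM magic)")
        # file meta group (0002) is always explicit little-endian
        meta = {}
        for tag, vr, value in _parse_elements(fh, explicit=True, stop_at_group=0x0002):
            meta[tag] = (vr, value)
        ts = TS_EXPLICIT_LE
        if TAG_TRANSFER_SYNTAX in meta:
            ts = _decode_str(meta[TAG_TRANSFER_SYNTAX][1])
        if ts == TS_EXPLICIT_LE:
            explicit = True
        elif ts == TS_IMPLICIT_LE:
            explicit = False
        else:
            raise DicomError(f"unsupported transfer syntax {ts!r} (compressed?)")

        ds = {}
        for tag, vr, value in _parse_elements(fh, explicit=explicit):
            ds[tag] = (vr, value)

    if TAG_PIXEL_DATA not in ds:
        raise DicomError(f"{path}: no PixelData element")

    def get_us(tag, default=None):
        if tag not in ds:
            if default is None:
                raise DicomError(f"missing required tag {tag}")
            return default
        return _decode_us(ds[tag][1])

    def get_str(tag, default=""):
        return _decode_str(ds[tag][1]) if tag in ds else default

    samples = get_us(TAG_SAMPLES_PER_PIXEL, default=1)
    if samples != 1:
        raise DicomError("color (SamplesPerPixel != 1) DICOM is not supported")
    n_frames = get_str(TAG_NUMBER_OF_FRAMES, default="1").strip() or "1"
    if int(n_frames) != 1:
        raise DicomError("multi-frame DICOM is not supported")

    rows = get_us(TAG_ROWS)
    cols = get_us(TAG_COLUMNS)
    bits_alloc = get_us(TAG_BITS_ALLOCATED)
    bits_stored = get_us(TAG_BITS_STORED, default=bits_alloc)
    pixel_repr = get_us(TAG_PIXEL_REPRESENTATION, default=0)
    photometric = get_str(TAG_PHOTOMETRIC, default="MONOCHROME2")
    if photometric not in ("MONOCHROME1", "MONOCHROME2"):
        raise DicomError(f"unsupported photometric interpretation {photometric!r}")

    raw = ds[TAG_PIXEL_DATA][1]
    if bits_alloc == 8:
        dtype = np.int8 if pixel_repr else np.uint8
    elif bits_alloc == 16:
        dtype = np.int16 if pixel_repr else np.uint16
    else:
        raise DicomError(f"unsupported BitsAllocated {bits_alloc}")
    expected = rows * cols * (bits_alloc // 8)
    if len(raw) < expected:
        raise DicomError("PixelData shorter than Rows*Columns")
    pixels = np.frombuffer(raw[:expected], dtype=np.dtype(dtype).newbyteorder("<"))
    pixels = pixels.reshape(rows, cols).astype(np.int64)

    slope = float(_decode_str(ds[TAG_RESCALE_SLOPE][1]) or 1.0) if TAG_RESCALE_SLOPE in ds else 1.0
    intercept = (
        float(_decode_str(ds[TAG_RESCALE_INTERCEPT][1]) or 0.0) if TAG_RESCALE_INTERCEPT in ds else 0.0
    )
    return DicomImage(
        pixels=pixels,
        bits_stored=bits_stored,
        photometric=photometric,
        rescale_slope=slope,
        rescale_intercept=intercept,
    )


def _encode_element(tag, vr: bytes, value: bytes) -> bytes:
    if len(value) % 2:
        value += b"\x00" if vr not in (b"UI",) else b"\x00"
    head = struct.pack("<HH", *tag)
    if vr in _LONG_VRS:
        return head + vr + b"\x00\x00" + struct.pack("<I", len(value)) + value
    return head + vr + struct.pack("<H", len(value)) + value


def _str_value(text: str) -> bytes:
    value = text.encode("ascii")
    if len(value) % 2:
        value += b"\x00"
    return value


def write_dicom(
    path,
    pixels: np.ndarray,
    bits_stored: int,
    photometric: str = "MONOCHROME2",
    rescale_slope: float | None = None,
    rescale_intercept: float | None = None,
) -> None:
    """Write a single-frame grayscale Explicit VR LE DICOM file."""
    pixels = np.asarray(pixels)
    if pixels.ndim != 2:
        raise DicomError("pixels must be 2-D")
    if photometric not in ("MONOCHROME1", "MONOCHROME2"):
        raise DicomError(f"invalid photometric {photometric!r}")
    if not 1 <= bits_stored <= 16:
        raise DicomError(f"bits_stored {bits_stored} out of range")
    bits_alloc = 8 if bits_stored <= 8 else 16
    hi = (1 << bits_stored) - 1
    if pixels.min() < 0 or pixels.max() > hi:
        raise DicomError(f"pixel values outside [0, {hi}]")
    arr = pixels.astype("<u1" if bits_alloc == 8 else "<u2")

    meta_elems = b"".join(
        [
            _encode_element((0x0002, 0x0002), b"UI", _str_value(SOP_SECONDARY_CAPTURE)),
            _encode_element((0x0002, 0x0003), b"UI", _str_value("1.2.826.0.1.3680043.999.1.1")),
            _encode_element(TAG_TRANSFER_SYNTAX, b"UI", _str_value(TS_EXPLICIT_LE)),
        ]
    )
    meta = _encode_element((0x0002, 0x0000), b"UL", struct.pack("<I", len(meta_elems))) + meta_elems

    body = [
        _encode_element(TAG_SOP_CLASS, b"UI", _str_value(SOP_SECONDARY_CAPTURE)),
        _encode_element(TAG_SOP_INSTANCE, b"UI", _str_value("1.2.826.0.1.3680043.999.1.1")),
        _encode_element(TAG_SAMPLES_PER_PIXEL, b"US", struct.pack("<H", 1)),
        _encode_element(TAG_PHOTOMETRIC, b"CS", _str_value(photometric)),
        _encode_element(TAG_ROWS, b"US", struct.pack("<H", arr.shape[0])),
        _encode_element(TAG_COLUMNS, b"US", struct.pack("<H", arr.shape[1])),
        _encode_element(TAG_BITS_ALLOCATED, b"US", struct.pack("<H", bits_alloc)),
        _encode_element(TAG_BITS_STORED, b"US", struct.pack("<H", bits_stored)),
        _encode_element(TAG_HIGH_BIT, b"US", struct.pack("<H", bits_stored - 1)),
        _encode_element(TAG_PIXEL_REPRESENTATION, b"US", struct.pack("<H", 0)),
    ]
    if rescale_intercept is not None:
        body.append(_encode_element(TAG_RESCALE_INTERCEPT, b"DS", _str_value(repr(rescale_intercept))))
    if rescale_slope is not None:
        body.append(_encode_element(TAG_RESCALE_SLOPE, b"DS", _str_value(repr(rescale_slope))))
    body.append(_encode_element(TAG_PIXEL_DATA, b"OW", arr.tobytes()))

    with open(path, "wb") as fh:
        fh.write(PREAMBLE + MAGIC + meta + b"".join(body))
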