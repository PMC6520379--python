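"""Minimal DICOM codec (explicit VR, little endian, single-frame MR images).

Supports exactly what this package reads and writes: uncompressed
explicit-VR little-endian files with a standard part-10 preamble and the
small tag set used for cardiac-gated phase-contrast series.  Sequences and
undefined-length elements are not supported.
"""

from __future__ import annotations

import struct
from pathlib import Path

from .errors import MetadataError, StructuralError

TRANSFER_SYNTAX_EXPLICIT_LE = "1.2.840.10008.1.2.1"
MR_SOP_CLASS = "1.2.840.10008.5.1.4.1.1.4"
_UID_ROOT = "1.2.826.0.1.3680043.10.1405"

# VRs whose length field is 4 bytes after a 2-byte reserved gap.
_LONG_VRS = {b"OB", b"OW", b"OF", b"SQ", b"UT", b"UN"}

# Tags used by this package.
MODALITY = (0x0008, 0x0060)
PATIENT_ID = (0x0010, 0x0020)
SEQUENCE_NAME = (0x0018, 0x0024)
TRIGGER_TIME = (0x0018, 0x1060)
NOMINAL_INTERVAL = (0x0018, 0x1062)
SERIES_DESCRIPTION = (0x0008, 0x103E)
INSTANCE_NUMBER = (0x0020, 0x0013)
IMAGE_COMMENTS = (0x0020, 0x4000)
SAMPLES_PER_PIXEL = (0x0028, 0x0002)
PHOTOMETRIC = (0x0028, 0x0004)
ROWS = (0x0028, 0x0010)
COLUMNS = (0x0028, 0x0011)
PIXEL_SPACING = (0x0028, 0x0030)
BITS_ALLOCATED = (0x0028, 0x0100)
BITS_STORED = (0x0028, 0x0101)
HIGH_BIT = (0x0028, 0x0102)
PIXEL_REPRESENTATION = (0x0028, 0x0103)
RESCALE_INTERCEPT = (0x0028, 0x1052)
RESCALE_SLOPE = (0x0028, 0x1053)
PIXEL_DATA = (0x7FE0, 0x0010)


def _pad(data: bytes, pad_byte: bytes) -> bytes:
    return data + pad_byte if len(data) % 2 else data


def _encode_value(vr: str, value) -> bytes:
    if vr in ("CS", "LO", "LT", "SH", "DS", "IS"):
        return _pad(str(value).encode("ascii"), b" ")
    if vr == "UI":
        return _pad(str(value).encode("ascii"), b"\x00")
    if vr == "US":
        return struct.pack("<H", int(value))
    if vr in ("OB", "OW"):
        return _pad(bytes(value), b"\x00")
    raise ValueError(f"unsupported VR for writing: {vr}")


def _element(tag: tuple[int, int], vr: str, value) -> bytes:
    data = _encode_value(vr, value)
    group, elem = tag
    vrb = vr.encode("ascii")
    if vrb in _LONG_VRS:
        return struct.pack("<HH2sHI", group, elem, vrb, 0, len(data)) + data
    return struct.pack("<HH2sH", group, elem, vrb, len(data)) + data


def write_dicom(path: Path, elements: list[tuple[tuple[int, int], str, object]],
                sop_instance_suffix: str) -> None:
    """Write a part-10 explicit-VR-LE file with the given dataset elements.

    `elements` must be sorted by tag; the file meta group is built here.
    """
    sop_uid = f"{_UID_ROOT}.{sop_instance_suffix}"
    meta_body = (
        _element((0x0002, 0x0001), "OB", b"\x00\x01")
        + _element((0x0002, 0x0002), "UI", MR_SOP_CLASS)
        + _element((0x0002, 0x0003), "UI", sop_uid)
        + _element((0x0002, 0x0010), "UI", TRANSFER_SYNTAX_EXPLICIT_LE)
        + _element((0x0002, 0x0012), "UI", _UID_ROOT)
    )
    meta = (
        struct.pack("<HH2sH", 0x0002, 0x0000, b"UL", 4)
        + struct.pack("<I", len(meta_body))
        + meta_body
    )
    body = b"".join(_element(tag, vr, value) for tag, vr, value in elements)
    with open(path, "wb") as fh:
        fh.write(b"\x00" * 128 + b"DICM" + meta + body)


def read_dicom(path: Path) -> dict[tuple[int, int], tuple[str, bytes]]:
    """Parse an explicit-VR-LE part-10 file into {tag: (vr, raw bytes)}."""
    raw = Path(path).read_bytes()
    if len(raw) < 132 or raw[128:132] != b"DICM":
        raise StructuralError(f"{path}: not a part-10 DICOM file (missing DICM marker)")
    pos = 132
    out: dict[tuple[int, int], tuple[str, bytes]] = {}
    n = len(raw)
    while pos + 8 <= n:
        group, elem = struct.unpack_from("<HH", raw, pos)
        vrb = raw[pos + 4:pos + 6]
        if vrb in _LONG_VRS:
            (length,) = struct.unpack_from("<I", raw, pos + 8)
            pos += 12
        else:
            (length,) = struct.unpack_from("<H", raw, pos + 6)
            pos += 8
        if length == 0xFFFFFFFF:
            raise StructuralError(f"{path}: undefined-length element not supported")
        if pos + length > n:
            raise StructuralError(f"{path}: truncated element ({group:04x},{elem:04x})")
        out[(group, elem)] = (vrb.decode("ascii", "replace"), raw[pos:pos + length])
        pos += length
    return out


def get_str(ds: dict, tag: tuple[int, int], field: str, path=None) -> str:
    if tag not in ds:
        where = f" in {path}" if path else ""
        raise MetadataError(f"missing required DICOM field {field} "
                            f"({tag[0]:04x},{tag[1]:04x}){where}")
    return ds[tag][1].decode("ascii").strip(" \x00")


def get_float(ds: dict, tag: tuple[int, int], field: str, path=None) -> float:
    return float(get_str(ds, tag, field, path))


def get_us(ds: dict, tag: tuple[int, int], field: str, path=None) -> int:
    if tag not in ds:
        where = f" in {path}" if path else ""
        raise MetadataError(f"missing required DICOM field {field} "
                            f"({tag[0]:04x},{tag[1]:04x}){where}")
    return struct.unpack("<H", ds[tag][1])[0]
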