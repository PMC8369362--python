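"""Minimal DICOM codec (Explicit VR Little Endian only).

Supports exactly the subset of DICOM this package writes: uncompressed
MONOCHROME2 grayscale, 16-bit unsigned pixels, either multi-frame files or
single-frame series.  Unknown elements are skipped on read, so files written
by other conformant tools are readable as long as they use the Explicit VR
Little Endian transfer syntax and uncompressed pixel data.
"""

from __future__ import annotations

import struct
from pathlib import Path

import numpy as np

TRANSFER_SYNTAX_EXPLICIT_LE = "1.2.840.10008.1.2.1"

# Tags used by this package, (group, element) -> (name, VR)
_TAGS = {
    (0x0008, 0x0060): ("Modality", "CS"),
    (0x0008, 0x103E): ("SeriesDescription", "LO"),
    (0x0010, 0x0020): ("PatientID", "LO"),
    (0x0020, 0x000D): ("StudyInstanceUID", "UI"),
    (0x0020, 0x000E): ("SeriesInstanceUID", "UI"),
    (0x0020, 0x0013): ("InstanceNumber", "IS"),
    (0x0028, 0x0002): ("SamplesPerPixel", "US"),
    (0x0028, 0x0004): ("PhotometricInterpretation", "CS"),
    (0x0028, 0x0008): ("NumberOfFrames", "IS"),
    (0x0028, 0x0010): ("Rows", "US"),
    (0x0028, 0x0011): ("Columns", "US"),
    (0x0028, 0x0100): ("BitsAllocated", "US"),
    (0x0028, 0x0101): ("BitsStored", "US"),
    (0x0028, 0x0102): ("HighBit", "US"),
    (0x0028, 0x0103): ("PixelRepresentation", "US"),
    (0x0028, 0x1050): ("WindowCenter", "DS"),
    (0x0028, 0x1051): ("WindowWidth", "DS"),
    (0x7FE0, 0x0010): ("PixelData", "OW"),
}

# VRs whose explicit form carries a 2-byte reserved field and 4-byte length
_LONG_VRS = {"OB", "OW", "OF", "SQ", "UT", "UN"}
_STRING_VRS = {"CS", "LO", "UI", "IS", "DS", "SH", "PN", "DA", "TM", "AE"}


class DicomFormatError(ValueError):
    """Raised when a file cannot be parsed as supported DICOM."""


def _encode_element(group: int, element: int, vr: str, value) -> bytes:
    if vr == "US":
        payload = struct.pack("<H", int(value))
    elif vr == "OW":
        payload = bytes(value)
    elif vr in _STRING_VRS:
        payload = str(value).encode("ascii")
        if len(payload) % 2:
            payload += b"\x00" if vr == "UI" else b" "
    else:  # pragma: no cover - writer only emits the VRs above
        raise DicomFormatError(f"unsupported VR for writing: {vr}")
    head = struct.pack("<HH", group, element) + vr.encode("ascii")
    if vr in _LONG_VRS:
        return head + b"\x00\x00" + struct.pack("<I", len(payload)) + payload
    return head + struct.pack("<H", len(payload)) + payload


def write_dicom(path: str | Path, elements: dict[str, object], pixels: np.ndarray) -> None:
    """Write ``pixels`` (uint16, 2-D frame or 3-D frame stack) with metadata.

    ``elements`` maps tag names from ``_TAGS`` to values; geometry and pixel
    tags are filled in automatically.
    """
    pixels = np.ascontiguousarray(np.asarray(pixels, dtype="<u2"))
    if pixels.ndim == 2:
        frames, rows, cols = 1, *pixels.shape
    elif pixels.ndim == 3:
        frames, rows, cols = pixels.shape
    else:
        raise DicomFormatError("pixels must be 2-D or 3-D")

    full = dict(elements)
    full.setdefault("Modality", "MG")
    full["SamplesPerPixel"] = 1
    full["PhotometricInterpretation"] = "MONOCHROME2"
    full["Rows"] = rows
    full["Columns"] = cols
    full["BitsAllocated"] = 16
    full["BitsStored"] = 16
    full["HighBit"] = 15
    full["PixelRepresentation"] = 0
    if frames > 1 or pixels.ndim == 3:
        full["NumberOfFrames"] = frames

    name_to_tag = {name: tag for tag, (name, _) in _TAGS.items()}
    body = b""
    for (group, element) in sorted(name_to_tag[n] for n in full):
        name, vr = _TAGS[(group, element)]
        body += _encode_element(group, element, vr, full[name])
    body += _encode_element(0x7FE0, 0x0010, "OW", pixels.tobytes())

    meta = _encode_element(0x0002, 0x0010, "UI", TRANSFER_SYNTAX_EXPLICIT_LE)
    group_len = (
        struct.pack("<HH", 0x0002, 0x0000) + b"UL" + struct.pack("<H", 4)
        + struct.pack("<I", len(meta))
    )
    with open(path, "wb") as fh:
        fh.write(b"\x00" * 128 + b"DICM")
        fh.write(group_len)
        fh.write(meta)
        fh.write(body)


def read_dicom(path: str | Path) -> dict[str, object]:
    """Parse a DICOM file; returns named elements plus a ``pixels`` array."""
    data = Path(path).read_bytes()
    if len(data) > 132 and data[128:132] == b"DICM":
        pos = 132
    elif data[:4] == struct.pack("<HH", 0x0002, 0x0000) or data[:4] == struct.pack(
        "<HH", 0x0008, 0x0060
    ):
        pos = 0
    else:
        raise DicomFormatError(f"not a DICOM file: {path}")

    out: dict[str, object] = {}
    n = len(data)
    while pos + 8 <= n:
        group, element = struct.unpack_from("<HH", data, pos)
        vr = data[pos + 4:pos + 6].decode("ascii", errors="replace")
        if vr.isalpha() and vr.isupper():
            if vr in _LONG_VRS:
                (length,) = struct.unpack_from("<I", data, pos + 8)
                pos += 12
            else:
                (length,) = struct.unpack_from("<H", data, pos + 6)
                pos += 8
        else:  # implicit VR fallback
            (length,) = struct.unpack_from("<I", data, pos + 4)
            vr = _TAGS.get((group, element), ("", "UN"))[1]
            pos += 8
        if length == 0xFFFFFFFF:
            raise DicomFormatError("undefined-length elements are not supported")
        raw = data[pos:pos + length]
        if len(raw) < length:
            raise DicomFormatError(f"truncated DICOM element in {path}")
        pos += length
        if group == 0x0002:
            if (group, element) == (0x0002, 0x0010):
                ts = raw.rstrip(b"\x00").decode("ascii")
                if ts != TRANSFER_SYNTAX_EXPLICIT_LE:
                    raise DicomFormatError(f"unsupported transfer syntax {ts}")
            continue
        info = _TAGS.get((group, element))
        if info is None:
            continue
        name, tag_vr = info
        if name == "PixelData":
            out["_pixel_bytes"] = raw
        elif tag_vr == "US":
            out[name] = struct.unpack("<H", raw[:2])[0]
        else:
            text = raw.rstrip(b"\x00 ").decode("ascii")
            if tag_vr == "IS":
                out[name] = int(text)
            elif tag_vr == "DS":
                # multi-valued window tags: take the first value
                out[name] = float(text.split("\\")[0])
            else:
                out[name] = text

    if "_pixel_bytes" in out:
        rows, cols = out.get("Rows"), out.get("Columns")
        if rows is None or cols is None:
            raise DicomFormatError("pixel data without Rows/Columns")
        frames = int(out.get("NumberOfFrames", 1))
        arr = np.frombuffer(out.pop("_pixel_bytes"), dtype="<u2")
        expected = frames * rows * cols
        if arr.size < expected:
            raise DicomFormatError("pixel data shorter than Rows*Columns*Frames")
        arr = arr[:expected].reshape(frames, rows, cols)
        out["pixels"] = arr[0] if frames == 1 and "NumberOfFrames" not in out else arr
    return out
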