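"""Minimal FCS 3.0/3.1 list-mode reader and writer.

Only the subset of the standard that the pipeline consumes is supported:
the TEXT segment (for $PnN channel names and data layout keywords) and an
uncompressed list-mode DATA segment of float ($DATATYPE/F, 32-bit), double
(/D) or integer (/I, 16/32-bit) values. This covers files exported by common
acquisition software in "FCS3.0 float" mode and our own writer; anything
more exotic (analysis segments, bit-packed integers, multi-dataset files)
raises :class:`~cytomito.errors.FormatError`.
"""
from __future__ import annotations

import struct

import numpy as np

from .errors import FormatError

_DELIM = b"/"

_DTYPES = {
    ("F", 32): "f4",
    ("D", 64): "f8",
    ("I", 16): "u2",
    ("I", 32): "u4",
}


def _parse_text(segment: bytes) -> dict[str, str]:
    if not segment:
        raise FormatError("empty TEXT segment")
    delim = segment[:1]
    # Keywords alternate key/value separated by the delimiter byte.
    parts = segment[1:].split(delim)
    if parts and parts[-1] == b"":
        parts = parts[:-1]
    if len(parts) % 2:
        raise FormatError("TEXT segment has an odd number of delimited fields")
    out: dict[str, str] = {}
    for i in range(0, len(parts), 2):
        key = parts[i].decode("utf-8", "replace").strip().upper()
        out[key] = parts[i + 1].decode("utf-8", "replace")
    return out


def read_fcs(path) -> tuple[list[str], np.ndarray, dict[str, str]]:
    """Read an FCS file.

    Returns ``(channel_names, events, keywords)`` where ``events`` is an
    ``(n_events, n_channels)`` float64 array in channel order $P1..$Pn.
    """
    with open(path, "rb") as fh:
        raw = fh.read()
    if len(raw) < 58 or not raw[:3] == b"FCS":
        raise FormatError(f"{path}: not an FCS file")
    version = raw[:6].decode("ascii", "replace")
    if version not in ("FCS3.0", "FCS3.1"):
        raise FormatError(f"{path}: unsupported FCS version {version!r}")
    try:
        text_start = int(raw[10:18])
        text_end = int(raw[18:26])
    except ValueError as exc:
        raise FormatError(f"{path}: malformed HEADER offsets") from exc
    text = _parse_text(raw[text_start : text_end + 1])

    try:
        n_par = int(text["$PAR"])
        n_tot = int(text["$TOT"])
        datatype = text["$DATATYPE"].strip().upper()
        byteord = text["$BYTEORD"].strip()
        data_start = int(text.get("$BEGINDATA") or raw[26:34])
        data_end = int(text.get("$ENDDATA") or raw[34:42])
    except (KeyError, ValueError) as exc:
        raise FormatError(f"{path}: missing or malformed required keyword ({exc})")
    if text.get("$MODE", "L").strip().upper() != "L":
        raise FormatError(f"{path}: only list mode ($MODE/L) is supported")

    bits = {int(text[f"$P{i}B"]) for i in range(1, n_par + 1) if f"$P{i}B" in text}
    if len(bits) != 1:
        raise FormatError(f"{path}: mixed or missing $PnB bit widths {bits}")
    nbits = bits.pop()
    key = (datatype, nbits)
    if key not in _DTYPES:
        raise FormatError(f"{path}: unsupported $DATATYPE/{datatype} at {nbits} bits")
    endian = "<" if byteord.startswith("1") else ">"
    dtype = np.dtype(endian + _DTYPES[key])

    names = [
        text.get(f"$P{i}N", f"P{i}").strip() for i in range(1, n_par + 1)
    ]
    buf = raw[data_start : data_end + 1]
    need = n_tot * n_par * dtype.itemsize
    if len(buf) < need:
        raise FormatError(f"{path}: DATA segment truncated ({len(buf)} < {need} bytes)")
    events = (
        np.frombuffer(buf[:need], dtype=dtype)
        .reshape(n_tot, n_par)
        .astype(np.float64)
    )
    return names, events, text


def write_fcs(path, channel_names: list[str], events: np.ndarray) -> None:
    """Write a minimal FCS 3.0 file (float32 list mode, little-endian)."""
    events = np.asarray(events, dtype="<f4")
    if events.ndim != 2 or events.shape[1] != len(channel_names):
        raise ValueError("events must be (n_events, n_channels)")
    n_tot, n_par = events.shape
    data = events.tobytes()

    def build_text(begindata: int, enddata: int) -> bytes:
        kw = {
            "$BEGINANALYSIS": "0",
            "$ENDANALYSIS": "0",
            "$BEGINSTEXT": "0",
            "$ENDSTEXT": "0",
            "$BEGINDATA": str(begindata),
            "$ENDDATA": str(enddata),
            "$DATATYPE": "F",
            "$MODE": "L",
            "$BYTEORD": "1,2,3,4",
            "$NEXTDATA": "0",
            "$PAR": str(n_par),
            "$TOT": str(n_tot),
        }
        for i, name in enumerate(channel_names, start=1):
            kw[f"$P{i}N"] = name
            kw[f"$P{i}B"] = "32"
            kw[f"$P{i}E"] = "0,0"
            kw[f"$P{i}R"] = str(int(max(float(events[:, i - 1].max(initial=0.0)), 1)) + 1)
        out = _DELIM
        for k, v in kw.items():
            if _DELIM in k.encode() or _DELIM in str(v).encode():
                raise ValueError("delimiter character in keyword")
            out += k.encode() + _DELIM + str(v).encode() + _DELIM
        return out

    header_len = 58
    # Offsets depend on TEXT length, which depends on the offsets; the digit
    # count stabilises after a couple of passes.
    begindata = header_len + 1000
    for _ in range(8):
        text = build_text(begindata, begindata + len(data) - 1)
        new_begin = header_len + len(text)
        if new_begin == begindata:
            break
        begindata = new_begin
    text = build_text(begindata, begindata + len(data) - 1)
    text_start = header_len
    text_end = text_start + len(text) - 1
    data_end = begindata + len(data) - 1
    if data_end > 99_999_999:
        data_off = (0, 0)  # too large for header field; TEXT keywords carry offsets
    else:
        data_off = (begindata, data_end)
    header = (
        b"FCS3.0    "
        + f"{text_start:>8d}".encode()
        + f"{text_end:>8d}".encode()
        + f"{data_off[0]:>8d}".encode()
        + f"{data_off[1]:>8d}".encode()
        + f"{0:>8d}".encode()
        + f"{0:>8d}".encode()
    )
    assert len(header) == header_len
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(text)
        fh.write(data)
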