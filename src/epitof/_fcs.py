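"""Minimal FCS 3.0/3.1 reader and writer.

Supports list-mode ($MODE L) files with float ($DATATYPE F/D) or integer
($DATATYPE I, byte-aligned widths) data — the shape exported by cytometry
acquisition/gating software. The writer emits single-precision list-mode
files and exists mainly so tests and examples can build fixtures in code.
"""

from __future__ import annotations

import struct
from pathlib import Path

import numpy as np

_DELIM = b"/"


class FcsError(IOError):
    """The file is not a readable FCS 3.0/3.1 list-mode file."""


def read_fcs(path: str | Path) -> tuple[dict, np.ndarray, list[str]]:
    """Read an FCS file.

    Returns ``(text, data, channel_names)`` where ``text`` is the TEXT
    segment keyword dict, ``data`` is an (events x channels) float array
    and ``channel_names`` are the $PnN short names in channel order.
    """
    raw = Path(path).read_bytes()
    if len(raw) < 58 or not raw[:6] in (b"FCS3.0", b"FCS3.1"):
        raise FcsError(f"{path}: not an FCS 3.0/3.1 file")
    try:
        text_begin = int(raw[10:18])
        text_end = int(raw[18:26])
    except ValueError as exc:  # pragma: no cover - malformed header
        raise FcsError(f"{path}: malformed FCS header") from exc
    text = _parse_text(raw[text_begin:text_end + 1])

    data_begin = int(text.get("$BEGINDATA", raw[26:34] or 0))
    data_end = int(text.get("$ENDDATA", raw[34:42] or 0))
    if data_begin == 0:
        data_begin = int(raw[26:34])
        data_end = int(raw[34:42])

    n_par = int(text["$PAR"])
    n_tot = int(text["$TOT"])
    names = [text.get(f"$P{i}N", f"P{i}") for i in range(1, n_par + 1)]
    if n_tot == 0:
        return text, np.empty((0, n_par), dtype=float), names

    order = text.get("$BYTEORD", "1,2,3,4")
    little = order.startswith("1")
    datatype = text.get("$DATATYPE", "F").upper()
    if text.get("$MODE", "L").upper() != "L":
        raise FcsError(f"{path}: only list-mode ($MODE L) data is supported")

    buf = raw[data_begin:data_end + 1]
    if datatype == "F":
        dtype = np.dtype("<f4" if little else ">f4")
    elif datatype == "D":
        dtype = np.dtype("<f8" if little else ">f8")
    elif datatype == "I":
        bits = {int(text.get(f"$P{i}B", 32)) for i in range(1, n_par + 1)}
        if len(bits) != 1 or bits.pop() not in (8, 16, 32):
            raise FcsError(f"{path}: unsupported integer channel widths")
        width = int(text.get("$P1B", 32)) // 8
        dtype = np.dtype(("<" if little else ">") + f"u{width}")
    else:
        raise FcsError(f"{path}: unsupported $DATATYPE {datatype!r}")

    need = n_tot * n_par * dtype.itemsize
    if len(buf) < need:
        raise FcsError(f"{path}: DATA segment truncated")
    data = np.frombuffer(buf[:need], dtype=dtype).astype(float).reshape(n_tot, n_par)
    return text, data, names


def write_fcs(path: str | Path, data: np.ndarray, channel_names: list[str]) -> None:
    """Write a single-precision little-endian list-mode FCS 3.1 file."""
    data = np.asarray(data, dtype="<f4")
    if data.ndim != 2 or data.shape[1] != len(channel_names):
        raise ValueError("data must be (events x channels) matching channel_names")
    n_tot, n_par = data.shape
    payload = data.tobytes()

    def kv(pairs: dict) -> bytes:
        out = _DELIM
        for k, v in pairs.items():
            out += k.encode() + _DELIM + str(v).encode() + _DELIM
        return out

    base = {
        "$DATATYPE": "F", "$MODE": "L", "$BYTEORD": "1,2,3,4",
        "$PAR": n_par, "$TOT": n_tot, "$NEXTDATA": 0,
    }
    for i, name in enumerate(channel_names, start=1):
        base[f"$P{i}N"] = name
        base[f"$P{i}B"] = 32
        base[f"$P{i}R"] = 262144
        base[f"$P{i}E"] = "0,0"

    # Offsets appear inside TEXT, whose length depends on their digit
    # count — iterate to the fixed point.
    header_len = 58
    text_begin = header_len
    data_begin = 0
    for _ in range(6):
        text_bytes = kv(base | {"$BEGINDATA": data_begin,
                                "$ENDDATA": data_begin + len(payload) - 1})
        new_begin = text_begin + len(text_bytes)
        if new_begin == data_begin:
            break
        data_begin = new_begin
    data_end = data_begin + len(payload) - 1
    text_end = text_begin + len(text_bytes) - 1
    header = b"FCS3.1    " + b"".join(
        f"{v:8d}".encode() for v in
        (text_begin, text_end,
         data_begin if data_end < 10**8 else 0,
         data_end if data_end < 10**8 else 0, 0, 0)
    )
    assert len(header) == header_len
    Path(path).write_bytes(header + text_bytes + payload)


def _parse_text(segment: bytes) -> dict:
    if not segment:
        raise FcsError("empty TEXT segment")
    delim = segment[0:1]
    parts = segment[1:].split(delim)
    if parts and parts[-1] in (b"", b" "):
        parts = parts[:-1]
    if len(parts) % 2 != 0:
        parts = parts[: len(parts) - 1]
    out = {}
    for i in range(0, len(parts), 2):
        out[parts[i].decode("latin-1").strip().upper()] = parts[i + 1].decode("latin-1")
    return out
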