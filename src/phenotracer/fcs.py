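"""Minimal FCS 3.0/3.1 reading and writing.

Covers the subset of the standard that list-mode cytometry exports use:
float32 ("$DATATYPE/F") or float64 ("D") list-mode ("$MODE/L") data with a
uniform byte order. The writer emits valid single-segment FCS 3.0 files and
exists chiefly to produce fixtures; no installed package reads FCS, so the
reader is implemented here.
"""

from __future__ import annotations

import struct
from pathlib import Path

import numpy as np

_DELIM = b"/"


def _parse_text_segment(raw: bytes) -> dict[str, str]:
    delim = raw[:1]
    parts = raw[1:].split(delim)
    # trailing empty chunk from the closing delimiter
    if parts and parts[-1] == b"":
        parts = parts[:-1]
    if len(parts) % 2 != 0:
        raise ValueError("malformed FCS TEXT segment (odd keyword count)")
    return {
        parts[i].decode("utf-8", "replace").strip(): parts[i + 1].decode(
            "utf-8", "replace"
        )
        for i in range(0, len(parts), 2)
    }


def read_fcs(path) -> tuple[np.ndarray, list[str], dict[str, str]]:
    """Read an FCS 3.0/3.1 file -> (events x channels array, names, keywords).

    Channel names prefer $PnS (stain/label) over $PnN (short name).
    """
    raw = Path(path).read_bytes()
    if len(raw) < 58:
        raise ValueError("truncated FCS file: header incomplete")
    version = raw[:6].decode("ascii", "replace")
    if not version.startswith("FCS3"):
        raise ValueError(f"unsupported FCS version {version!r}")

    def _offset(lo, hi):
        return int(raw[lo:hi].decode("ascii").strip() or 0)

    text_start, text_end = _offset(10, 18), _offset(18, 26)
    if text_end >= len(raw):
        raise ValueError("truncated FCS file: TEXT segment out of range")
    kw = _parse_text_segment(raw[text_start : text_end + 1])

    data_start = int(kw.get("$BEGINDATA", 0)) or _offset(26, 34)
    data_end = int(kw.get("$ENDDATA", 0)) or _offset(34, 42)
    n_par = int(kw["$PAR"])
    n_tot = int(kw["$TOT"])
    dtype_code = kw.get("$DATATYPE", "F").upper()
    if dtype_code not in ("F", "D"):
        raise ValueError(f"unsupported $DATATYPE {dtype_code!r}")
    if kw.get("$MODE", "L").upper() != "L":
        raise ValueError("only list-mode ($MODE/L) FCS is supported")
    byteord = kw.get("$BYTEORD", "1,2,3,4")
    little = byteord.startswith("1")
    np_dtype = ("<" if little else ">") + ("f4" if dtype_code == "F" else "f8")

    itemsize = 4 if dtype_code == "F" else 8
    need = n_par * n_tot * itemsize
    if data_end - data_start + 1 < need or data_start + need > len(raw):
        raise ValueError("truncated FCS file: DATA segment shorter than $PAR*$TOT")
    data = np.frombuffer(raw[data_start : data_start + need], dtype=np_dtype)
    values = data.reshape(n_tot, n_par).astype(float)

    names = []
    for i in range(1, n_par + 1):
        names.append(kw.get(f"$P{i}S") or kw.get(f"$P{i}N") or f"P{i}")
    return values, names, kw


def write_fcs(path, values: np.ndarray, channel_names: list[str]) -> None:
    """Write a minimal single-dataset FCS 3.0 file with float32 data."""
    values = np.ascontiguousarray(values, dtype="<f4")
    n_tot, n_par = values.shape
    if len(channel_names) != n_par:
        raise ValueError("one channel name per column required")

    data_bytes = values.tobytes()

    def build_text(begin_data: int, end_data: int) -> bytes:
        pairs = [
            ("$DATATYPE", "F"),
            ("$MODE", "L"),
            ("$BYTEORD", "1,2,3,4"),
            ("$PAR", str(n_par)),
            ("$TOT", str(n_tot)),
            ("$BEGINANALYSIS", "0"),
            ("$ENDANALYSIS", "0"),
            ("$BEGINSTEXT", "0"),
            ("$ENDSTEXT", "0"),
            ("$BEGINDATA", str(begin_data)),
            ("$ENDDATA", str(end_data)),
        ]
        for i, name in enumerate(channel_names, start=1):
            rng = max(1.0, float(np.max(values[:, i - 1], initial=1.0)))
            pairs += [
                (f"$P{i}N", name),
                (f"$P{i}S", name),
                (f"$P{i}B", "32"),
                (f"$P{i}E", "0,0"),
                (f"$P{i}R", str(int(np.ceil(rng)) + 1)),
            ]
        out = _DELIM
        for k, v in pairs:
            out += k.encode() + _DELIM + v.encode() + _DELIM
        return out

    header_len = 58
    # iterate: text length depends on the data offsets it encodes
    begin_data = 0
    for _ in range(4):
        text = build_text(begin_data, begin_data + len(data_bytes) - 1)
        new_begin = header_len + len(text)
        if new_begin == begin_data:
            break
        begin_data = new_begin
    text = build_text(begin_data, begin_data + len(data_bytes) - 1)
    text_start = header_len
    text_end = text_start + len(text) - 1
    header = b"FCS3.0    " + b"".join(
        struct.pack(">8s", str(v).rjust(8).encode())
        for v in (
            text_start,
            text_end,
            begin_data,
            begin_data + len(data_bytes) - 1,
            0,
            0,
        )
    )
    assert len(header) == header_len
    Path(path).write_bytes(header + text + data_bytes)
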