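"""Minimal FCS 3.1 list-mode reader and writer.

Supports the subset of the flow-cytometry standard this pipeline needs:
list-mode ($MODE L) single-dataset files with float ($DATATYPE F/D) or
integer ($DATATYPE I, byte-aligned widths) parameters and little- or
big-endian byte order.  Written files use FCS3.1, float32 data, one TEXT
segment, and no ANALYSIS segment.
"""

from __future__ import annotations

import struct
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["read_fcs", "write_fcs", "FcsFormatError"]

_DELIM = "/"


class FcsFormatError(ValueError):
    """File does not conform to the supported FCS subset."""


def write_fcs(df: pd.DataFrame, path: str | Path, channels: list[str] | None = None) -> None:
    """Write an event table as an FCS 3.1 file (float32, little-endian)."""
    channels = channels or list(df.columns)
    data = np.ascontiguousarray(df[channels].to_numpy(dtype="<f4"))
    n_events, n_par = data.shape

    keywords: dict[str, str] = {
        "$BEGINANALYSIS": "0",
        "$ENDANALYSIS": "0",
        "$BEGINSTEXT": "0",
        "$ENDSTEXT": "0",
        "$BYTEORD": "1,2,3,4",
        "$DATATYPE": "F",
        "$MODE": "L",
        "$NEXTDATA": "0",
        "$TOT": str(n_events),
        "$PAR": str(n_par),
    }
    for i, name in enumerate(channels, start=1):
        keywords[f"$P{i}N"] = name
        keywords[f"$P{i}B"] = "32"
        keywords[f"$P{i}E"] = "0,0"
        keywords[f"$P{i}R"] = str(int(np.ceil(max(float(data[:, i - 1].max(), ), 1.0))) + 1)

    header_len = 58
    data_bytes = data.tobytes()

    # iterate: the BEGINDATA/ENDDATA values change the TEXT length
    begin_data = 0
    for _ in range(8):
        kw = dict(keywords)
        kw["$BEGINDATA"] = str(begin_data)
        kw["$ENDDATA"] = str(begin_data + len(data_bytes) - 1 if begin_data else 0)
        text = _DELIM + _DELIM.join(f"{k}{_DELIM}{v}" for k, v in kw.items()) + _DELIM
        text_bytes = text.encode("ascii")
        new_begin = header_len + len(text_bytes)
        if new_begin == begin_data:
            break
        begin_data = new_begin
    end_data = begin_data + len(data_bytes) - 1

    kw = dict(keywords)
    kw["$BEGINDATA"] = str(begin_data)
    kw["$ENDDATA"] = str(end_data)
    text_bytes = (_DELIM + _DELIM.join(f"{k}{_DELIM}{v}" for k, v in kw.items()) + _DELIM).encode(
        "ascii"
    )
    text_start = header_len
    text_end = text_start + len(text_bytes) - 1

    def _off(v: int) -> bytes:
        s = str(v)
        if len(s) > 8:
            s = "0"  # out-of-header-range offsets are carried in TEXT only
        return s.rjust(8).encode("ascii")

    header = b"FCS3.1    " + _off(text_start) + _off(text_end) + _off(begin_data) + _off(
        end_data
    ) + _off(0) + _off(0)
    assert len(header) == 58
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(text_bytes)
        fh.write(data_bytes)


def _parse_text(raw: bytes) -> dict[str, str]:
    if not raw:
        raise FcsFormatError("empty TEXT segment")
    delim = chr(raw[0])
    parts = raw.decode("latin-1").split(delim)[1:-1]
    if len(parts) % 2:
        parts = parts[:-1]
    return {k.strip().upper(): v for k, v in zip(parts[::2], parts[1::2])}


def read_fcs(path: str | Path) -> pd.DataFrame:
    """Read a list-mode FCS 3.0/3.1 file into a DataFrame of events."""
    blob = Path(path).read_bytes()
    if not blob[:3] == b"FCS":
        raise FcsFormatError(f"{path}: not an FCS file")

    def _int(slice_: bytes) -> int:
        s = slice_.decode("ascii").strip()
        return int(s) if s else 0

    text_start, text_end = _int(blob[10:18]), _int(blob[18:26])
    data_start, data_end = _int(blob[26:34]), _int(blob[34:42])
    kw = _parse_text(blob[text_start : text_end + 1])
    if data_start == 0:
        data_start = int(kw["$BEGINDATA"])
        data_end = int(kw["$ENDDATA"])
    if kw.get("$MODE", "L").upper() != "L":
        raise FcsFormatError("only list-mode ($MODE L) files are supported")

    n_par = int(kw["$PAR"])
    n_events = int(kw["$TOT"])
    dtype_code = kw["$DATATYPE"].upper()
    byteord = kw.get("$BYTEORD", "1,2,3,4")
    endian = "<" if byteord.startswith("1") else ">"
    names = [kw.get(f"$P{i}N", f"P{i}") for i in range(1, n_par + 1)]
    widths = [int(kw.get(f"$P{i}B", "32")) for i in range(1, n_par + 1)]

    raw = blob[data_start : data_end + 1]
    if dtype_code == "F":
        arr = np.frombuffer(raw, dtype=f"{endian}f4", count=n_events * n_par)
    elif dtype_code == "D":
        arr = np.frombuffer(raw, dtype=f"{endian}f8", count=n_events * n_par)
    elif dtype_code == "I":
        if len(set(widths)) != 1 or widths[0] not in (8, 16, 32, 64):
            raise FcsFormatError("integer data requires one byte-aligned width")
        arr = np.frombuffer(raw, dtype=f"{endian}u{widths[0] // 8}", count=n_events * n_par)
    else:
        raise FcsFormatError(f"unsupported $DATATYPE {dtype_code!r}")
    df = pd.DataFrame(arr.reshape(n_events, n_par).astype(float), columns=names)
    df.attrs["fcs_keywords"] = kw
    return df
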