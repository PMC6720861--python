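"""Minimal FCS 3.1 writer/reader for single-cell cytometry export.

One FCS *event* per segmented cell, one *parameter* per numeric feature.
Data are stored in list mode as little-endian float32 with no
transformations, the most broadly readable layout.  Only the subset of the
standard needed for round-tripping our own tables is implemented: a fixed
58-byte header, a single slash-delimited TEXT segment, and one DATA segment.
"""

from __future__ import annotations

import os
import re
from typing import Sequence

import numpy as np

_DELIM = "/"
_HEADER_LEN = 58


def _escape(value: str) -> str:
    return value.replace(_DELIM, _DELIM * 2)


def _sanitize_name(name: str) -> str:
    # the TEXT delimiter may not appear unescaped in parameter names
    return name.replace(_DELIM, "_")


def write_fcs(
    path: str | os.PathLike,
    parameter_names: Sequence[str],
    data: np.ndarray,
) -> None:
    """Write an (events, parameters) float array as an FCS 3.1 file."""
    data = np.asarray(data, dtype="<f4")
    if data.ndim != 2:
        raise ValueError(f"data must be 2-D (events, parameters), got {data.shape}")
    n_events, n_par = data.shape
    if n_par != len(parameter_names):
        raise ValueError(
            f"{len(parameter_names)} names for {n_par} data columns"
        )

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
    for i, name in enumerate(parameter_names, start=1):
        keywords[f"$P{i}N"] = _sanitize_name(str(name))
        keywords[f"$P{i}B"] = "32"
        keywords[f"$P{i}E"] = "0,0"
        col_max = float(np.max(data[:, i - 1])) if n_events else 0.0
        keywords[f"$P{i}R"] = str(int(max(col_max, 1)) + 1)

    payload = data.tobytes()

    # offsets appear inside TEXT, so settle them by fixed-point iteration
    begin_data, end_data = 0, 0
    for _ in range(3):
        kw = dict(keywords)
        kw["$BEGINDATA"] = str(begin_data)
        kw["$ENDDATA"] = str(end_data)
        text = _DELIM + _DELIM.join(
            f"{_escape(k)}{_DELIM}{_escape(v)}" for k, v in kw.items()
        ) + _DELIM
        text_bytes = text.encode("ascii")
        new_begin = _HEADER_LEN + len(text_bytes)
        new_end = new_begin + len(payload) - 1 if payload else new_begin
        if (new_begin, new_end) == (begin_data, end_data):
            break
        begin_data, end_data = new_begin, new_end

    text_begin = _HEADER_LEN
    text_end = text_begin + len(text_bytes) - 1

    def field(v: int) -> bytes:
        s = str(v)
        if len(s) > 8:
            s = "0"  # too large for the header; TEXT keywords carry it
        return s.rjust(8).encode("ascii")

    header = b"FCS3.1    " + b"".join(
        field(v) for v in (
            text_begin, text_end,
            begin_data if begin_data <= 99999999 else 0,
            end_data if end_data <= 99999999 else 0,
            0, 0,
        )
    )
    assert len(header) == _HEADER_LEN
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(text_bytes)
        fh.write(payload)


def read_fcs(path: str | os.PathLike) -> tuple[list[str], np.ndarray]:
    """Read an FCS file written by :func:`write_fcs` (float32 list mode).

    Returns (parameter names, (events, parameters) float32 array).
    """
    with open(path, "rb") as fh:
        raw = fh.read()
    if not raw.startswith(b"FCS3"):
        raise ValueError(f"{path}: not an FCS 3.x file")
    text_begin = int(raw[10:18])
    text_end = int(raw[18:26])
    text = raw[text_begin:text_end + 1].decode("ascii")
    delim = text[0]
    # split on single delimiters; doubled delimiters are escapes
    d = re.escape(delim)
    parts = re.split(rf"(?<!{d}){d}(?!{d})",
                     text[1:-1] if text.endswith(delim) else text[1:])
    parts = [p.replace(delim * 2, delim) for p in parts]
    kw = {parts[i]: parts[i + 1] for i in range(0, len(parts) - 1, 2)}

    n_events = int(kw["$TOT"])
    n_par = int(kw["$PAR"])
    if kw.get("$DATATYPE", "F") != "F":
        raise ValueError("only $DATATYPE F is supported")
    byteord = kw.get("$BYTEORD", "1,2,3,4")
    endian = "<" if byteord.startswith("1") else ">"
    begin_data = int(kw.get("$BEGINDATA") or raw[26:34])
    names = [kw.get(f"$P{i}N", f"P{i}") for i in range(1, n_par + 1)]
    count = n_events * n_par
    data = np.frombuffer(raw, dtype=f"{endian}f4", count=count,
                         offset=begin_data).reshape(n_events, n_par)
    return names, np.ascontiguousarray(data)
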