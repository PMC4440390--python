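"""Minimal FCS 3.1 list-mode writer and reader.

Writes one DATA segment of 32-bit little-endian floats ($DATATYPE/F/,
$MODE/L/), one event per table row and one parameter per column — the
layout every cytometry package reads.  The reader understands exactly
what the writer produces (plus byte-order variants) and is meant for
round-trip verification, not as a general FCS parser.
"""

from __future__ import annotations

import re
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["write_fcs", "read_fcs", "sanitize_parameter_names"]

_DELIM = "/"
_HEADER_LEN = 58


def sanitize_parameter_names(names: list[str]) -> list[str]:
    """Deterministic ASCII-safe, delimiter-free, unique parameter names."""
    out: list[str] = []
    seen: set[str] = set()
    for i, name in enumerate(names):
        clean = re.sub(r"[^A-Za-z0-9_\-. ]", "_", str(name)).strip()
        clean = re.sub(r"_+", "_", clean)
        if not clean:
            clean = f"P{i + 1}"
        if clean != str(name):
            warnings.warn(
                f"FCS parameter name {name!r} sanitized to {clean!r}",
                stacklevel=3,
            )
        base, k = clean, 2
        while clean in seen:
            clean = f"{base}_{k}"
            k += 1
        seen.add(clean)
        out.append(clean)
    return out


def write_fcs(table: pd.DataFrame, path: str | Path) -> None:
    """Write a per-event parameter table as an FCS 3.1 file."""
    if len(table) == 0 or table.shape[1] == 0:
        raise ValueError("cannot write an empty event table")
    names = sanitize_parameter_names([str(c) for c in table.columns])
    data = np.ascontiguousarray(table.to_numpy(dtype="<f4"))
    n_events, n_par = data.shape

    keywords: list[tuple[str, str]] = [
        ("$BEGINANALYSIS", "0"),
        ("$ENDANALYSIS", "0"),
        ("$BEGINSTEXT", "0"),
        ("$ENDSTEXT", "0"),
        ("$BEGINDATA", "%010d"),
        ("$ENDDATA", "%010d"),
        ("$BYTEORD", "1,2,3,4"),
        ("$DATATYPE", "F"),
        ("$MODE", "L"),
        ("$NEXTDATA", "0"),
        ("$TOT", str(n_events)),
        ("$PAR", str(n_par)),
    ]
    for i, name in enumerate(names, start=1):
        col = data[:, i - 1]
        rng_max = float(np.nanmax(col)) if np.isfinite(col).any() else 1.0
        keywords += [
            (f"$P{i}N", name),
            (f"$P{i}B", "32"),
            (f"$P{i}E", "0,0"),
            (f"$P{i}R", str(int(np.ceil(max(rng_max, 1.0))) + 1)),
        ]

    def render(begin_data: int, end_data: int) -> bytes:
        parts = [_DELIM]
        for key, val in keywords:
            if val == "%010d":
                val = "%010d" % (begin_data if key == "$BEGINDATA" else end_data)
            parts.append(f"{key}{_DELIM}{val}{_DELIM}")
        return "".join(parts).encode("ascii")

    text = render(0, 0)  # placeholders are fixed-width: length is final
    text_start = _HEADER_LEN
    text_end = text_start + len(text) - 1
    data_start = text_start + len(text)
    data_end = data_start + data.nbytes - 1
    text = render(data_start, data_end)

    header = (
        b"FCS3.1    "
        + b"%8d%8d%8d%8d%8d%8d"
        % (text_start, text_end, data_start, data_end, 0, 0)
    )
    assert len(header) == _HEADER_LEN
    Path(path).write_bytes(header + text + data.tobytes())


def read_fcs(path: str | Path) -> tuple[pd.DataFrame, dict]:
    """Read an FCS file written by :func:`write_fcs`.

    Returns the event table (float32 values) and the TEXT-segment
    keyword dictionary.
    """
    raw = Path(path).read_bytes()
    if not raw[:6].startswith(b"FCS3"):
        raise ValueError(f"{path}: not an FCS 3.x file")
    offsets = [int(raw[10 + 8 * i : 18 + 8 * i]) for i in range(4)]
    text_start, text_end, data_start, data_end = offsets
    text = raw[text_start : text_end + 1].decode("ascii")
    delim = text[0]
    tokens = text.strip(delim).split(delim)
    meta = dict(zip(tokens[::2], tokens[1::2]))
    if meta.get("$DATATYPE") != "F" or meta.get("$MODE") != "L":
        raise ValueError(f"{path}: only list-mode float FCS data is supported")
    if data_start == 0:
        data_start = int(meta["$BEGINDATA"])
        data_end = int(meta["$ENDDATA"])
    n_par = int(meta["$PAR"])
    n_tot = int(meta["$TOT"])
    dtype = "<f4" if meta.get("$BYTEORD", "1,2,3,4") == "1,2,3,4" else ">f4"
    data = np.frombuffer(
        raw[data_start : data_end + 1], dtype=dtype, count=n_par * n_tot
    ).reshape(n_tot, n_par)
    names = [meta.get(f"$P{i}N", f"P{i}") for i in range(1, n_par + 1)]
    return pd.DataFrame(data.astype("<f4"), columns=names), meta
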