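"""Minimal FCS 3.1 reader/writer for list-mode floating-point data.

Covers the subset of the FCS standard this pipeline produces and
consumes: a single dataset, ``$MODE L``, ``$DATATYPE F`` or ``D``,
little- or big-endian ``$BYTEORD``, with channel names in ``$PnN`` and an
optional ``$SPILLOVER`` keyword. It is not a general-purpose FCS
implementation (no analysis segments, no integer data, no multi-dataset
files).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

_DELIM = "/"
_HEADER_LEN = 58
_OFFSET_WIDTH = 10  # zero-padded offsets inside TEXT keep its length fixed


def write_fcs(
    path: str | Path,
    data: pd.DataFrame,
    extra_keywords: dict[str, str] | None = None,
) -> None:
    """Write an events x channels table as an FCS 3.1 file (float32)."""
    path = Path(path)
    values = np.ascontiguousarray(data.values, dtype="<f4")
    n_events, n_par = values.shape

    keywords: dict[str, str] = {
        "$BEGINANALYSIS": "0",
        "$ENDANALYSIS": "0",
        "$BEGINSTEXT": "0",
        "$ENDSTEXT": "0",
        "$BEGINDATA": "0" * _OFFSET_WIDTH,
        "$ENDDATA": "0" * _OFFSET_WIDTH,
        "$BYTEORD": "1,2,3,4",
        "$DATATYPE": "F",
        "$MODE": "L",
        "$NEXTDATA": "0",
        "$PAR": str(n_par),
        "$TOT": str(n_events),
    }
    for i, name in enumerate(data.columns, start=1):
        if _DELIM in str(name):
            raise ValueError(f"channel name {name!r} contains the TEXT delimiter")
        keywords[f"$P{i}N"] = str(name)
        keywords[f"$P{i}B"] = "32"
        keywords[f"$P{i}E"] = "0,0"
        keywords[f"$P{i}R"] = str(int(max(float(values[:, i - 1].max(), ), 1.0)) + 1)
    if extra_keywords:
        keywords.update(extra_keywords)

    def render(kw: dict[str, str]) -> bytes:
        parts = [_DELIM]
        for k, v in kw.items():
            parts.append(f"{k}{_DELIM}{v}{_DELIM}")
        return "".join(parts).encode("ascii")

    text = render(keywords)
    text_begin = _HEADER_LEN
    text_end = text_begin + len(text) - 1
    data_begin = text_end + 1
    data_end = data_begin + values.nbytes - 1
    keywords["$BEGINDATA"] = str(data_begin).zfill(_OFFSET_WIDTH)
    keywords["$ENDDATA"] = str(data_end).zfill(_OFFSET_WIDTH)
    text = render(keywords)
    assert text_begin + len(text) - 1 == text_end  # offsets stayed fixed-width

    header = b"FCS3.1    " + "".join(
        f"{off:>8d}"
        for off in (text_begin, text_end, data_begin, data_end, 0, 0)
    ).encode("ascii")
    assert len(header) == _HEADER_LEN

    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(text)
        fh.write(values.tobytes())


def read_fcs(path: str | Path) -> tuple[pd.DataFrame, dict[str, str]]:
    """Read an FCS 3.0/3.1 list-mode file; returns (events table, keywords)."""
    raw = Path(path).read_bytes()
    if not raw[:6] in (b"FCS3.0", b"FCS3.1"):
        raise ValueError(f"{path}: not an FCS 3.0/3.1 file")
    text_begin = int(raw[10:18])
    text_end = int(raw[18:26])
    text = raw[text_begin : text_end + 1].decode("ascii", errors="replace")
    delim = text[0]
    tokens = text[1:].split(delim)
    if tokens and tokens[-1] == "":
        tokens = tokens[:-1]
    if len(tokens) % 2:
        raise ValueError(f"{path}: malformed TEXT segment")
    keywords = {tokens[i]: tokens[i + 1] for i in range(0, len(tokens), 2)}

    if keywords.get("$MODE", "L") != "L":
        raise ValueError(f"{path}: only list mode ($MODE L) is supported")
    dtype_char = keywords.get("$DATATYPE", "F")
    if dtype_char not in ("F", "D"):
        raise ValueError(f"{path}: unsupported $DATATYPE {dtype_char!r}")
    byteord = keywords.get("$BYTEORD", "1,2,3,4")
    endian = "<" if byteord.startswith("1") else ">"
    dtype = np.dtype(f"{endian}f{4 if dtype_char == 'F' else 8}")

    n_par = int(keywords["$PAR"])
    n_tot = int(keywords["$TOT"])
    data_begin = int(keywords.get("$BEGINDATA") or raw[26:34])
    data_end = int(keywords.get("$ENDDATA") or raw[34:42])
    buf = raw[data_begin : data_end + 1]
    values = np.frombuffer(buf, dtype=dtype, count=n_par * n_tot).reshape(n_tot, n_par)
    names = [keywords.get(f"$P{i}N", f"P{i}") for i in range(1, n_par + 1)]
    return pd.DataFrame(np.asarray(values, float), columns=names), keywords


def spillover_keyword(detectors: list[str], matrix: np.ndarray) -> str:
    """Encode a spillover matrix as the FCS $SPILLOVER keyword value."""
    n = len(detectors)
    cells = ",".join(f"{v:.10g}" for v in np.asarray(matrix, float).ravel())
    return f"{n},{','.join(detectors)},{cells}"


def parse_spillover_keyword(value: str):
    """Decode a $SPILLOVER keyword into (detectors, matrix)."""
    parts = value.split(",")
    n = int(parts[0])
    detectors = parts[1 : 1 + n]
    cells = np.array([float(x) for x in parts[1 + n :]])
    if cells.size != n * n:
        raise ValueError("malformed $SPILLOVER keyword")
    return detectors, cells.reshape(n, n)
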