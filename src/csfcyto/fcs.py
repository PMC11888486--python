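"""Minimal FCS 3.0 / 3.1 list-mode reader.

Reads the TEXT segment keywords and a list-mode DATA segment of float32,
float64 or fixed-width integer events, and maps instrument channel names
($PnN / $PnS) onto the analysis panel with an arcsinh transform (cofactor
configurable) applied to fluorescence channels.  This covers plain exports
from conventional cytometers; compensation, bit-masked integers and
multi-dataset files are out of scope.
"""

from __future__ import annotations

import re

import numpy as np
import pandas as pd

from .panel import MarkerPanel, SSC_CHANNEL


def _read_text_segment(raw: bytes, start: int, end: int) -> dict[str, str]:
    text = raw[start:end + 1].decode("ascii", errors="replace")
    delim = text[0]
    # split on single delimiters; doubled delimiters escape a literal one
    parts = [p.replace("\x00", delim) for p in
             text[1:].replace(delim + delim, "\x00").split(delim)]
    if parts and parts[-1] == "":
        parts = parts[:-1]
    if len(parts) % 2:
        parts = parts[:-1]
    return {parts[i].strip().upper(): parts[i + 1]
            for i in range(0, len(parts), 2)}


def read_fcs(path) -> tuple[pd.DataFrame, dict[str, str]]:
    """Return (events frame with $PnN column names, TEXT keyword dict)."""
    with open(path, "rb") as fh:
        raw = fh.read()
    version = raw[:6].decode("ascii", errors="replace")
    if version not in ("FCS3.0", "FCS3.1"):
        raise ValueError(f"unsupported FCS version {version!r}")
    text_start, text_end = int(raw[10:18]), int(raw[18:26])
    data_start, data_end = int(raw[26:34]), int(raw[34:42])
    kw = _read_text_segment(raw, text_start, text_end)
    if data_start == 0:
        data_start = int(kw["$BEGINDATA"])
        data_end = int(kw["$ENDDATA"])

    if kw.get("$MODE", "L").upper() != "L":
        raise ValueError("only list-mode ($MODE/L) FCS data is supported")
    n_par = int(kw["$PAR"])
    n_tot = int(kw["$TOT"])
    datatype = kw["$DATATYPE"].upper()
    byteord = kw["$BYTEORD"].strip()
    endian = "<" if byteord.startswith("1") else ">"
    if datatype == "F":
        dtype = np.dtype(endian + "f4")
    elif datatype == "D":
        dtype = np.dtype(endian + "f8")
    elif datatype == "I":
        bits = {int(kw[f"$P{i}B"]) for i in range(1, n_par + 1)}
        if len(bits) != 1 or bits.pop() not in (16, 32):
            raise ValueError("integer data requires uniform $PnB of 16 or 32")
        width = int(kw["$P1B"]) // 8
        dtype = np.dtype(f"{endian}u{width}")
    else:
        raise ValueError(f"unsupported $DATATYPE {datatype!r}")

    data = np.frombuffer(raw[data_start:data_end + 1], dtype=dtype,
                         count=n_par * n_tot).reshape(n_tot, n_par)
    names = [kw.get(f"$P{i}N", f"P{i}") for i in range(1, n_par + 1)]
    return pd.DataFrame(np.asarray(data, dtype=float), columns=names), kw


def _normalize(name: str) -> str:
    return re.sub(r"[^A-Z0-9]", "", name.upper())


def load_fcs_events(path, panel: MarkerPanel | None = None,
                    arcsinh_cofactor: float = 150.0) -> pd.DataFrame:
    """FCS events mapped onto the panel, arcsinh-transformed.

    Each panel channel is matched against the $PnS stain name first, then
    $PnN (normalized: case and punctuation ignored; an ``SSC*`` detector name
    matches the SSC channel).  Fluorescence channels get
    ``arcsinh(x / cofactor)``; SSC is left on its acquired scale.
    """
    panel = panel or MarkerPanel()
    frame, kw = read_fcs(path)
    n_par = int(kw["$PAR"])
    candidates: dict[str, str] = {}
    for i in range(1, n_par + 1):
        pnn = kw.get(f"$P{i}N", f"P{i}")
        for label in (kw.get(f"$P{i}S", ""), pnn):
            key = _normalize(label)
            if key and key not in candidates:
                candidates[key] = pnn
    ssc_cols = [kw.get(f"$P{i}N") for i in range(1, n_par + 1)
                if _normalize(kw.get(f"$P{i}N", "")).startswith("SSC")]

    out = {}
    missing = []
    for ch in panel.channels:
        if ch == SSC_CHANNEL:
            col = candidates.get("SSC") or (ssc_cols[0] if ssc_cols else None)
            if col is None:
                missing.append(ch)
                continue
            out[ch] = frame[col].to_numpy()
        else:
            col = candidates.get(_normalize(ch))
            if col is None:
                missing.append(ch)
                continue
            out[ch] = np.arcsinh(frame[col].to_numpy() / arcsinh_cofactor)
    if missing:
        raise ValueError("FCS file is missing panel channel(s): "
                         + ", ".join(missing))
    return pd.DataFrame(out, columns=list(panel.channels))
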