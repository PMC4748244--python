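"""Minimal FCS 3.1 list-mode I/O and the plain-CSV event dialect.

Writes single-dataset FCS 3.1 files with float32 data ($DATATYPE/F, $MODE/L,
little-endian $BYTEORD) and reads them back, including the $SPILLOVER
keyword when present. Covers exactly the subset of the standard this
pipeline produces; it is not a general-purpose FCS parser (no integer data
types, bit masks, multi-dataset files, or analysis segments).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .frames import FLUORO, SCATTER, VIABILITY, ChannelInfo, EventFrame, SpilloverMatrix

# TEXT delimiter: the record-separator byte cannot occur in keyword values
# (detector names, markers like "Live/Dead", or numeric spillover entries)
_DELIM = "\x1e"
_HEADER_LEN = 58  # "FCS3.1" + 4 spaces + six 8-byte offset fields


def _infer_role(detector: str, marker: str) -> str:
    d = detector.upper()
    if d.startswith(("FSC", "SSC")):
        return SCATTER
    if marker.lower() in ("live/dead", "livedead", "viability", "dead"):
        return VIABILITY
    return FLUORO


def write_fcs(path, frame: EventFrame, spillover: SpilloverMatrix | None = None) -> None:
    """Write one EventFrame as an FCS 3.1 file (float32 list mode)."""
    path = Path(path)
    data = np.ascontiguousarray(frame.data, dtype="<f4")
    n_events, n_par = data.shape

    kw: dict[str, str] = {
        "$FCSVERSION": "3.1",
        "$MODE": "L",
        "$DATATYPE": "F",
        "$BYTEORD": "1,2,3,4",
        "$NEXTDATA": "0",
        "$PAR": str(n_par),
        "$TOT": str(n_events),
    }
    for k, ch in enumerate(frame.channels, start=1):
        kw[f"$P{k}B"] = "32"
        kw[f"$P{k}E"] = "0,0"
        kw[f"$P{k}N"] = ch.detector
        kw[f"$P{k}S"] = ch.marker
        kw[f"$P{k}R"] = "262144"
    if spillover is not None:
        vals = ",".join(repr(float(v)) for v in spillover.matrix.ravel())
        kw["$SPILLOVER"] = f"{len(spillover.detectors)},{','.join(spillover.detectors)},{vals}"

    # BEGIN/END data offsets are zero-padded so the text length is fixed
    kw["$BEGINDATA"] = "0" * 12
    kw["$ENDDATA"] = "0" * 12

    def render(d: dict[str, str]) -> bytes:
        parts = [_DELIM]
        for key, val in d.items():
            parts.append(f"{key}{_DELIM}{val}{_DELIM}")
        return "".join(parts).encode("ascii")

    text = render(kw)
    text_start = _HEADER_LEN
    text_end = text_start + len(text) - 1
    data_start = text_start + len(text)
    data_end = data_start + data.nbytes - 1
    kw["$BEGINDATA"] = str(data_start).zfill(12)
    kw["$ENDDATA"] = str(data_end).zfill(12)
    text = render(kw)

    def off(v: int) -> bytes:
        # header offsets are 0 when they do not fit the 8-char field
        s = str(v) if v <= 99_999_999 else "0"
        return s.rjust(8).encode("ascii")

    header = b"FCS3.1    " + off(text_start) + off(text_end)
    header += off(data_start if data_end <= 99_999_999 else 0)
    header += off(data_end if data_end <= 99_999_999 else 0)
    header += off(0) + off(0)
    assert len(header) == _HEADER_LEN

    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(text)
        fh.write(data.tobytes())


def _parse_text(raw: bytes) -> dict[str, str]:
    delim = raw[:1].decode("latin-1")
    body = raw.decode("latin-1")[1:]
    if body.endswith(delim):
        body = body[:-1]
    parts = body.split(delim)
    return {parts[i]: parts[i + 1] for i in range(0, len(parts) - 1, 2)}


def read_fcs(path) -> tuple[EventFrame, dict[str, str]]:
    """Read an FCS file written by :func:`write_fcs`.

    Returns the frame (raw scale) and the full TEXT keyword dict.
    """
    blob = Path(path).read_bytes()
    if not blob[:6] == b"FCS3.1" and not blob[:6] == b"FCS3.0":
        raise ValueError("not an FCS 3.x file")
    text_start = int(blob[10:18])
    text_end = int(blob[18:26])
    kw = _parse_text(blob[text_start : text_end + 1])
    if kw.get("$DATATYPE") != "F":
        raise ValueError("only $DATATYPE/F (float) is supported")
    order = "<" if kw.get("$BYTEORD", "1,2,3,4") == "1,2,3,4" else ">"
    n_par = int(kw["$PAR"])
    n_tot = int(kw["$TOT"])
    data_start = int(kw.get("$BEGINDATA") or blob[26:34])
    data = np.frombuffer(
        blob, dtype=f"{order}f4", count=n_par * n_tot, offset=data_start
    ).reshape(n_tot, n_par)
    channels = []
    for k in range(1, n_par + 1):
        det = kw[f"$P{k}N"]
        marker = kw.get(f"$P{k}S", det)
        channels.append(ChannelInfo(det, marker, _infer_role(det, marker)))
    return EventFrame(np.asarray(data, dtype=np.float64), channels), kw


def spillover_from_keywords(kw: dict[str, str]) -> SpilloverMatrix | None:
    """Parse the $SPILLOVER (or legacy $COMP/SPILL) keyword if present."""
    raw = kw.get("$SPILLOVER") or kw.get("SPILL") or kw.get("$COMP")
    if raw is None:
        return None
    parts = raw.split(",")
    n = int(parts[0])
    dets = parts[1 : 1 + n]
    vals = np.array([float(v) for v in parts[1 + n :]], dtype=np.float64)
    return SpilloverMatrix(vals.reshape(n, n), dets)


# ---------------------------------------------------------------------------
# plain-CSV event dialect (header = detector names)
# ---------------------------------------------------------------------------


def write_events_csv(path, frame: EventFrame) -> None:
    frame.to_dataframe().to_csv(path, index=False, float_format="%.6g")


def read_events_csv(path, panel=None) -> EventFrame:
    """Read the CSV dialect; channel roles/markers come from ``panel`` when
    given, else are inferred from detector names."""
    df = pd.read_csv(path)
    if panel is not None:
        by_det = {c.detector: c for c in panel.channels}
        channels = [
            ChannelInfo(d, by_det[d].marker, by_det[d].role) if d in by_det else
            ChannelInfo(d, d, _infer_role(d, d))
            for d in df.columns
        ]
    else:
        markers = {"FITC-A": "Live/Dead"}
        channels = [
            ChannelInfo(d, markers.get(d, d), _infer_role(d, markers.get(d, d)))
            for d in df.columns
        ]
    return EventFrame(df.to_numpy(dtype=np.float64), channels)
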