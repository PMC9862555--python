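"""Minimal FCS 3.0/3.1 event-data IO and the in-memory event container.

Only what the pipeline needs is implemented: list-mode (``$MODE L``) files
with single-precision float data (``$DATATYPE F``, written little-endian),
one dataset per file.  The writer always emits FCS 3.1; the reader accepts
3.0 and 3.1 headers and both byte orders.  Keyword validation beyond what
reading requires is deliberately out of scope.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np

from .channels import ChannelMap

__all__ = [
    "EventTable",
    "FcsReadError",
    "read_fcs",
    "write_fcs",
    "RAW_FULL_SCALE",
]

#: 18-bit full scale used by the instruments emulated here.
RAW_FULL_SCALE = 262144.0


class FcsReadError(IOError):
    """File-level QC failure: unreadable, truncated or incomplete FCS data."""


@dataclass
class EventTable:
    """Per-tube matrix of events x channels with a channel-role mapping.

    ``scale`` tracks, per channel name, whether values are ``raw``,
    ``compensated`` or ``logicle``; scatter and Time stay ``raw`` for the
    whole pipeline.
    """

    events: np.ndarray                       # (n_events, n_channels) float
    channel_names: List[str]
    channel_map: ChannelMap
    scale: Dict[str, str] = field(default_factory=dict)
    meta: Dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.events = np.asarray(self.events, dtype=np.float64)
        if self.events.ndim != 2:
            raise ValueError("events must be a 2-D matrix")
        if self.events.shape[1] != len(self.channel_names):
            raise ValueError("channel_names length does not match event matrix")
        for name in self.channel_names:
            self.scale.setdefault(name, "raw")

    # -- access -----------------------------------------------------------
    @property
    def n_events(self) -> int:
        return self.events.shape[0]

    def column_index(self, role: str) -> int:
        name = self.channel_map.resolve(role)
        try:
            return self.channel_names.index(name)
        except ValueError:
            raise KeyError(
                f"channel {name!r} (role {role}) not present in this tube"
            ) from None

    def get(self, role: str) -> np.ndarray:
        """Column of values for a logical role."""
        return self.events[:, self.column_index(role)]

    def set(self, role: str, values: np.ndarray, scale: Optional[str] = None) -> None:
        idx = self.column_index(role)
        self.events[:, idx] = values
        if scale is not None:
            self.scale[self.channel_names[idx]] = scale

    def role_scale(self, role: str) -> str:
        return self.scale[self.channel_map.resolve(role)]

    def copy(self) -> "EventTable":
        return EventTable(
            events=self.events.copy(),
            channel_names=list(self.channel_names),
            channel_map=self.channel_map,
            scale=dict(self.scale),
            meta=dict(self.meta),
        )

    # -- invariants --------------------------------------------------------
    def validate(self, required_roles: Sequence[str]) -> None:
        for role in required_roles:
            if role not in self.channel_map or self.channel_map.resolve(role) not in self.channel_names:
                raise FcsReadError(f"required role missing from tube: {role}")
        if not np.all(np.isfinite(self.events)):
            raise FcsReadError("non-finite raw event values")
        t = self.get("TIME") if "TIME" in self.channel_map else None
        if t is not None and t.size > 1 and np.any(np.diff(t) < 0):
            raise FcsReadError("Time channel is not non-decreasing")

    def clip_to_range(self) -> int:
        """Clip raw values into [0, full scale]; returns number clipped."""
        lo = self.events < 0.0
        hi = self.events > RAW_FULL_SCALE
        n = int(lo.sum() + hi.sum())
        if n:
            np.clip(self.events, 0.0, RAW_FULL_SCALE, out=self.events)
            warnings.warn(f"clipped {n} raw values to [0, {RAW_FULL_SCALE:g}]")
        return n


# ---------------------------------------------------------------------------
# FCS 3.1 writer

def _text_segment(keywords: Dict[str, str], delim: str = "/") -> bytes:
    parts = [delim]
    for k, v in keywords.items():
        parts.append(k)
        parts.append(delim)
        parts.append(str(v))
        parts.append(delim)
    return "".join(parts).encode("ascii")


def write_fcs(path, events: np.ndarray, channel_names: Sequence[str],
              extra_keywords: Optional[Dict[str, str]] = None) -> None:
    """Write a single-dataset FCS 3.1 file (float32, little-endian)."""
    data = np.ascontiguousarray(np.asarray(events, dtype="<f4"))
    n_events, n_par = data.shape
    if n_par != len(channel_names):
        raise ValueError("channel_names length mismatch")
    databytes = data.tobytes()

    kw: Dict[str, str] = {
        "$BEGINANALYSIS": "0", "$ENDANALYSIS": "0",
        "$BYTEORD": "1,2,3,4",
        "$DATATYPE": "F",
        "$MODE": "L",
        "$NEXTDATA": "0",
        "$PAR": str(n_par),
        "$TOT": str(n_events),
    }
    for i, name in enumerate(channel_names, start=1):
        kw[f"$P{i}N"] = name
        kw[f"$P{i}B"] = "32"
        kw[f"$P{i}E"] = "0,0"
        kw[f"$P{i}R"] = str(int(RAW_FULL_SCALE))
    if extra_keywords:
        kw.update(extra_keywords)

    # two-pass layout: placeholder offsets, then fill in
    header_len = 58
    begin_text = header_len
    for _ in range(3):  # offsets lengthen the TEXT segment; iterate to fix point
        kw["$BEGINDATA"] = "0"
        kw["$ENDDATA"] = "0"
        probe = _text_segment(kw)
        begin_data = begin_text + len(probe)
        end_data = begin_data + len(databytes) - 1
        kw["$BEGINDATA"] = str(begin_data)
        kw["$ENDDATA"] = str(end_data)
        text = _text_segment(kw)
        if begin_text + len(text) == begin_data:
            break
        # digits count changed; re-derive with the longer segment
        begin_data = begin_text + len(text)
        end_data = begin_data + len(databytes) - 1
        kw["$BEGINDATA"] = str(begin_data)
        kw["$ENDDATA"] = str(end_data)
        text = _text_segment(kw)
        if begin_text + len(text) == begin_data:
            break
    end_text = begin_text + len(text) - 1

    def _off(x: int) -> bytes:
        s = str(x) if x <= 99999999 else "0"
        return s.rjust(8).encode("ascii")

    header = b"FCS3.1    " + _off(begin_text) + _off(end_text) + \
        _off(begin_data if end_data <= 99999999 else 0) + \
        _off(end_data if end_data <= 99999999 else 0) + _off(0) + _off(0)
    assert len(header) == 58
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(text)
        fh.write(databytes)


# ---------------------------------------------------------------------------
# FCS reader

def _parse_text(raw: bytes) -> Dict[str, str]:
    if not raw:
        raise FcsReadError("empty TEXT segment")
    delim = raw[:1].decode("latin-1")
    body = raw.decode("latin-1")
    parts = body.split(delim)
    # leading empty chunk before the first delimiter; trailing after the last
    parts = parts[1:]
    if parts and parts[-1] == "":
        parts = parts[:-1]
    if len(parts) % 2:
        parts = parts[:-1]
    return {parts[i].strip(): parts[i + 1] for i in range(0, len(parts), 2)}


def read_fcs(path, cmap: ChannelMap,
             required_roles: Sequence[str] = ("TIME",)) -> EventTable:
    """Read an FCS 3.0/3.1 file and map channels to logical roles.

    Raises :class:`FcsReadError` on unreadable files ("file QC failure"),
    on declared-vs-decoded event-count mismatch ("incomplete data matrix"),
    and when a required role is missing (named in the message).
    """
    path = Path(path)
    try:
        blob = path.read_bytes()
    except OSError as exc:
        raise FcsReadError(f"file QC failure: cannot read {path}: {exc}") from exc
    if len(blob) < 58 or not blob[:6] in (b"FCS3.0", b"FCS3.1"):
        raise FcsReadError(f"file QC failure: {path} is not an FCS 3.0/3.1 file")
    try:
        bt, et = int(blob[10:18]), int(blob[18:26])
        bd, ed = int(blob[26:34]), int(blob[34:42])
    except ValueError as exc:
        raise FcsReadError(f"file QC failure: malformed header in {path}") from exc
    if et >= len(blob):
        raise FcsReadError(f"file QC failure: truncated TEXT segment in {path}")
    kw = _parse_text(blob[bt:et + 1])
    if bd == 0:
        bd = int(kw.get("$BEGINDATA", "0"))
        ed = int(kw.get("$ENDDATA", "0"))
    try:
        n_par = int(kw["$PAR"])
        n_tot = int(kw["$TOT"])
        datatype = kw["$DATATYPE"].strip().upper()
        byteord = kw["$BYTEORD"].strip()
    except KeyError as exc:
        raise FcsReadError(f"file QC failure: missing keyword {exc} in {path}") from exc
    if datatype != "F":
        raise FcsReadError(f"unsupported $DATATYPE {datatype!r} (only F supported)")
    endian = "<" if byteord.startswith("1") else ">"
    names = [kw.get(f"$P{i}N", f"P{i}") for i in range(1, n_par + 1)]

    expected = 4 * n_par * n_tot
    data_blob = blob[bd:ed + 1]
    if len(data_blob) < expected or ed >= len(blob):
        raise FcsReadError(
            f"incomplete data matrix in {path}: header declares {n_tot} events "
            f"({expected} bytes), {min(len(data_blob), max(0, len(blob)-bd))} bytes present"
        )
    arr = np.frombuffer(data_blob[:expected], dtype=endian + "f4").reshape(n_tot, n_par)

    table = EventTable(
        events=arr.astype(np.float64),
        channel_names=names,
        channel_map=cmap,
        meta={k: v for k, v in kw.items() if not k.startswith("$P")},
    )
    table.validate(required_roles)
    return table
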