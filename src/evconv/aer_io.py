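"""Reading, writing, validating and time-scaling AER event streams.

Two on-disk dialects are supported:

* **CSV** — the canonical interchange format: one event per line,
  columns ``t,x,y,p[,k]``, optional header line.
* **AEDAT** — a plain binary dialect of 8-byte records (big-endian
  32-bit address word followed by a big-endian 32-bit timestamp), the
  record layout commonly used for DVS exports.  No file headers.

Timestamps are integers in clock ticks; the real duration of one tick is
carried by the stream (default 20 ns, i.e. a 50 MHz clock).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, NamedTuple

import numpy as np

from .errors import ParseError, StreamValidationError

DEFAULT_TICK_SECONDS = 20e-9  # 50 MHz clock

# Bit layout of the AEDAT 32-bit address word (artifact-defined packing):
#   bit 0      polarity (1 -> +1, 0 -> -1)
#   bits 1-10  x coordinate (10 bits)
#   bits 11-20 y coordinate (10 bits)
#   bits 21-28 kernel id + 1 (0 means "no kernel id")
_P_BIT = 0
_X_SHIFT, _X_MASK = 1, 0x3FF
_Y_SHIFT, _Y_MASK = 11, 0x3FF
_K_SHIFT, _K_MASK = 21, 0xFF


class Event(NamedTuple):
    """A timestamped AER spike.

    ``t`` is in clock ticks, ``p`` is +1/-1, ``k`` is the kernel id
    (present on unit-input events, ``None`` on raw sensor events).
    """

    t: int
    x: int
    y: int
    p: int
    k: int | None = None


@dataclass
class EventStream:
    """An ordered, bounded-address-space sequence of events."""

    events: list[Event] = field(default_factory=list)
    address_space: tuple[int, int] = (0, 0)  # (x_max, y_max), exclusive bounds
    tick_seconds: float = DEFAULT_TICK_SECONDS

    def __len__(self) -> int:
        return len(self.events)

    def __iter__(self):
        return iter(self.events)

    @property
    def duration_ticks(self) -> int:
        if len(self.events) < 2:
            return 0
        return self.events[-1].t - self.events[0].t

    @property
    def duration_seconds(self) -> float:
        return self.duration_ticks * self.tick_seconds

    def validate(self) -> None:
        """Check stream invariants, raising ``StreamValidationError``."""
        x_max, y_max = self.address_space
        prev_t = -1
        for i, ev in enumerate(self.events):
            if ev.t < 0:
                raise StreamValidationError(f"event {i}: negative timestamp {ev.t}")
            if ev.t < prev_t:
                raise StreamValidationError(
                    f"event {i}: timestamp {ev.t} < previous {prev_t} (stream unsorted)"
                )
            if not (0 <= ev.x < x_max and 0 <= ev.y < y_max):
                raise StreamValidationError(
                    f"event {i}: address ({ev.x}, {ev.y}) outside "
                    f"declared space {self.address_space}"
                )
            if ev.p not in (1, -1):
                raise StreamValidationError(f"event {i}: polarity {ev.p} not in {{+1, -1}}")
            prev_t = ev.t


def _infer_address_space(events: Iterable[Event]) -> tuple[int, int]:
    x_max = y_max = 0
    for ev in events:
        x_max = max(x_max, ev.x + 1)
        y_max = max(y_max, ev.y + 1)
    return (x_max, y_max)


def _read_csv(path: Path, sort: bool) -> list[Event]:
    events: list[Event] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        for lineno, row in enumerate(reader, start=1):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            first = row[0].strip()
            if lineno == 1 and not first.lstrip("-").isdigit():
                continue  # optional header line
            if len(row) not in (4, 5):
                raise ParseError(f"{path}:{lineno}: expected 4 or 5 columns, got {len(row)}")
            try:
                t, x, y, p = (int(v) for v in row[:4])
                k = None
                if len(row) == 5 and row[4].strip():
                    k = int(row[4])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            if p not in (1, -1):
                raise ParseError(f"{path}:{lineno}: polarity must be +1/-1, got {p}")
            events.append(Event(t, x, y, p, k))
    return events


def _read_aedat(path: Path, sort: bool) -> list[Event]:
    raw = Path(path).read_bytes()
    if len(raw) % 8:
        raise ParseError(f"{path}: file size {len(raw)} is not a multiple of 8 bytes")
    words = np.frombuffer(raw, dtype=">u4").reshape(-1, 2)
    events: list[Event] = []
    for i, (addr, ts) in enumerate(words.tolist()):
        p = 1 if (addr >> _P_BIT) & 1 else -1
        x = (addr >> _X_SHIFT) & _X_MASK
        y = (addr >> _Y_SHIFT) & _Y_MASK
        kfield = (addr >> _K_SHIFT) & _K_MASK
        events.append(Event(ts, x, y, p, kfield - 1 if kfield else None))
    return events


def read_events(
    path: str | Path,
    format: str = "csv",
    *,
    sort: bool = False,
    address_space: tuple[int, int] | None = None,
    tick_seconds: float = DEFAULT_TICK_SECONDS,
) -> EventStream:
    """Read and validate an event stream.

    Unsorted timestamps raise ``StreamValidationError`` unless
    ``sort=True`` requests a stable sort on read.
    """
    path = Path(path)
    if format == "csv":
        events = _read_csv(path, sort)
    elif format == "aedat":
        events = _read_aedat(path, sort)
    else:
        raise ValueError(f"unknown format {format!r} (expected 'csv' or 'aedat')")
    if sort:
        events.sort(key=lambda ev: ev.t)  # stable: ties keep file order
    stream = EventStream(
        events=events,
        address_space=address_space or _infer_address_space(events),
        tick_seconds=tick_seconds,
    )
    stream.validate()
    return stream


def write_events(stream: EventStream, path: str | Path, format: str = "csv") -> None:
    """Write ``stream`` in the named dialect (inverse of ``read_events``)."""
    path = Path(path)
    if format == "csv":
        with_k = any(ev.k is not None for ev in stream.events)
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["t", "x", "y", "p", "k"] if with_k else ["t", "x", "y", "p"])
            for ev in stream.events:
                row = [ev.t, ev.x, ev.y, ev.p]
                if with_k:
                    row.append("" if ev.k is None else ev.k)
                writer.writerow(row)
    elif format == "aedat":
        words = np.empty((len(stream.events), 2), dtype=">u4")
        for i, ev in enumerate(stream.events):
            if not 0 <= ev.t < 2**32:
                raise ValueError(f"event {i}: timestamp {ev.t} does not fit in 32 bits")
            if ev.x > _X_MASK or ev.y > _Y_MASK:
                raise ValueError(f"event {i}: address ({ev.x}, {ev.y}) does not fit in 10 bits")
            k = 0 if ev.k is None else ev.k + 1
            if k > _K_MASK:
                raise ValueError(f"event {i}: kernel id {ev.k} does not fit in 8 bits")
            addr = ((1 if ev.p > 0 else 0) << _P_BIT) | (ev.x << _X_SHIFT) | (ev.y << _Y_SHIFT) | (k << _K_SHIFT)
            words[i, 0] = addr
            words[i, 1] = ev.t
        Path(path).write_bytes(words.tobytes())
    else:
        raise ValueError(f"unknown format {format!r} (expected 'csv' or 'aedat')")


def apply_slowdown(stream: EventStream, factor: int) -> EventStream:
    """Scale all timestamps by an integer slow-down factor (>= 1)."""
    if factor < 1 or int(factor) != factor:
        raise ValueError(f"slow-down factor must be a positive integer, got {factor}")
    factor = int(factor)
    if factor == 1:
        return replace(stream, events=list(stream.events))
    return replace(stream, events=[ev._replace(t=ev.t * factor) for ev in stream.events])
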