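"""Synthetic stimulus generation.

Two generators: single-address spike trains with normally distributed
inter-spike intervals (for node characterization), and DVS-like ON/OFF
event streams produced by a symbol mask moving across a small field (a
stand-in for real sensor recordings; the contrast rule is binary
occupancy change, not photometric).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .aer_io import DEFAULT_TICK_SECONDS, Event, EventStream

SYMBOLS = ("club", "diamond", "heart", "spade")


@dataclass(frozen=True)
class ISITrainSpec:
    """Spike train at one address with Normal(1/f_in, std_frac/f_in) ISIs."""

    f_in: float
    duration: float  # seconds
    std_frac: float = 0.10
    address: tuple[int, int] = (0, 0)
    polarity: int = 1
    seed: int | None = None
    tick_seconds: float = DEFAULT_TICK_SECONDS

    def __post_init__(self):
        if self.f_in <= 0:
            raise ValueError("f_in must be positive")
        if not 0 <= self.std_frac < 1:
            raise ValueError("std_frac must be in [0, 1)")


def gen_isi_train(spec: ISITrainSpec) -> EventStream:
    """Generate the ISI-controlled train; non-positive ISI draws are
    resampled, timestamps are cumulative and quantized to ticks."""
    rng = np.random.default_rng(spec.seed)
    mean = 1.0 / spec.f_in
    std = spec.std_frac * mean
    n_target = int(spec.duration * spec.f_in * 1.2) + 16
    isis = np.empty(0)
    total = 0.0
    while total < spec.duration:
        batch = rng.normal(mean, std, size=n_target) if std > 0 else np.full(n_target, mean)
        while True:  # resample non-positive draws
            bad = batch <= 0
            if not bad.any():
                break
            batch[bad] = rng.normal(mean, std, size=int(bad.sum()))
        isis = np.concatenate([isis, batch])
        total = float(isis.sum())
    times = np.cumsum(isis)
    times = times[times <= spec.duration]
    ticks = np.round(times / spec.tick_seconds).astype(np.int64)
    x, y = spec.address
    events = [Event(int(t), x, y, spec.polarity) for t in ticks]
    return EventStream(events, (x + 1, y + 1), spec.tick_seconds)


# ---------------------------------------------------------------------------
# Symbol masks and moving-symbol scenes
# ---------------------------------------------------------------------------


def symbol_mask(symbol: str, size: int = 13) -> np.ndarray:
    """Boolean stencil of a poker symbol, indexed ``[y][x]``."""
    if symbol not in SYMBOLS:
        raise ValueError(f"unknown symbol {symbol!r}, expected one of {SYMBOLS}")
    half = (size - 1) / 2.0
    ys, xs = np.mgrid[0:size, 0:size] - half
    r = size / 2.0
    if symbol == "diamond":
        return np.abs(xs) + np.abs(ys) <= r
    if symbol == "heart":
        lobe = r * 0.45
        left = (xs + lobe) ** 2 + (ys + lobe) ** 2 <= lobe**2 * 1.4
        right = (xs - lobe) ** 2 + (ys + lobe) ** 2 <= lobe**2 * 1.4
        tip = (np.abs(xs) * 1.1 + ys <= r * 0.85) & (ys >= -lobe * 0.4)
        return left | right | tip
    if symbol == "spade":
        lobe = r * 0.45
        left = (xs + lobe) ** 2 + (ys - lobe) ** 2 <= lobe**2 * 1.4
        right = (xs - lobe) ** 2 + (ys - lobe) ** 2 <= lobe**2 * 1.4
        tip = (np.abs(xs) * 1.1 - ys <= r * 0.85) & (ys <= lobe * 0.4)
        stem = (np.abs(xs) <= max(1, size // 10)) & (ys >= lobe * 0.2)
        return left | right | tip | stem
    # club: three lobes plus a stem
    lobe = r * 0.42
    top = xs**2 + (ys + lobe) ** 2 <= lobe**2 * 1.5
    left = (xs + lobe) ** 2 + ys**2 <= lobe**2 * 1.5
    right = (xs - lobe) ** 2 + ys**2 <= lobe**2 * 1.5
    stem = (np.abs(xs) <= max(1, size // 10)) & (ys >= 0)
    return top | left | right | stem


@dataclass(frozen=True)
class SymbolSceneSpec:
    """A symbol translated across a field along a displacement trajectory.

    ``trajectory`` is a sequence of ``(t_ticks, dx, dy)`` displacements
    of the symbol center from the field center; occupancy is rendered at
    each step and ON/OFF events are emitted where it rises/falls.
    """

    symbol: str
    trajectory: tuple[tuple[int, int, int], ...]
    field_size: tuple[int, int] = (32, 32)
    symbol_size: int = 13
    jitter_ticks: int = 0
    seed: int | None = None
    tick_seconds: float = DEFAULT_TICK_SECONDS

    def __post_init__(self):
        if self.symbol not in SYMBOLS:
            raise ValueError(f"unknown symbol {self.symbol!r}")
        if self.symbol_size > min(self.field_size):
            raise ValueError("symbol mask does not fit the field")


def render_occupancy(spec: SymbolSceneSpec, dx: int, dy: int) -> np.ndarray:
    """Occupancy frame with the symbol center displaced by (dx, dy);
    portions leaving the field are clipped."""
    w, h = spec.field_size
    frame = np.zeros((h, w), dtype=bool)
    mask = symbol_mask(spec.symbol, spec.symbol_size)
    cy, cx = h // 2 + dy, w // 2 + dx
    y0 = cy - spec.symbol_size // 2
    x0 = cx - spec.symbol_size // 2
    ay0, ax0 = max(y0, 0), max(x0, 0)
    ay1 = min(y0 + spec.symbol_size, h)
    ax1 = min(x0 + spec.symbol_size, w)
    if ay0 < ay1 and ax0 < ax1:
        frame[ay0:ay1, ax0:ax1] = mask[ay0 - y0 : ay1 - y0, ax0 - x0 : ax1 - x0]
    return frame


def gen_moving_symbol(spec: SymbolSceneSpec) -> EventStream:
    """DVS-like stream: +1 where occupancy rises, -1 where it falls."""
    rng = np.random.default_rng(spec.seed)
    w, h = spec.field_size
    prev = np.zeros((h, w), dtype=bool)
    events: list[Event] = []
    for t, dx, dy in spec.trajectory:
        frame = render_occupancy(spec, dx, dy)
        on = frame & ~prev
        off = prev & ~frame
        for polarity, mask in ((1, on), (-1, off)):
            ys, xs = np.nonzero(mask)
            for y, x in zip(ys.tolist(), xs.tolist()):
                tt = int(t)
                if spec.jitter_ticks:
                    tt = max(0, tt + int(rng.integers(-spec.jitter_ticks, spec.jitter_ticks + 1)))
                events.append(Event(tt, int(x), int(y), polarity))
        prev = frame
    events.sort(key=lambda ev: ev.t)
    return EventStream(events, spec.field_size, spec.tick_seconds)


def linear_trajectory(
    n_steps: int, step_ticks: int, dx_per_step: int = 1, dy_per_step: int = 0, start: tuple[int, int] = (0, 0)
) -> tuple[tuple[int, int, int], ...]:
    """Convenience: uniform translation sampled every ``step_ticks``."""
    x0, y0 = start
    return tuple(
        (i * step_ticks, x0 + i * dx_per_step, y0 + i * dy_per_step) for i in range(n_steps)
    )
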