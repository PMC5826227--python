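"""The event-driven convolutional unit.

An array of integrate-and-fire pixels driven by AER events.  Each input
event adds a (possibly sign-inverted) kernel patch to a neighbourhood of
pixels; pixels crossing the positive threshold (2*Th) emit a positive
event and reset to Th, pixels crossing 0 emit a negative event and reset
to Th.  Firing is gated by a hardware-faithful rate-saturation
(refractory) mechanism that stores only an 8-bit slice of the 32-bit
allow time per pixel, together with an overflow flag and a pending-delta
flag, and is kept consistent by a periodic refresh pulse.

A global leakage process moves all pixels toward the reset value every
``t_leak`` ticks, and a cycle-accurate cost model gives the per-event
processing latency.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .aer_io import DEFAULT_TICK_SECONDS, Event
from .errors import ConfigurationError

# ---------------------------------------------------------------------------
# Kernels and configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class KernelSpec:
    """A 2D integer weight matrix with its centering shift.

    ``weights`` is indexed ``[y][x]``; ``xk_max``/``yk_max`` are the
    kernel dimensions and ``shift_x``/``shift_y`` offset the kernel
    center relative to the input event address.
    """

    weights: np.ndarray
    shift_x: int = 0
    shift_y: int = 0

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=np.int64)
        if w.ndim != 2:
            raise ConfigurationError("kernel weights must be a 2D matrix")
        object.__setattr__(self, "weights", w)

    @property
    def xk_max(self) -> int:
        return self.weights.shape[1]

    @property
    def yk_max(self) -> int:
        return self.weights.shape[0]

    @property
    def size(self) -> int:
        return self.weights.size

    def to_text(self) -> str:
        header = f"{self.xk_max} {self.yk_max} {self.shift_x} {self.shift_y}"
        rows = [" ".join(str(v) for v in row) for row in self.weights.tolist()]
        return "\n".join([header] + rows)

    @classmethod
    def from_text(cls, text: str) -> "KernelSpec":
        lines = [ln for ln in text.strip().splitlines() if ln.strip()]
        xk, yk, sx, sy = (int(v) for v in lines[0].split())
        rows = [[int(v) for v in ln.split()] for ln in lines[1 : 1 + yk]]
        w = np.array(rows, dtype=np.int64)
        if w.shape != (yk, xk):
            raise ConfigurationError(
                f"kernel block is {w.shape}, header declares ({yk}, {xk})"
            )
        return cls(weights=w, shift_x=sx, shift_y=sy)


def tr_bounds(b_tr: int) -> tuple[int, int]:
    """(TRmin, TRmax) programmable for a given MSB index ``b_tr``."""
    return 1 << (b_tr - 7), (1 << (b_tr + 1)) - 1


def b_tr_for(t_r_ticks: int) -> int:
    """Smallest valid MSB index whose range contains ``t_r_ticks``."""
    b = max(7, int(t_r_ticks).bit_length() - 1)
    lo, hi = tr_bounds(b)
    if not lo <= t_r_ticks <= hi:
        raise ConfigurationError(f"no valid b_TR for T_R={t_r_ticks}")
    return b


@dataclass
class UnitConfig:
    """Static parameters of one convolutional unit.

    The pixel state register is ``n_bits`` wide; the reset value is
    ``th``, the negative threshold 0 and the positive threshold
    ``2*th``.  ``t_leak``/``t_r`` are in clock ticks; ``t_leak=0``
    disables leakage.  ``dt_correction`` enables the delta-t
    compensation that makes the saturated output rate exactly ``1/T_R``.
    """

    n_x: int
    n_y: int
    th: int = 128
    n_bits: int = 9
    t_leak: int = 0
    n_leak: int = 0
    t_r: int = 1
    b_tr: int = 7
    n_kernels: int = 8
    in_addr_space: tuple[int, int] | None = None
    out_addr_space: tuple[int, int] | None = None
    fifo_depth_in: int = 64
    fifo_depth_out: int = 64
    dt_correction: bool = True
    leak_cost_per_pixel: int = 0  # optional cycle charge per pixel per leak pulse

    def __post_init__(self):
        if self.n_x < 1 or self.n_y < 1:
            raise ConfigurationError("pixel array dimensions must be positive")
        if not 0 < self.th <= 128:
            raise ConfigurationError(f"threshold must be in (0, 128], got {self.th}")
        if not 7 <= self.b_tr <= 31:
            raise ConfigurationError(f"b_TR must be in [7, 31], got {self.b_tr}")
        lo, hi = tr_bounds(self.b_tr)
        if not lo <= self.t_r <= hi:
            raise ConfigurationError(
                f"T_R={self.t_r} outside [{lo}, {hi}] for b_TR={self.b_tr}"
            )
        if self.out_addr_space is None:
            self.out_addr_space = (self.n_x, self.n_y)
        if self.in_addr_space is None:
            self.in_addr_space = (self.n_x, self.n_y)


# ---------------------------------------------------------------------------
# Cost model
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CostModel:
    """Per-event latency: router-in + init + convolution + router-out."""

    t_router_in: int = 6
    t_ini: int = 37
    cycles_per_weight: int = 16
    t_router_out: int = 4
    t_clk: float = DEFAULT_TICK_SECONDS

    def t_proc(self, kernel: KernelSpec) -> int:
        """Cycles spent on the convolution itself."""
        return self.cycles_per_weight * kernel.size

    def event_cost(self, kernel: KernelSpec) -> int:
        """Total cycles from router input to router output."""
        return self.t_router_in + self.t_ini + self.t_proc(kernel) + self.t_router_out

    def latency_seconds(self, kernel: KernelSpec) -> float:
        return self.event_cost(kernel) * self.t_clk


def event_cost(kernel: KernelSpec, model: CostModel | None = None) -> int:
    """Latency, in clock cycles, to process one event with ``kernel``."""
    return (model or CostModel()).event_cost(kernel)


# ---------------------------------------------------------------------------
# Rate-saturation mechanism (8-bit slice of the 32-bit counter)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RateSatEntry:
    """Per-pixel refractory state: 8-bit t_lim slice plus two flags."""

    tlim8b: int = 0
    f_of: bool = False
    f_dt: bool = False


def _slice8(t: int, b_tr: int) -> int:
    """Bits ``b_tr .. b_tr-7`` of a counter value."""
    return (int(t) >> (b_tr - 7)) & 0xFF


def rate_sat_allow(entry: RateSatEntry, t: int, b_tr: int) -> tuple[bool, RateSatEntry]:
    """Decide whether a threshold-crossing pixel may fire at time ``t``.

    Denied while the counter slice is below the stored ``tlim8b``, and
    likewise when an overflow is pending (``f_of`` set, meaning the true
    t_lim lies in the next refresh window).  On denial the pending-delta
    flag is raised (the caller holds the pixel at the crossed threshold).
    """
    t8 = _slice8(t, b_tr)
    if t8 >= entry.tlim8b and not entry.f_of:
        return True, entry
    return False, RateSatEntry(entry.tlim8b, entry.f_of, True)


def rate_sat_update(
    entry: RateSatEntry, t: int, t_r: int, b_tr: int, dt_correction: bool = True
) -> RateSatEntry:
    """Recompute ``t_lim = t + T_R - dt`` after an output event at ``t``.

    ``dt`` compensates the delay between the ideal fire time (previous
    ``t_lim``) and the actual one; it is quantized to the stored 8-bit
    resolution and clamped to ``[0, T_R]``.
    """
    q = 1 << (b_tr - 7)
    t8 = _slice8(t, b_tr)
    dt = 0
    if entry.f_dt and dt_correction:
        dt = (t8 - entry.tlim8b) * q
        dt = min(max(dt, 0), t_r)
    tlim = t + t_r - dt
    tlim8 = _slice8(tlim, b_tr)
    return RateSatEntry(tlim8b=tlim8, f_of=tlim8 < t8, f_dt=False)


def rate_sat_refresh_entry(entry: RateSatEntry) -> RateSatEntry:
    """One refresh pulse: clear a pending overflow, else expire t_lim."""
    if entry.f_of:
        return RateSatEntry(entry.tlim8b, False, entry.f_dt)
    return RateSatEntry(0, False, entry.f_dt)


# ---------------------------------------------------------------------------
# The unit itself
# ---------------------------------------------------------------------------


@dataclass
class ConvUnit:
    """Mutable state and behaviour of one convolutional unit.

    Pixels are stored row-major (``[y][x]``); the rate-saturation state
    is kept as parallel arrays (``tlim8b``, ``f_of``, ``f_dt``).
    """

    cfg: UnitConfig
    kernels: list[KernelSpec] = field(default_factory=list)
    cost: CostModel = field(default_factory=CostModel)

    def __post_init__(self):
        if len(self.kernels) > self.cfg.n_kernels:
            raise ConfigurationError(
                f"{len(self.kernels)} kernels loaded, unit holds {self.cfg.n_kernels}"
            )
        shape = (self.cfg.n_y, self.cfg.n_x)
        self.pixels = np.full(shape, self.cfg.th, dtype=np.int64)
        self.tlim8b = np.zeros(shape, dtype=np.int64)
        self.f_of = np.zeros(shape, dtype=bool)
        self.f_dt = np.zeros(shape, dtype=bool)
        self.global_counter = 0
        self.fifo_out_occupancy = 0

    # -- clock-driven processes -------------------------------------------

    def apply_leakage(self, pulses: int = 1) -> None:
        """Move every pixel ``pulses * n_leak`` toward the reset value,
        never crossing it."""
        step = pulses * self.cfg.n_leak
        if step <= 0:
            return
        d = self.pixels - self.cfg.th
        np.subtract(self.pixels, np.sign(d) * np.minimum(np.abs(d), step), out=self.pixels)

    def rate_sat_refresh(self) -> None:
        """Refresh pulse over all pixels (see ``rate_sat_refresh_entry``)."""
        clear = ~self.f_of
        self.tlim8b[clear] = 0
        self.f_of[:] = False

    def advance_to(self, t: int) -> None:
        """Advance the global counter to ``t``, applying every leak pulse
        and refresh pulse whose boundary falls in ``(counter, t]``.

        A refresh pulse fires at the last tick of each window
        (``t mod 2^(b_TR+1) == 2^(b_TR+1)-1``) but takes effect after
        any event processed at that same tick, so it is applied here
        once the counter moves strictly past the boundary.

        Pulses are collapsed: ``n`` consecutive leak pulses equal one
        pulse of amplitude ``n * n_leak`` (leak is a contraction and no
        events interleave), and two or more refreshes without intervening
        fires leave every entry at ``(tlim8b=0, f_of=0)``.
        """
        gc = self.global_counter
        if t < gc:
            raise ValueError(f"counter cannot move backwards ({gc} -> {t})")
        if self.cfg.t_leak > 0 and self.cfg.n_leak > 0:
            n = t // self.cfg.t_leak - gc // self.cfg.t_leak
            if n > 0:
                self.apply_leakage(n)
        window = 1 << (self.cfg.b_tr + 1)
        nref = t // window - gc // window
        if nref >= 2:
            self.tlim8b[:] = 0
            self.f_of[:] = False
        elif nref == 1:
            self.rate_sat_refresh()
        self.global_counter = t

    # -- event processing --------------------------------------------------

    def process_event(self, ev: Event, t_proc: int | None = None) -> tuple[list[Event], int]:
        """Apply kernel ``ev.k`` around ``(ev.x, ev.y)`` and collect fires.

        ``t_proc`` is the tick at which processing starts (defaults to
        the event timestamp; the network engine passes the dequeue time).
        Returns the emitted events — all stamped with the completion
        time — and the cycles consumed.
        """
        k = ev.k if ev.k is not None else 0
        if not 0 <= k < len(self.kernels):
            raise ConfigurationError(f"unknown kernel id {k} ({len(self.kernels)} loaded)")
        kern = self.kernels[k]
        if t_proc is None:
            t_proc = ev.t
        self.advance_to(t_proc)

        cfg = self.cfg
        cx = ev.x + kern.shift_x
        cy = ev.y + kern.shift_y
        x0 = cx - kern.xk_max // 2
        y0 = cy - kern.yk_max // 2
        ax0, ay0 = max(x0, 0), max(y0, 0)
        ax1, ay1 = min(x0 + kern.xk_max, cfg.n_x), min(y0 + kern.yk_max, cfg.n_y)
        if ax0 >= ax1 or ay0 >= ay1:
            # whole kernel window misses the array: discard before T_proc
            return [], self.cost.t_router_in + self.cost.t_ini

        cycles = self.cost.event_cost(kern)
        t_done = t_proc + cycles
        w = kern.weights[ay0 - y0 : ay1 - y0, ax0 - x0 : ax1 - x0]
        sub = self.pixels[ay0:ay1, ax0:ax1]
        if ev.p < 0:
            sub -= w
        else:
            sub += w

        outputs: list[Event] = []
        pos_th = 2 * cfg.th
        crossed = (sub >= pos_th) | (sub <= 0)
        if crossed.any():
            ys, xs = np.nonzero(crossed)  # row-major scan order
            b_tr, t_r = cfg.b_tr, cfg.t_r
            for dy, dx in zip(ys.tolist(), xs.tolist()):
                gy, gx = ay0 + dy, ax0 + dx
                pol = 1 if self.pixels[gy, gx] >= pos_th else -1
                entry = RateSatEntry(
                    int(self.tlim8b[gy, gx]), bool(self.f_of[gy, gx]), bool(self.f_dt[gy, gx])
                )
                allowed, entry = rate_sat_allow(entry, t_proc, b_tr)
                if allowed:
                    entry = rate_sat_update(entry, t_proc, t_r, b_tr, cfg.dt_correction)
                    self.pixels[gy, gx] = cfg.th
                    outputs.append(Event(t_done, gx, gy, pol))
                else:
                    self.pixels[gy, gx] = pos_th if pol > 0 else 0
                self.tlim8b[gy, gx] = entry.tlim8b
                self.f_of[gy, gx] = entry.f_of
                self.f_dt[gy, gx] = entry.f_dt
        # saturating arithmetic at the register bounds (never wraps)
        np.clip(sub, 0, (1 << cfg.n_bits) - 1, out=sub)
        self.fifo_out_occupancy += len(outputs)
        return outputs, cycles
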