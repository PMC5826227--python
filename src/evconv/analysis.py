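"""Characterization and evaluation helpers.

Saturation curves for the refractory mechanism, the winner-take-all
symbol decision rule, stream statistics and the energy arithmetic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .aer_io import DEFAULT_TICK_SECONDS, Event, EventStream
from .conv_unit import ConvUnit, KernelSpec, UnitConfig, b_tr_for
from .stimulus import ISITrainSpec, SYMBOLS, gen_isi_train


# ---------------------------------------------------------------------------
# Single-pixel saturation characterization
# ---------------------------------------------------------------------------


def measure_output_rate(
    f_in: float,
    t_r_seconds: float,
    th: int = 10,
    duration: float = 10.0,
    seed: int | None = None,
    std_frac: float = 0.10,
    tick_seconds: float = DEFAULT_TICK_SECONDS,
    dt_correction: bool = True,
) -> float:
    """Drive one pixel (1x1 kernel of weight 1) with an ISI-normal train
    and return output events per second of stimulus."""
    t_r_ticks = max(1, int(round(t_r_seconds / tick_seconds)))
    cfg = UnitConfig(
        n_x=1,
        n_y=1,
        th=th,
        t_r=t_r_ticks,
        b_tr=b_tr_for(t_r_ticks),
        n_kernels=1,
        dt_correction=dt_correction,
    )
    unit = ConvUnit(cfg, [KernelSpec(np.array([[1]]))])
    train = gen_isi_train(
        ISITrainSpec(f_in=f_in, duration=duration, std_frac=std_frac, seed=seed,
                     tick_seconds=tick_seconds)
    )
    n_out = 0
    for ev in train.events:
        outs, _ = unit.process_event(ev._replace(k=0))
        n_out += len(outs)
    return n_out / duration


def characterize_saturation(
    f_in_grid,
    t_r_list,
    th: int = 10,
    reps: int = 3,
    duration: float = 10.0,
    seed: int = 0,
    std_frac: float = 0.10,
    tick_seconds: float = DEFAULT_TICK_SECONDS,
) -> pd.DataFrame:
    """Measure mean/std output rate over ``reps`` seeded repetitions for
    every (T_R, f_in) grid point.  Returns a tidy frame with columns
    ``t_r``, ``f_in``, ``f_out_mean``, ``f_out_std``."""
    rows = []
    trial = 0
    for t_r in t_r_list:
        for f_in in f_in_grid:
            rates = []
            for _ in range(reps):
                rates.append(
                    measure_output_rate(
                        f_in, t_r, th=th, duration=duration, seed=seed + trial,
                        std_frac=std_frac, tick_seconds=tick_seconds,
                    )
                )
                trial += 1
            rows.append(
                {
                    "t_r": t_r,
                    "f_in": f_in,
                    "f_out_mean": float(np.mean(rates)),
                    "f_out_std": float(np.std(rates)),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Recognition decision rule
# ---------------------------------------------------------------------------


@dataclass
class RecognitionResult:
    intervals: list[tuple[int, int, str]]
    counts: list[dict[str, int]] = field(default_factory=list)
    decisions: list[str | None] = field(default_factory=list)

    @property
    def n_correct(self) -> int:
        return sum(
            1 for (_, _, label), dec in zip(self.intervals, self.decisions) if dec == label
        )

    @property
    def recognition_rate(self) -> float:
        """Correct decisions over total intervals, in percent."""
        if not self.intervals:
            return 0.0
        return 100.0 * self.n_correct / len(self.intervals)


def classify_symbols(
    output: EventStream,
    intervals: list[tuple[int, int, str]],
    labels: tuple[str, ...] = SYMBOLS,
) -> RecognitionResult:
    """Apply the strict-maximum positive-event count rule per interval.

    Output events must carry ``k`` identifying the output neuron (index
    into ``labels``).  Ties and silent intervals are unclassified and
    count as incorrect.
    """
    ordered = sorted(intervals, key=lambda iv: iv[0])
    for (s0, e0, _), (s1, _, _) in zip(ordered, ordered[1:]):
        if s1 < e0:
            raise ValueError(f"intervals overlap: [{s0}, {e0}) and [{s1}, ...)")
    result = RecognitionResult(intervals=list(intervals))
    for t_start, t_end, _label in intervals:
        counts = {name: 0 for name in labels}
        for ev in output.events:
            if t_start <= ev.t < t_end and ev.p > 0 and ev.k is not None:
                counts[labels[ev.k]] += 1
        result.counts.append(counts)
        best = max(counts.values())
        winners = [name for name, c in counts.items() if c == best]
        result.decisions.append(winners[0] if best > 0 and len(winners) == 1 else None)
    return result


# ---------------------------------------------------------------------------
# Stream statistics and energy arithmetic
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StreamStats:
    count: int
    duration_seconds: float
    rate_eps: float

    @property
    def rate_keps(self) -> float:
        return self.rate_eps / 1e3

    @property
    def rate_meps(self) -> float:
        return self.rate_eps / 1e6


def stream_stats(stream: EventStream) -> StreamStats:
    """(event count, duration, mean event rate) for a stream."""
    n = len(stream.events)
    if n == 0:
        return StreamStats(0, 0.0, 0.0)
    duration = stream.duration_seconds
    if duration == 0:
        if n > 1:
            raise ValueError(f"{n} events with zero duration")
        return StreamStats(n, 0.0, 0.0)
    return StreamStats(n, duration, n / duration)


@dataclass(frozen=True)
class EnergyMetrics:
    energy_joules: float
    classifications_per_joule: float


def energy_metrics(power_watts: float, t_symbol_seconds: float) -> EnergyMetrics:
    """Energy per classification (power x presentation time) and its inverse."""
    if power_watts <= 0:
        raise ValueError("power must be positive")
    if t_symbol_seconds <= 0:
        raise ValueError("symbol presentation time must be positive")
    energy = power_watts * t_symbol_seconds
    return EnergyMetrics(energy, 1.0 / energy)
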