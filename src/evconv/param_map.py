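"""Frame-to-event parameter mapping.

Stage one deterministically rescales a frame-trained parameter set to
the fixed-point hardware ranges: every layer threshold is scaled up to a
common target (128 by default) with the kernel weights kept
proportional, leakage rates scale with the threshold, and
rate-saturation periods are left untouched.  Stage two is a generic,
fully seeded simulated-annealing fine-tuner driven by an arbitrary
simulator-evaluation callback.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np


@dataclass(frozen=True)
class LayerParam:
    """Parameters of one convolutional layer.

    ``th`` is the firing threshold; ``lr`` the leakage rate in
    threshold-units per second (threshold over the time leakage takes to
    drain it to reset); ``t_r`` the rate-saturation period in seconds
    (``None`` when the layer has no rate limitation); ``kernel_scale``
    the factor applied to this layer's kernel weights.
    """

    th: float
    lr: float
    t_r: float | None = None
    kernel_scale: float = 1.0


@dataclass(frozen=True)
class LayerParams:
    layers: tuple[LayerParam, ...]
    names: tuple[str, ...] = ()

    def __post_init__(self):
        if self.names and len(self.names) != len(self.layers):
            raise ValueError("names/layers length mismatch")
        for p in self.layers:
            if p.th <= 0:
                raise ValueError(f"layer threshold must be positive, got {p.th}")
            if p.t_r is not None and p.t_r < 0:
                raise ValueError(f"rate-saturation period must be >= 0, got {p.t_r}")

    def to_text(self) -> str:
        lines = ["layer\tth\tlr\tt_r\tkernel_scale"]
        names = self.names or tuple(str(i + 1) for i in range(len(self.layers)))
        for name, p in zip(names, self.layers):
            tr = "" if p.t_r is None else repr(p.t_r)
            lines.append(f"{name}\t{p.th!r}\t{p.lr!r}\t{tr}\t{p.kernel_scale!r}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "LayerParams":
        lines = [ln for ln in text.splitlines() if ln.strip()]
        names, layers = [], []
        for ln in lines[1:]:
            name, th, lr, tr, ks = ln.split("\t")
            names.append(name)
            layers.append(
                LayerParam(float(th), float(lr), float(tr) if tr else None, float(ks))
            )
        return cls(tuple(layers), tuple(names))


#: Frame-domain starting point for the bundled poker network (four
#: convolutional layers; rate saturation only in layers 2 and 3).
POKER_SOURCE_PARAMS = LayerParams(
    layers=(
        LayerParam(th=0.64, lr=0.72),
        LayerParam(th=1.42, lr=0.90, t_r=0.10e-3),
        LayerParam(th=7.36, lr=1.21, t_r=0.46e-3),
        LayerParam(th=2.17, lr=0.72),
    ),
    names=("C1", "C3", "C5", "C6"),
)


def round_half_away(x: float) -> int:
    """Round to nearest integer, ties away from zero."""
    return int(math.copysign(math.floor(abs(x) + 0.5), x))


def scale_kernel(weights: np.ndarray, factor: float) -> np.ndarray:
    """Scale integer/float kernel weights and round half-away-from-zero."""
    scaled = np.asarray(weights, dtype=float) * factor
    return np.where(scaled >= 0, np.floor(scaled + 0.5), -np.floor(-scaled + 0.5)).astype(
        np.int64
    )


def scale_parameters(src: LayerParams, target_th: int = 128) -> LayerParams:
    """Stage-one mapping: raise every threshold to ``target_th``.

    Kernel scale factors and leakage rates grow by ``target_th / th``;
    rate-saturation periods are unchanged.  Idempotent once thresholds
    equal the target.
    """
    if target_th <= 0:
        raise ValueError("target threshold must be positive")
    out = []
    for p in src.layers:
        factor = target_th / p.th
        out.append(
            replace(
                p,
                th=float(target_th),
                lr=p.lr * factor,
                kernel_scale=p.kernel_scale * factor,
            )
        )
    return LayerParams(tuple(out), src.names)


def leak_settings(lr: float, tick_seconds: float, n_leak: int = 1) -> tuple[int, int]:
    """(n_leak, t_leak_ticks) approximating a leakage rate in units/s."""
    if lr <= 0:
        return 0, 0
    t_leak = max(1, int(round(n_leak / (lr * tick_seconds))))
    return n_leak, t_leak


# ---------------------------------------------------------------------------
# Simulated-annealing fine-tuner
# ---------------------------------------------------------------------------


@dataclass
class AnnealResult:
    best: LayerParams
    best_score: float
    accepted: int = 0
    rejected: int = 0
    non_finite: int = 0
    trace: list[float] = field(default_factory=list)


def _propose(params: LayerParams, rng: np.random.Generator, log_step: float, th_step: int) -> LayerParams:
    layers = list(params.layers)
    i = int(rng.integers(len(layers)))
    p = layers[i]
    which = rng.integers(3)
    if which == 0:  # integer jitter on the threshold
        th = max(1, round_half_away(p.th) + int(rng.integers(-th_step, th_step + 1)))
        p = replace(p, th=float(th))
    elif which == 1:  # log-scale jitter on the leakage rate
        p = replace(p, lr=p.lr * math.exp(rng.normal(0.0, log_step)))
    elif p.t_r is not None:  # log-scale jitter on the time constant
        p = replace(p, t_r=p.t_r * math.exp(rng.normal(0.0, log_step)))
    layers[i] = p
    return LayerParams(tuple(layers), params.names)


def anneal_parameters(
    initial: LayerParams,
    objective,
    schedule: tuple[float, float, int] = (1.0, 0.95, 100),
    seed: int | None = None,
    log_step: float = 0.1,
    th_step: int = 4,
) -> AnnealResult:
    """Maximize ``objective(LayerParams) -> float`` by simulated annealing.

    ``schedule`` is ``(T0, cooling, iterations)`` with geometric cooling.
    Proposals are Gaussian on the log of time constants and integer
    jitters on thresholds; acceptance follows ``exp(delta / T)``.
    Non-finite objective values reject the proposal.  Returns the
    best-seen parameters; fully deterministic under a fixed seed.
    """
    t0, cooling, iters = schedule
    rng = np.random.default_rng(seed)
    current = initial
    current_score = float(objective(current))
    if not math.isfinite(current_score):
        raise ValueError("objective is non-finite at the initial parameters")
    result = AnnealResult(best=current, best_score=current_score)
    temp = t0
    for _ in range(int(iters)):
        cand = _propose(current, rng, log_step, th_step)
        try:
            score = float(objective(cand))
        except (ValueError, ArithmeticError):
            score = float("nan")
        if not math.isfinite(score):
            result.non_finite += 1
            result.rejected += 1
        else:
            delta = score - current_score
            if delta >= 0 or rng.random() < math.exp(delta / max(temp, 1e-300)):
                current, current_score = cand, score
                result.accepted += 1
                if score > result.best_score:
                    result.best, result.best_score = cand, score
            else:
                result.rejected += 1
        result.trace.append(current_score)
        temp *= cooling
    return result
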