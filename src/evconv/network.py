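"""Multi-layer network assembly and discrete-event simulation.

A network is a grid of nodes (convolutional units plus router-only
placeholders) with destination-driven routing tables, an input splitter,
an output merger, and optional subsampling links that right-shift event
addresses by one bit (merging each 2x2 window into one pixel).

The engine is a logical-time discrete-event simulator: each unit
processes one event at a time, busy for the cycle count given by the
cost model.  Traffic control drops an event at the *network input*
whenever any node's FIFO is full at the instant the event is offered;
internal links never drop.  Processed events keep their original
timestamps — congestion delays live in the units' completion times, not
in payload timestamps.
"""

from __future__ import annotations

import heapq
from collections import deque
from dataclasses import dataclass, field

import numpy as np
import yaml

from .aer_io import Event, EventStream
from .conv_unit import ConvUnit, CostModel, KernelSpec, UnitConfig
from .errors import ConfigurationError
from .router import NodeAddress, RoutingTable, wrap_outgoing


@dataclass
class NodeSpec:
    """One grid slot: a convolutional unit or a router-only passthrough."""

    unit: UnitConfig | None = None
    kernels: list[KernelSpec] = field(default_factory=list)

    @property
    def is_conv(self) -> bool:
        return self.unit is not None


@dataclass
class NetworkConfig:
    grid_shape: tuple[int, int]  # (rows, cols)
    nodes: dict[NodeAddress, NodeSpec]
    routing: dict[NodeAddress, RoutingTable] = field(default_factory=dict)
    subsample_links: set[tuple[NodeAddress, NodeAddress]] = field(default_factory=set)
    input_targets: list[tuple[NodeAddress, int]] = field(default_factory=list)
    output_sources: list[NodeAddress] = field(default_factory=list)

    def validate(self) -> None:
        rows, cols = self.grid_shape
        for addr in self.nodes:
            if not (0 <= addr.col < cols and 0 <= addr.row < rows):
                raise ConfigurationError(f"node {addr} outside grid {self.grid_shape}")
        for src, table in self.routing.items():
            if src not in self.nodes:
                raise ConfigurationError(f"routing table for unknown node {src}")
            for dest, kid in table.destinations:
                spec = self.nodes.get(dest)
                if spec is None:
                    raise ConfigurationError(f"dangling destination {dest} from {src}")
                if spec.is_conv and not 0 <= kid < len(spec.kernels):
                    raise ConfigurationError(
                        f"destination {dest} has no kernel id {kid} (from {src})"
                    )
        for dest, kid in self.input_targets:
            spec = self.nodes.get(dest)
            if spec is None:
                raise ConfigurationError(f"input splitter targets unknown node {dest}")
            if spec.is_conv and not 0 <= kid < len(spec.kernels):
                raise ConfigurationError(f"input target {dest} has no kernel id {kid}")
        for src in self.output_sources:
            if src not in self.nodes:
                raise ConfigurationError(f"output merger lists unknown node {src}")


def subsample_address(ev: Event) -> Event:
    """Drop the LSB of both coordinates (2x2 window -> one pixel)."""
    return ev._replace(x=ev.x >> 1, y=ev.y >> 1)


def count_architecture(cfg: NetworkConfig) -> tuple[int, int, int]:
    """(neurons, synapses, kernels) with full fan-in synapse counting.

    Each convolutional node contributes ``n_x * n_y`` neurons and, per
    loaded kernel, ``n_x * n_y * kernel_size`` synapses (border clipping
    ignored).
    """
    neurons = synapses = kernels = 0
    for spec in cfg.nodes.values():
        if not spec.is_conv:
            continue
        n = spec.unit.n_x * spec.unit.n_y
        neurons += n
        kernels += len(spec.kernels)
        synapses += n * sum(k.size for k in spec.kernels)
    return neurons, synapses, kernels


# ---------------------------------------------------------------------------
# Simulation engine
# ---------------------------------------------------------------------------


@dataclass
class SimLog:
    offered_inputs: int = 0
    processed_inputs: int = 0
    dropped_inputs: int = 0
    per_node_events: dict[NodeAddress, int] = field(default_factory=dict)
    internal_events: int = 0
    output: EventStream = field(default_factory=EventStream)

    @property
    def processed_fraction(self) -> float:
        return self.processed_inputs / self.offered_inputs if self.offered_inputs else 1.0


class _NodeRuntime:
    __slots__ = ("addr", "unit", "table", "queue", "in_service", "depth", "processed")

    def __init__(self, addr: NodeAddress, unit: ConvUnit | None, table: RoutingTable, depth: int):
        self.addr = addr
        self.unit = unit
        self.table = table
        self.queue: deque[Event] = deque()
        self.in_service = 0
        self.depth = depth
        self.processed = 0

    @property
    def occupancy(self) -> int:
        return len(self.queue) + self.in_service

    @property
    def full_fifo(self) -> bool:
        return self.occupancy >= self.depth


class Network:
    """An instantiated grid of nodes ready to simulate."""

    def __init__(self, cfg: NetworkConfig, cost_model: CostModel | None = None):
        cfg.validate()
        self.cfg = cfg
        self.cost_model = cost_model or CostModel()
        self.nodes: dict[NodeAddress, _NodeRuntime] = {}
        for addr, spec in cfg.nodes.items():
            unit = None
            if spec.is_conv:
                unit = ConvUnit(spec.unit, spec.kernels, self.cost_model)
            table = cfg.routing.get(addr, RoutingTable())
            depth = spec.unit.fifo_depth_out if spec.is_conv else 1
            self.nodes[addr] = _NodeRuntime(addr, unit, table, depth)
        self._conv_nodes = [rt for rt in self.nodes.values() if rt.unit is not None]
        self._source_index = {addr: i for i, addr in enumerate(cfg.output_sources)}

    def _any_full(self) -> bool:
        return any(rt.full_fifo for rt in self._conv_nodes)

    def simulate(self, stream: EventStream) -> SimLog:
        """Run the stream through the network and account every event."""
        log = SimLog(offered_inputs=len(stream.events))
        heap: list[tuple[int, int, int, object]] = []
        seq = 0
        _INPUT, _DONE = 0, 1
        for ev in stream.events:
            heap.append((ev.t, seq, _INPUT, ev))
            seq += 1
        heapq.heapify(heap)
        outputs: list[Event] = []

        def deliver(addr: NodeAddress, ev: Event, now: int) -> None:
            rt = self.nodes[addr]
            if rt.unit is None:
                return  # router-only slot: no local processing
            rt.queue.append(ev)
            try_start(rt, now)

        def try_start(rt: _NodeRuntime, now: int) -> None:
            nonlocal seq
            if rt.in_service or not rt.queue:
                return
            ev = rt.queue.popleft()
            rt.in_service = 1
            outs, cycles = rt.unit.process_event(ev, t_proc=now)
            heapq.heappush(heap, (now + cycles, seq, _DONE, (rt, outs)))
            seq += 1

        while heap:
            now, _, kind, data = heapq.heappop(heap)
            if kind == _INPUT:
                ev: Event = data
                if self._any_full():
                    log.dropped_inputs += 1
                    continue
                log.processed_inputs += 1
                for addr, kid in self.cfg.input_targets:
                    deliver(addr, ev._replace(k=kid), now)
            else:  # _DONE
                rt, outs = data
                rt.in_service = 0
                rt.processed += 1
                rt.unit.fifo_out_occupancy = 0  # drained by the router below
                for out in outs:
                    log.internal_events += 1
                    src_idx = self._source_index.get(rt.addr)
                    if src_idx is not None:
                        # merger output; k tags the source node for analysis
                        outputs.append(out._replace(k=src_idx))
                    for clone in wrap_outgoing(rt.addr, out, rt.table):
                        payload = clone.payload
                        if (rt.addr, clone.header) in self.cfg.subsample_links:
                            payload = subsample_address(payload)
                        deliver(clone.header, payload, now)
                try_start(rt, now)

        assert log.processed_inputs + log.dropped_inputs == log.offered_inputs
        outputs.sort(key=lambda ev: ev.t)
        out_space = (1, 1)
        if outputs:
            out_space = (max(e.x for e in outputs) + 1, max(e.y for e in outputs) + 1)
        log.output = EventStream(outputs, out_space, stream.tick_seconds)
        log.per_node_events = {rt.addr: rt.processed for rt in self._conv_nodes}
        return log


def build_network(cfg: NetworkConfig, cost_model: CostModel | None = None) -> Network:
    """Validate ``cfg`` and instantiate a simulator with fresh state."""
    return Network(cfg, cost_model)


# ---------------------------------------------------------------------------
# YAML serialization
# ---------------------------------------------------------------------------


def _addr_key(addr: NodeAddress) -> str:
    return f"{addr.col},{addr.row}"


def _parse_addr(key: str) -> NodeAddress:
    col, row = (int(v) for v in str(key).split(","))
    return NodeAddress(col, row)


def config_to_yaml(cfg: NetworkConfig) -> str:
    doc: dict = {
        "grid": {"rows": cfg.grid_shape[0], "cols": cfg.grid_shape[1]},
        "nodes": {},
        "routing": {},
        "subsample_links": [[_addr_key(a), _addr_key(b)] for a, b in sorted(cfg.subsample_links)],
        "input": [[_addr_key(a), k] for a, k in cfg.input_targets],
        "output": [_addr_key(a) for a in cfg.output_sources],
    }
    for addr, spec in cfg.nodes.items():
        if spec.is_conv:
            u = spec.unit
            doc["nodes"][_addr_key(addr)] = {
                "n_x": u.n_x,
                "n_y": u.n_y,
                "th": u.th,
                "n_bits": u.n_bits,
                "t_leak": u.t_leak,
                "n_leak": u.n_leak,
                "t_r": u.t_r,
                "b_tr": u.b_tr,
                "n_kernels": u.n_kernels,
                "fifo_depth_in": u.fifo_depth_in,
                "fifo_depth_out": u.fifo_depth_out,
                "kernels": [
                    {
                        "shift_x": k.shift_x,
                        "shift_y": k.shift_y,
                        "weights": k.weights.tolist(),
                    }
                    for k in spec.kernels
                ],
            }
        else:
            doc["nodes"][_addr_key(addr)] = "router"
    for src, table in cfg.routing.items():
        doc["routing"][_addr_key(src)] = [[_addr_key(d), k] for d, k in table.destinations]
    return yaml.safe_dump(doc, sort_keys=True)


def config_from_yaml(text: str) -> NetworkConfig:
    doc = yaml.safe_load(text)
    grid_shape = (int(doc["grid"]["rows"]), int(doc["grid"]["cols"]))
    nodes: dict[NodeAddress, NodeSpec] = {}
    for key, body in doc.get("nodes", {}).items():
        addr = _parse_addr(key)
        if addr in nodes:
            raise ConfigurationError(f"duplicate node address {addr}")
        if body == "router":
            nodes[addr] = NodeSpec()
            continue
        kernels = [
            KernelSpec(np.array(k["weights"]), k.get("shift_x", 0), k.get("shift_y", 0))
            for k in body.get("kernels", [])
        ]
        unit = UnitConfig(
            n_x=int(body["n_x"]),
            n_y=int(body["n_y"]),
            th=int(body.get("th", 128)),
            n_bits=int(body.get("n_bits", 9)),
            t_leak=int(body.get("t_leak", 0)),
            n_leak=int(body.get("n_leak", 0)),
            t_r=int(body.get("t_r", 1)),
            b_tr=int(body.get("b_tr", 7)),
            n_kernels=int(body.get("n_kernels", max(8, len(kernels)))),
            fifo_depth_in=int(body.get("fifo_depth_in", 64)),
            fifo_depth_out=int(body.get("fifo_depth_out", 64)),
        )
        nodes[addr] = NodeSpec(unit=unit, kernels=kernels)
    routing = {
        _parse_addr(src): RoutingTable([(_parse_addr(d), int(k)) for d, k in dests])
        for src, dests in doc.get("routing", {}).items()
    }
    cfg = NetworkConfig(
        grid_shape=grid_shape,
        nodes=nodes,
        routing=routing,
        subsample_links={(_parse_addr(a), _parse_addr(b)) for a, b in doc.get("subsample_links", [])},
        input_targets=[(_parse_addr(a), int(k)) for a, k in doc.get("input", [])],
        output_sources=[_parse_addr(a) for a in doc.get("output", [])],
    )
    cfg.validate()
    return cfg


# ---------------------------------------------------------------------------
# Bundled poker-recognition topology
# ---------------------------------------------------------------------------


def _gabor_kernel(size: int, theta: float, scale: int = 60) -> np.ndarray:
    """Integer Gabor patch: oriented edge detector for the first layer."""
    half = (size - 1) / 2.0
    ys, xs = np.mgrid[0:size, 0:size] - half
    xr = xs * np.cos(theta) + ys * np.sin(theta)
    yr = -xs * np.sin(theta) + ys * np.cos(theta)
    sigma, lam = size / 4.0, size / 1.5
    g = np.exp(-(xr**2 + yr**2) / (2 * sigma**2)) * np.cos(2 * np.pi * xr / lam)
    return np.round(scale * g).astype(np.int64)


def poker_network(
    seed: int = 0,
    fifo_depth: int = 64,
    tick_seconds: float = 20e-9,
) -> NetworkConfig:
    """The bundled 4-layer poker-symbol topology on a 6x4 grid.

    22 convolutional nodes (6 of 28x28 in the first layer with one 10x10
    kernel each, 4 of 10x10 with six 5x5 kernels, 8 single-pixel nodes
    with four 5x5 kernels, 4 single-pixel output nodes with eight 1x1
    kernels) plus 2 router-only slots.  Subsampling links halve the
    address space between layers 1-2 and 2-3.

    The trained weights of the original network are not published; the
    first layer uses oriented Gabor patches and the deeper layers use
    seeded placeholder integers, so the topology, counts and dynamics
    are exercised with representative (not trained) kernels.
    """
    rng = np.random.default_rng(seed)
    # time constants: layer-2/3 rate-saturation periods of 0.10 ms and
    # 0.46 ms at a 20 ns tick; other layers effectively unconstrained.
    tr3 = int(round(0.10e-3 / tick_seconds))
    tr5 = int(round(0.46e-3 / tick_seconds))

    def unit(n: int, th: int, t_r: int, b_tr: int, n_kernels: int, in_space: int) -> UnitConfig:
        return UnitConfig(
            n_x=n,
            n_y=n,
            th=th,
            t_r=t_r,
            b_tr=b_tr,
            n_kernels=n_kernels,
            in_addr_space=(in_space, in_space),
            fifo_depth_in=fifo_depth,
            fifo_depth_out=fifo_depth,
        )

    from .conv_unit import b_tr_for

    nodes: dict[NodeAddress, NodeSpec] = {}
    c1 = [NodeAddress(0, r) for r in range(6)]
    c3 = [NodeAddress(1, r) for r in range(4)]
    router_only = [NodeAddress(1, 4), NodeAddress(1, 5)]
    c5 = [NodeAddress(2, r) for r in range(6)] + [NodeAddress(3, 4), NodeAddress(3, 5)]
    c6 = [NodeAddress(3, r) for r in range(4)]

    for i, addr in enumerate(c1):
        k = KernelSpec(_gabor_kernel(10, np.pi * i / 6.0), shift_x=-2, shift_y=-2)
        nodes[addr] = NodeSpec(unit(28, 128, 1, 7, 1, 32), [k])
    for addr in c3:
        ks = [
            KernelSpec(rng.integers(-20, 21, size=(5, 5)), shift_x=-2, shift_y=-2)
            for _ in range(6)
        ]
        nodes[addr] = NodeSpec(unit(10, 128, tr3, b_tr_for(tr3), 6, 14), ks)
    for addr in router_only:
        nodes[addr] = NodeSpec()
    for addr in c5:
        ks = [KernelSpec(rng.integers(-20, 21, size=(5, 5))) for _ in range(4)]
        nodes[addr] = NodeSpec(unit(1, 128, tr5, b_tr_for(tr5), 4, 5), ks)
    for addr in c6:
        ks = [KernelSpec(rng.integers(-30, 31, size=(1, 1))) for _ in range(8)]
        nodes[addr] = NodeSpec(unit(1, 128, 1, 7, 8, 1), ks)

    routing: dict[NodeAddress, RoutingTable] = {}
    subsample: set[tuple[NodeAddress, NodeAddress]] = set()
    for i, src in enumerate(c1):
        routing[src] = RoutingTable([(dst, i) for dst in c3])
        subsample.update((src, dst) for dst in c3)
    for i, src in enumerate(c3):
        routing[src] = RoutingTable([(dst, i) for dst in c5])
        subsample.update((src, dst) for dst in c5)
    for i, src in enumerate(c5):
        routing[src] = RoutingTable([(dst, i) for dst in c6])
    for src in c6:
        routing[src] = RoutingTable()

    cfg = NetworkConfig(
        grid_shape=(6, 4),
        nodes=nodes,
        routing=routing,
        subsample_links=subsample,
        input_targets=[(addr, 0) for addr in c1],
        output_sources=list(c6),
    )
    cfg.validate()
    return cfg
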