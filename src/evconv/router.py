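"""Destination-driven event routing on a 2D mesh.

Every event travelling the mesh carries a header naming its destination
node.  Routers deliver locally on an address match and otherwise forward
along the dimension-order (column-first) shortest path, so the number of
hops always equals the Manhattan distance.  Locally generated events are
cloned once per routing-table destination, each clone carrying the
kernel id that tells the destination unit which kernel to apply.

Port convention: ``E``/``W`` correct the column (East = increasing
column), ``N``/``S`` correct the row (North = increasing row).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .aer_io import Event
from .errors import ConfigurationError, RoutingError

PORTS = ("N", "S", "E", "W")


@dataclass(frozen=True, order=True)
class NodeAddress:
    col: int
    row: int


@dataclass
class RoutingTable:
    """Destinations (with per-destination kernel ids) for local events."""

    destinations: list[tuple[NodeAddress, int]] = field(default_factory=list)

    def __post_init__(self):
        addrs = [d for d, _ in self.destinations]
        if len(set(addrs)) != len(addrs):
            raise ConfigurationError("routing-table destinations must be distinct")

    def __len__(self) -> int:
        return len(self.destinations)


@dataclass(frozen=True)
class RoutedEvent:
    header: NodeAddress
    payload: Event


def route_incoming(
    node: NodeAddress, ev: RoutedEvent, grid_shape: tuple[int, int] | None = None
) -> tuple[str, str | None]:
    """Routing decision at ``node`` for an arriving event.

    Returns ``("deliver_local", None)`` on an address match, else
    ``("forward", port)`` with the dimension-order port choice.
    ``grid_shape`` is ``(rows, cols)``; when given, off-grid headers
    raise ``RoutingError``.
    """
    dest = ev.header
    if grid_shape is not None:
        rows, cols = grid_shape
        if not (0 <= dest.col < cols and 0 <= dest.row < rows):
            raise RoutingError(f"header {dest} outside grid {grid_shape}")
    if dest == node:
        return ("deliver_local", None)
    if dest.col > node.col:
        return ("forward", "E")
    if dest.col < node.col:
        return ("forward", "W")
    if dest.row > node.row:
        return ("forward", "N")
    return ("forward", "S")


def wrap_outgoing(node: NodeAddress, ev: Event, table: RoutingTable) -> list[RoutedEvent]:
    """Clone a locally generated event once per routing-table destination."""
    return [
        RoutedEvent(header=dest, payload=ev._replace(k=kernel_id))
        for dest, kernel_id in table.destinations
    ]


def hop_count(src: NodeAddress, dst: NodeAddress) -> int:
    """Manhattan distance between two mesh nodes."""
    return abs(src.col - dst.col) + abs(src.row - dst.row)


def step(node: NodeAddress, port: str) -> NodeAddress:
    """Neighbouring address reached by leaving ``node`` through ``port``."""
    if port == "E":
        return NodeAddress(node.col + 1, node.row)
    if port == "W":
        return NodeAddress(node.col - 1, node.row)
    if port == "N":
        return NodeAddress(node.col, node.row + 1)
    if port == "S":
        return NodeAddress(node.col, node.row - 1)
    raise ValueError(f"unknown port {port!r}")
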