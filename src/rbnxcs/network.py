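"""NK random Boolean networks: construction, synchronous dynamics, state space.

An NK Boolean network has N binary nodes, each reading K input nodes through
a fixed randomly drawn truth table.  All nodes update synchronously, so the
2**N states form a functional graph that decomposes into attractor cycles and
their basins of attraction.  This module generates such networks, provides the
fully specified 3-node AND/XOR motifs used as worked examples, simulates the
synchronous dynamics, and maps the complete state space exhaustively.

Conventions
-----------
* Network states are bit strings; node 1 is the leftmost character.
* A truth-table row index is formed by reading the input bits in stored input
  order with the first input as the most significant bit.
* Action index ``i`` (1-based) flips the ``i``-th character; action 0 is
  "no action".
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "BooleanNetwork",
    "Attractor",
    "StateSpaceGraph",
    "generate_network",
    "motif_network",
    "synchronous_step",
    "flip_bit",
    "map_state_space",
    "bit_flip_distance",
    "successor_table",
    "state_to_int",
    "int_to_state",
    "save_network",
    "load_network",
]

#: exhaustive state-space enumeration is refused above this many nodes
MAX_MAP_NODES = 24


def state_to_int(state: str) -> int:
    """Encode a bit string (node 1 leftmost) as an integer (node 1 = MSB)."""
    return int(state, 2)


def int_to_state(x: int, n_nodes: int) -> str:
    """Inverse of :func:`state_to_int`."""
    return format(x, f"0{n_nodes}b")


def _check_state(state: str, n_nodes: int) -> None:
    if len(state) != n_nodes or any(c not in "01" for c in state):
        raise ValueError(
            f"state {state!r} is not a {n_nodes}-character bit string"
        )


@dataclass(frozen=True)
class BooleanNetwork:
    """Immutable wiring and truth tables of an NK Boolean network.

    Attributes
    ----------
    n_nodes : int
        Number of nodes N.
    k_inputs : int
        Number of inputs K per node.
    inputs : tuple of tuple of int
        For each node, the K input node indices (1-based), in stored order.
    truth_tables : tuple of tuple of int
        For each node, the 2**K output bits; row indices read the input bits
        in stored order, first input as most significant bit.
    """

    n_nodes: int
    k_inputs: int
    inputs: tuple[tuple[int, ...], ...]
    truth_tables: tuple[tuple[int, ...], ...]

    def __post_init__(self) -> None:
        n, k = self.n_nodes, self.k_inputs
        if n < 1 or k < 1:
            raise ValueError("n_nodes and k_inputs must be positive")
        if len(self.inputs) != n or len(self.truth_tables) != n:
            raise ValueError("inputs and truth_tables must list every node")
        for node, (inp, table) in enumerate(zip(self.inputs, self.truth_tables), 1):
            if len(inp) != k:
                raise ValueError(f"node {node} must have exactly {k} inputs")
            if any(i < 1 or i > n for i in inp):
                raise ValueError(f"node {node} has an input index outside [1, {n}]")
            if len(table) != 2**k:
                raise ValueError(f"node {node} must have a {2**k}-entry truth table")
            if any(b not in (0, 1) for b in table):
                raise ValueError(f"node {node} truth table must contain only 0/1")

    def step(self, state: str) -> str:
        """Synchronously update ``state`` by one time step."""
        return synchronous_step(self, state)

    def to_dict(self) -> dict:
        return {
            "n": self.n_nodes,
            "k": self.k_inputs,
            "inputs": [list(i) for i in self.inputs],
            "truth_tables": [list(t) for t in self.truth_tables],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BooleanNetwork":
        return cls(
            n_nodes=int(d["n"]),
            k_inputs=int(d["k"]),
            inputs=tuple(tuple(int(i) for i in row) for row in d["inputs"]),
            truth_tables=tuple(tuple(int(b) for b in row) for row in d["truth_tables"]),
        )


def generate_network(n: int, k: int, rng) -> BooleanNetwork:
    """Draw a random NK network: K distinct inputs per node, random tables.

    Input nodes are sampled uniformly without replacement (self-loops are
    allowed, duplicate links are not); every truth-table bit is an independent
    fair coin.  Identical ``(n, k, seed)`` give identical networks.

    Parameters
    ----------
    rng : int or numpy.random.Generator
        Seed or generator driving the draw.
    """
    if k < 1 or k > n:
        raise ValueError(f"k must satisfy 1 <= k <= n (got n={n}, k={k})")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    inputs = tuple(
        tuple(int(i) + 1 for i in rng.choice(n, size=k, replace=False))
        for _ in range(n)
    )
    tables = tuple(
        tuple(int(b) for b in rng.integers(0, 2, size=2**k)) for _ in range(n)
    )
    return BooleanNetwork(n, k, inputs, tables)


_MOTIF_TABLES = {"AND": (0, 0, 0, 1), "XOR": (0, 1, 1, 0)}


def motif_network(logic: str) -> BooleanNetwork:
    """The 3-node clockwise motif: every node reads itself and its predecessor.

    Nodes are ordered A, B, C; A reads (A, C), B reads (B, A), C reads (C, B).
    All three nodes apply the named 2-input function (``"AND"`` or ``"XOR"``).
    """
    key = logic.upper()
    if key not in _MOTIF_TABLES:
        raise ValueError(f"unknown motif logic {logic!r}; expected 'AND' or 'XOR'")
    table = _MOTIF_TABLES[key]
    return BooleanNetwork(
        n_nodes=3,
        k_inputs=2,
        inputs=((1, 3), (2, 1), (3, 2)),
        truth_tables=(table, table, table),
    )


def synchronous_step(net: BooleanNetwork, state: str) -> str:
    """All nodes update at once from the pre-step state."""
    _check_state(state, net.n_nodes)
    bits = [int(c) for c in state]
    out = []
    for inp, table in zip(net.inputs, net.truth_tables):
        row = 0
        for i in inp:
            row = (row << 1) | bits[i - 1]
        out.append(str(table[row]))
    return "".join(out)


def flip_bit(state: str, index: int) -> str:
    """Apply action ``index``: flip the index-th character (1-based); 0 is a no-op."""
    if index == 0:
        return state
    if index < 1 or index > len(state):
        raise ValueError(
            f"action index {index} outside [0, {len(state)}] for state {state!r}"
        )
    pos = index - 1
    flipped = "1" if state[pos] == "0" else "0"
    return state[:pos] + flipped + state[pos + 1 :]


def successor_table(net: BooleanNetwork) -> np.ndarray:
    """Successor of every one of the 2**N states, as an int64 array.

    The state integer encoding is that of :func:`state_to_int`.
    """
    n = net.n_nodes
    if n > MAX_MAP_NODES:
        raise ValueError(
            f"state space of 2**{n} states exceeds the N <= {MAX_MAP_NODES} guard"
        )
    states = np.arange(2**n, dtype=np.int64)
    nxt = np.zeros_like(states)
    for node, (inp, table) in enumerate(zip(net.inputs, net.truth_tables), 1):
        row = np.zeros_like(states)
        for i in inp:
            row = (row << 1) | ((states >> (n - i)) & 1)
        bit = np.asarray(table, dtype=np.int64)[row]
        nxt |= bit << (n - node)
    return nxt


def _canonical_rotation(cycle: Sequence[str]) -> tuple[str, ...]:
    k = min(range(len(cycle)), key=lambda i: cycle[i])
    return tuple(cycle[k:]) + tuple(cycle[:k])


@dataclass(frozen=True)
class Attractor:
    """A state cycle, stored in canonical rotation.

    The cycle is rotated so that it starts at the lexicographically smallest
    state; a fixed point is a cycle of length 1.
    """

    cycle: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.cycle:
            raise ValueError("attractor cycle must be non-empty")
        n = len(self.cycle[0])
        for s in self.cycle:
            _check_state(s, n)
        if len(set(self.cycle)) != len(self.cycle):
            raise ValueError("attractor cycle must not repeat a state")
        object.__setattr__(self, "cycle", _canonical_rotation(self.cycle))

    @property
    def n_nodes(self) -> int:
        return len(self.cycle[0])

    @property
    def states(self) -> frozenset[str]:
        return frozenset(self.cycle)

    def __len__(self) -> int:
        return len(self.cycle)


def bit_flip_distance(a: Attractor, b: Attractor) -> int:
    """Minimum Hamming distance between any state of ``a`` and any of ``b``.

    This is the smallest number of simultaneous single-bit flips that would
    carry some state of one cycle directly onto some state of the other.
    """
    if a.n_nodes != b.n_nodes:
        raise ValueError("attractors are defined over different node counts")
    return min(
        bin(state_to_int(x) ^ state_to_int(y)).count("1")
        for x in a.cycle
        for y in b.cycle
    )


@dataclass(frozen=True)
class StateSpaceGraph:
    """Exhaustive map of the synchronous dynamics of one network.

    ``successor_array[s]`` is the successor of state integer ``s``;
    ``basin_array[s]`` is the index into ``attractors`` of the attractor that
    the trajectory from ``s`` eventually reaches.
    """

    n_nodes: int
    successor_array: np.ndarray
    attractors: tuple[Attractor, ...]
    basin_array: np.ndarray

    def successor(self, state: str) -> str:
        _check_state(state, self.n_nodes)
        return int_to_state(int(self.successor_array[state_to_int(state)]), self.n_nodes)

    def basin(self, state: str) -> int:
        """Index of the attractor whose basin contains ``state``."""
        _check_state(state, self.n_nodes)
        return int(self.basin_array[state_to_int(state)])

    def basin_sizes(self) -> tuple[int, ...]:
        counts = np.bincount(self.basin_array, minlength=len(self.attractors))
        return tuple(int(c) for c in counts)

    def basin_states(self, attractor_index: int) -> list[str]:
        return [
            int_to_state(int(s), self.n_nodes)
            for s in np.flatnonzero(self.basin_array == attractor_index)
        ]

    def to_dot(self) -> str:
        """Render the state-space graph in Graphviz DOT form.

        One node per state labelled with its bit string, one edge per
        successor; attractor states are drawn with a double border.
        """
        lines = ["digraph statespace {", "  node [shape=ellipse];"]
        on_cycle = {s for a in self.attractors for s in a.cycle}
        for s in sorted(on_cycle):
            lines.append(f'  "{s}" [peripheries=2];')
        for x in range(2**self.n_nodes):
            src = int_to_state(x, self.n_nodes)
            dst = int_to_state(int(self.successor_array[x]), self.n_nodes)
            lines.append(f'  "{src}" -> "{dst}";')
        lines.append("}")
        return "\n".join(lines) + "\n"


def map_state_space(net: BooleanNetwork) -> StateSpaceGraph:
    """Enumerate all 2**N states, find every attractor, assign every basin.

    Attractors are located by trajectory-following with visited-set cycle
    detection; each state inherits the basin of the attractor its trajectory
    reaches.  Refuses networks above ``MAX_MAP_NODES`` nodes.
    """
    n = net.n_nodes
    succ = successor_table(net)
    basin = np.full(2**n, -1, dtype=np.int64)
    cycles: list[list[int]] = []
    for s0 in range(2**n):
        if basin[s0] >= 0:
            continue
        path: list[int] = []
        on_path: dict[int, int] = {}
        s = s0
        while basin[s] < 0 and s not in on_path:
            on_path[s] = len(path)
            path.append(s)
            s = int(succ[s])
        if basin[s] >= 0:
            aid = int(basin[s])
        else:
            cycles.append(path[on_path[s] :])
            aid = len(cycles) - 1
        for q in path:
            basin[q] = aid
    attractors = tuple(
        Attractor(tuple(int_to_state(s, n) for s in cyc)) for cyc in cycles
    )
    return StateSpaceGraph(n, succ, attractors, basin)


def save_network(net: BooleanNetwork, path) -> None:
    """Write the network as a JSON document (1-based input indices)."""
    with open(path, "w") as fh:
        json.dump(net.to_dict(), fh, indent=1)
        fh.write("\n")


def load_network(path) -> BooleanNetwork:
    with open(path) as fh:
        return BooleanNetwork.from_dict(json.load(fh))
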