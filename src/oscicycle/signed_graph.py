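"""Signed directed graphs and the odd inhibitory cycle rule.

A network of excitatory (E) and inhibitory (I) populations is represented as
a directed graph whose edge signs are *derived from the source node*: every
edge leaving an inhibitory node is inhibitory, every edge leaving an
excitatory node is excitatory (Dale-type convention — a population is purely
E or purely I).

A directed cycle is *negative* when it contains an odd number of inhibitory
edges and *positive* otherwise.  Only negative cycles can support
oscillations (the odd inhibitory cycle rule); positive cycles settle into
synchrony or winner-take-all dynamics.  This module enumerates simple cycles,
classifies their parity, and performs the subnetwork-coverage combinatorics
used to count potential oscillators in the cortico-basal-ganglia network.
"""

from __future__ import annotations

import csv
import itertools
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import networkx as nx

from .exceptions import ArgumentError, SizeError

EXCITATORY = "E"
INHIBITORY = "I"

#: verdicts of :func:`classify_cycle`
CAPABLE = "oscillation-capable"
NOT_CAPABLE = "not-capable"

_MAX_CYCLE_NODES = 20


class SignedDigraph:
    """Directed graph with E/I-labelled nodes and source-sign-derived edges.

    Parameters
    ----------
    nodes
        Iterable of ``(name, sign)`` pairs, sign in ``{"E", "I"}``.
    edges
        Iterable of ``(source, target)`` pairs. Self-loops are allowed,
        duplicate directed edges are rejected.
    weights
        Optional mapping ``(source, target) -> positive magnitude``.
    """

    def __init__(
        self,
        nodes: Iterable[tuple[str, str]],
        edges: Iterable[tuple[str, str]],
        weights: dict[tuple[str, str], float] | None = None,
    ):
        self._signs: dict[str, str] = {}
        for name, sign in nodes:
            if sign not in (EXCITATORY, INHIBITORY):
                raise ArgumentError(
                    f"node {name!r}: sign must be 'E' or 'I', got {sign!r}"
                )
            if name in self._signs and self._signs[name] != sign:
                raise ArgumentError(
                    f"node {name!r} declared with both signs; a node is purely E or I"
                )
            self._signs[name] = sign
        self._edges: list[tuple[str, str]] = []
        seen = set()
        for s, t in edges:
            for endpoint in (s, t):
                if endpoint not in self._signs:
                    raise ArgumentError(f"edge ({s!r}, {t!r}): unknown node {endpoint!r}")
            if (s, t) in seen:
                raise ArgumentError(f"duplicate directed edge ({s!r}, {t!r})")
            seen.add((s, t))
            self._edges.append((s, t))
        self.weights: dict[tuple[str, str], float] = {}
        if weights:
            for (s, t), w in weights.items():
                if (s, t) not in seen:
                    raise ArgumentError(f"weight given for absent edge ({s!r}, {t!r})")
                if not w > 0:
                    raise ArgumentError(
                        f"weight magnitude for ({s!r}, {t!r}) must be positive, got {w}"
                    )
                self.weights[(s, t)] = float(w)

    # -- basic accessors ---------------------------------------------------
    @property
    def nodes(self) -> list[str]:
        return list(self._signs)

    @property
    def edges(self) -> list[tuple[str, str]]:
        return list(self._edges)

    def sign(self, node: str) -> str:
        return self._signs[node]

    def node_signs(self) -> dict[str, str]:
        return dict(self._signs)

    def edge_is_inhibitory(self, source: str, target: str) -> bool:
        """Edge sign is derived: inhibitory iff the source node is inhibitory."""
        if (source, target) not in set(self._edges):
            raise ArgumentError(f"no edge ({source!r}, {target!r})")
        return self._signs[source] == INHIBITORY

    def __len__(self) -> int:
        return len(self._signs)

    def __contains__(self, node: str) -> bool:
        return node in self._signs

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        for name, sign in self._signs.items():
            g.add_node(name, sign=sign)
        for s, t in self._edges:
            g.add_edge(s, t, inhibitory=self._signs[s] == INHIBITORY)
        return g

    def subgraph(self, keep: Iterable[str]) -> "SignedDigraph":
        keep = set(keep)
        unknown = keep - set(self._signs)
        if unknown:
            raise ArgumentError(f"unknown nodes {sorted(unknown)}")
        return SignedDigraph(
            [(n, s) for n, s in self._signs.items() if n in keep],
            [(s, t) for s, t in self._edges if s in keep and t in keep],
            {e: w for e, w in self.weights.items() if e[0] in keep and e[1] in keep},
        )

    # -- I/O ---------------------------------------------------------------
    @classmethod
    def from_json(cls, path: str | Path) -> "SignedDigraph":
        """Load from a single JSON document::

            {"nodes": [{"name": "Proto", "sign": "I"}, ...],
             "edges": [["Proto", "STN"], ...],
             "weights": {"Proto->STN": 1.0}}        # optional
        """
        doc = json.loads(Path(path).read_text())
        return cls.from_dict(doc)

    @classmethod
    def from_dict(cls, doc: dict) -> "SignedDigraph":
        nodes = [(n["name"], n["sign"]) for n in doc["nodes"]]
        edges = [tuple(e) for e in doc["edges"]]
        weights = None
        if "weights" in doc:
            weights = {}
            for key, w in doc["weights"].items():
                s, t = key.split("->")
                weights[(s.strip(), t.strip())] = w
        return cls(nodes, edges, weights)

    def to_dict(self) -> dict:
        doc: dict = {
            "nodes": [{"name": n, "sign": s} for n, s in self._signs.items()],
            "edges": [list(e) for e in self._edges],
        }
        if self.weights:
            doc["weights"] = {f"{s}->{t}": w for (s, t), w in self.weights.items()}
        return doc

    @classmethod
    def from_csv(cls, edge_path: str | Path, node_path: str | Path) -> "SignedDigraph":
        """Load from an edge list CSV (``source,target``) plus a node-sign
        table (``node,sign``). Header rows are detected and skipped."""
        nodes = []
        with open(node_path, newline="") as fh:
            for row in csv.reader(fh):
                if not row or row[0].strip().lower() == "node":
                    continue
                nodes.append((row[0].strip(), row[1].strip()))
        edges = []
        with open(edge_path, newline="") as fh:
            for row in csv.reader(fh):
                if not row or row[0].strip().lower() == "source":
                    continue
                edges.append((row[0].strip(), row[1].strip()))
        return cls(nodes, edges)

    def to_dot(self) -> str:
        """GraphViz DOT export; inhibitory edges are drawn with tee arrowheads."""
        lines = ["digraph G {"]
        for n, s in self._signs.items():
            shape = "circle" if s == EXCITATORY else "doublecircle"
            lines.append(f'  "{n}" [shape={shape}, label="{n} ({s})"];')
        for s, t in self._edges:
            style = "arrowhead=tee, color=red" if self._signs[s] == INHIBITORY else "color=black"
            lines.append(f'  "{s}" -> "{t}" [{style}];')
        lines.append("}")
        return "\n".join(lines)


@dataclass(frozen=True)
class CycleRecord:
    """A simple directed cycle in rotation-canonical form.

    ``nodes`` starts at the lexicographically smallest node name; parity is
    invariant under rotation.  ``parity`` is ``"negative"`` for an odd number
    of inhibitory edges (the oscillation-capable case) and ``"positive"``
    otherwise.
    """

    nodes: tuple[str, ...]
    n_inhibitory: int
    parity: str = field(init=False)

    def __post_init__(self):
        if self.n_inhibitory < 0 or self.n_inhibitory > len(self.nodes):
            raise ArgumentError(
                "inhibitory edge count must lie in [0, cycle length]"
            )
        object.__setattr__(
            self, "parity", "negative" if self.n_inhibitory % 2 == 1 else "positive"
        )

    @property
    def length(self) -> int:
        return len(self.nodes)

    @property
    def is_self_loop(self) -> bool:
        return len(self.nodes) == 1

    @staticmethod
    def canonicalize(nodes: Sequence[str]) -> tuple[str, ...]:
        """Rotate so the lexicographically smallest node comes first."""
        i = min(range(len(nodes)), key=lambda k: nodes[k])
        return tuple(nodes[i:]) + tuple(nodes[:i])

    @classmethod
    def from_graph(cls, g: SignedDigraph, nodes: Sequence[str]) -> "CycleRecord":
        canon = cls.canonicalize(nodes)
        n_inh = sum(1 for n in canon if g.sign(n) == INHIBITORY)
        return cls(canon, n_inh)


def enumerate_simple_cycles(g: SignedDigraph) -> list[CycleRecord]:
    """All simple directed cycles of ``g`` (including length-1 self-loops),
    each exactly once in rotation-canonical form.

    Uses Johnson's algorithm via :func:`networkx.simple_cycles`.  Guarded to
    graphs of at most 20 nodes — the cycle count grows factorially.
    """
    if len(g) > _MAX_CYCLE_NODES:
        raise SizeError(
            f"cycle enumeration limited to {_MAX_CYCLE_NODES} nodes, got {len(g)}"
        )
    records = [CycleRecord.from_graph(g, cyc) for cyc in nx.simple_cycles(g.to_networkx())]
    records.sort(key=lambda r: (r.length, r.nodes))
    return records


def classify_cycle(c: CycleRecord) -> str:
    """Apply the odd inhibitory cycle rule to a single cycle.

    A cycle can support oscillations iff its inhibitory-edge count is odd
    (negative loop); an even count yields synchrony or winner-take-all
    dynamics instead.
    """
    return CAPABLE if c.n_inhibitory % 2 == 1 else NOT_CAPABLE


@dataclass
class OscillationReport:
    """Per-cycle classification plus the network-level verdict."""

    cycles: list[CycleRecord]
    verdicts: list[str]
    #: True iff the network contains at least one negative cycle (length >= 1).
    can_oscillate: bool
    #: negative self-loops, reported separately: the single-cycle theory
    #: requires length >= 2, so a self-inhibiting node is flagged, not pooled.
    negative_self_loops: list[CycleRecord]

    @property
    def negative_cycles(self) -> list[CycleRecord]:
        return [c for c, v in zip(self.cycles, self.verdicts) if v == CAPABLE]


def network_oscillation_potential(g: SignedDigraph) -> OscillationReport:
    """Classify every simple cycle of ``g`` and derive the network verdict.

    The network has oscillation potential iff it admits at least one negative
    loop (Thomas' necessary condition).  An acyclic network always reports
    ``False``.
    """
    cycles = enumerate_simple_cycles(g)
    verdicts = [classify_cycle(c) for c in cycles]
    negative = [c for c, v in zip(cycles, verdicts) if v == CAPABLE]
    return OscillationReport(
        cycles=cycles,
        verdicts=verdicts,
        can_oscillate=len(negative) > 0,
        negative_self_loops=[c for c in negative if c.is_self_loop],
    )


def enumerate_subnetworks(
    g: SignedDigraph, kmin: int, kmax: int
) -> Iterator[frozenset[str]]:
    """Yield every induced node subset of size ``kmin..kmax`` exactly once."""
    n = len(g)
    if not (1 <= kmin <= kmax <= n):
        raise ArgumentError(f"need 1 <= kmin <= kmax <= {n}, got ({kmin}, {kmax})")
    names = sorted(g.nodes)
    for k in range(kmin, kmax + 1):
        for combo in itertools.combinations(names, k):
            yield frozenset(combo)


def subnetwork_count(n: int, kmin: int, kmax: int) -> int:
    """Closed-form count of subsets: sum of binomial coefficients."""
    return sum(math.comb(n, k) for k in range(kmin, kmax + 1))


@dataclass
class CoverageReport:
    """How many induced subnetworks contain at least one whole oscillatory loop."""

    total: int
    covered: int
    loop_node_sets: list[frozenset[str]]
    #: loop count excluding each queried node name
    excluding: dict[str, int] = field(default_factory=dict)
    #: loop count touching any node of each queried named set
    including: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        if not (0 <= self.covered <= self.total):
            raise ArgumentError("covered count must lie in [0, total]")


def loop_coverage(
    g: SignedDigraph,
    loops: Sequence[Iterable[str]],
    kmin: int,
    kmax: int,
    exclude_queries: Sequence[str] = (),
    include_queries: dict[str, Iterable[str]] | None = None,
) -> CoverageReport:
    """Count subnetworks of size ``kmin..kmax`` that contain >= 1 full loop.

    A subset is *covered* when the node set of at least one loop is entirely
    inside it.  ``exclude_queries`` asks, per node name, how many loops avoid
    that node; ``include_queries`` maps a label to a node set and asks how
    many loops touch the set (used e.g. for "loops featuring GPe" with the
    set {Proto, Arky}).
    """
    loop_sets = []
    node_set = set(g.nodes)
    for loop in loops:
        ls = frozenset(loop)
        unknown = ls - node_set
        if unknown:
            raise ArgumentError(f"loop contains unknown nodes {sorted(unknown)}")
        loop_sets.append(ls)
    total = 0
    covered = 0
    for sub in enumerate_subnetworks(g, kmin, kmax):
        total += 1
        if any(ls <= sub for ls in loop_sets):
            covered += 1
    excluding = {
        q: sum(1 for ls in loop_sets if q not in ls) for q in exclude_queries
    }
    including = {}
    for label, names in (include_queries or {}).items():
        names = frozenset(names)
        unknown = names - node_set
        if unknown:
            raise ArgumentError(f"include query {label!r}: unknown nodes {sorted(unknown)}")
        including[label] = sum(1 for ls in loop_sets if ls & names)
    return CoverageReport(
        total=total,
        covered=covered,
        loop_node_sets=loop_sets,
        excluding=excluding,
        including=including,
    )
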