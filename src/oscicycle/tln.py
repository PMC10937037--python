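"""Threshold-linear network (TLN) dynamics and the single-cycle regime theory.

The TLN(W, b) model evolves nonnegative activities by

    dx_i/dt = -x_i + [ sum_j W_ij x_j + b_i ]_+ ,

with [.]_+ = max(., 0).  Two structural results organise this module:

* An acyclic interaction graph forces a unique, globally asymptotically
  stable fixed point, computable exactly by forward propagation in
  topological order (:func:`dag_fixed_point`).

* For a single directed cycle with nI inhibitory nodes, the long-term
  behaviour is decided by (a) segment-wise weight products against input
  ratios (weak vs strong coupling), (b) the parity of nI, and (c) for odd
  nI, the geometric-mean weight against the critical value 1/cos(pi/n)
  (:func:`classify_regime`).  Oscillations require odd nI *and* coupling
  above the critical value; even nI yields bistable winner-take-all
  behaviour under strong coupling.

Cycle convention: node ``i`` projects to node ``i+1`` (cyclically) with
weight magnitude ``w_i``, signed negatively when node ``i`` is inhibitory.
The *inhibited* nodes A = {a_1 < ... < a_nI} are those whose cyclic
predecessor is inhibitory; exactly these carry a positive constant input.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import numba
import networkx as nx

from .exceptions import ArgumentError, IntegrationError, SizeError, StructureError
from .signed_graph import INHIBITORY, SignedDigraph

# ---------------------------------------------------------------------------
# Regime labels
# ---------------------------------------------------------------------------
WEAK_GLOBAL_STABLE = "WEAK_GLOBAL_STABLE"
EVEN_BISTABLE = "EVEN_BISTABLE"
ODD_STABLE = "ODD_STABLE"
ODD_UNSTABLE_OSCILLATORY = "ODD_UNSTABLE_OSCILLATORY"
INDETERMINATE_GAP = "INDETERMINATE_GAP"
OUT_OF_SCOPE = "OUT_OF_SCOPE"

#: relative tolerance for strict inequalities in the regime conditions; a
#: quantity within this band of its bound is reported as INDETERMINATE_GAP
#: rather than guessed (the theory itself leaves a gap between conditions).
BOUNDARY_RTOL = 1e-9

_MAX_FIXED_POINT_NODES = 20


# ---------------------------------------------------------------------------
# Network containers
# ---------------------------------------------------------------------------
@dataclass
class TLNNetwork:
    """General TLN(W, b): ``W[i, j]`` is the strength from node j to node i."""

    W: np.ndarray
    b: np.ndarray

    def __post_init__(self):
        self.W = np.asarray(self.W, dtype=float)
        self.b = np.asarray(self.b, dtype=float)
        if self.W.ndim != 2 or self.W.shape[0] != self.W.shape[1]:
            raise ArgumentError("W must be square")
        if self.b.shape != (self.W.shape[0],):
            raise ArgumentError("b must have one entry per node")

    @property
    def n(self) -> int:
        return self.W.shape[0]

    @classmethod
    def from_signed_digraph(
        cls,
        g: SignedDigraph,
        b: dict[str, float] | None = None,
        default_weight: float = 1.0,
        order: Sequence[str] | None = None,
    ) -> tuple["TLNNetwork", list[str]]:
        """Build W from a signed graph: entries take the sign of the source
        node (column sign consistency), magnitudes from the graph's weights
        or ``default_weight``.  Returns the network and the node order used."""
        names = list(order) if order is not None else sorted(g.nodes)
        if set(names) != set(g.nodes):
            raise ArgumentError("order must be a permutation of the graph's nodes")
        idx = {n: i for i, n in enumerate(names)}
        W = np.zeros((len(names), len(names)))
        for s, t in g.edges:
            mag = g.weights.get((s, t), default_weight)
            sgn = -1.0 if g.sign(s) == INHIBITORY else 1.0
            W[idx[t], idx[s]] = sgn * mag
        bvec = np.zeros(len(names))
        for name, val in (b or {}).items():
            if name not in idx:
                raise ArgumentError(f"input given for unknown node {name!r}")
            bvec[idx[name]] = val
        return cls(W, bvec), names

    @classmethod
    def from_json(cls, path: str | Path) -> "TLNNetwork":
        doc = json.loads(Path(path).read_text())
        n = len(doc["b"])
        W = np.array(doc["W"], dtype=float).reshape(n, n)
        return cls(W, np.array(doc["b"], dtype=float))

    def to_dict(self) -> dict:
        return {"W": self.W.ravel().tolist(), "b": self.b.tolist()}


@dataclass
class CycleTLN:
    """A TLN whose interaction graph is one directed cycle.

    Parameters
    ----------
    signs
        Per-node E/I labels, length n; node i projects to node i+1 mod n.
    weights
        Positive magnitudes ``w_i`` on the edge i -> i+1.
    b
        External inputs; must be positive exactly on the inhibited nodes
        (nodes whose predecessor is inhibitory) and zero elsewhere.

    The single-cycle theory needs n >= 2, and n >= 3 when nI = 1; the EI
    pair (n=2, nI=1) is still constructible — it is covered separately (it
    always converges; its Jacobian eigenvalues are -1 ± i·sqrt(w1 w2)).
    """

    signs: tuple[str, ...]
    weights: np.ndarray
    b: np.ndarray

    def __post_init__(self):
        self.signs = tuple(self.signs)
        self.weights = np.asarray(self.weights, dtype=float)
        self.b = np.asarray(self.b, dtype=float)
        n = len(self.signs)
        if n < 2:
            raise ArgumentError("a cycle needs at least 2 nodes")
        if any(s not in ("E", "I") for s in self.signs):
            raise ArgumentError("signs must be 'E' or 'I'")
        if self.weights.shape != (n,) or self.b.shape != (n,):
            raise ArgumentError("weights and b must have one entry per node")
        if not np.all(self.weights > 0):
            raise ArgumentError("weight magnitudes must be strictly positive")
        inhibited = self.inhibited_nodes
        for i in range(n):
            if i in inhibited and not self.b[i] > 0:
                raise ArgumentError(
                    f"node {i} is inhibited (predecessor inhibitory) and needs b > 0"
                )
            if i not in inhibited and self.b[i] != 0:
                raise ArgumentError(
                    f"node {i} is excited (predecessor excitatory) and needs b = 0"
                )

    @property
    def n(self) -> int:
        return len(self.signs)

    @property
    def n_inhibitory(self) -> int:
        return sum(1 for s in self.signs if s == INHIBITORY)

    @property
    def inhibited_nodes(self) -> tuple[int, ...]:
        """A = sorted nodes whose cyclic predecessor is inhibitory."""
        n = len(self.signs)
        return tuple(i for i in range(n) if self.signs[(i - 1) % n] == INHIBITORY)

    def meets_theorem_preconditions(self) -> bool:
        """n >= 2 with nI >= 1, and n >= 3 when nI == 1."""
        nI = self.n_inhibitory
        return nI >= 1 and (self.n >= 3 or nI >= 2)

    def to_tln(self) -> TLNNetwork:
        n = self.n
        W = np.zeros((n, n))
        for i in range(n):
            sgn = -1.0 if self.signs[i] == INHIBITORY else 1.0
            W[(i + 1) % n, i] = sgn * self.weights[i]
        return TLNNetwork(W, self.b.copy())

    # -- segment bookkeeping ----------------------------------------------
    def segment_product(self, start: int, stop: int) -> float:
        """Product of w over the cyclic edge segment start..stop-1.

        ``stop == start`` means the full loop (all n edges), matching the
        single-inhibited-node case where the segment wraps the whole cycle.
        """
        steps = (stop - start) % self.n
        if steps == 0:
            steps = self.n
        return float(
            np.prod([self.weights[(start + t) % self.n] for t in range(steps)])
        )

    def segment_products(self) -> np.ndarray:
        """Per-inhibited-node products prod_{i=a_k}^{a_{k+1}-1} w_i."""
        A = self.inhibited_nodes
        if not A:
            raise ArgumentError("cycle has no inhibitory node")
        return np.array(
            [self.segment_product(A[k], A[(k + 1) % len(A)]) for k in range(len(A))]
        )

    def input_ratios(self) -> np.ndarray:
        """Per-inhibited-node ratios b_{a_{k+1}} / b_{a_k}."""
        A = self.inhibited_nodes
        return np.array(
            [self.b[A[(k + 1) % len(A)]] / self.b[A[k]] for k in range(len(A))]
        )

    def geometric_mean_weight(self) -> float:
        return float(np.exp(np.mean(np.log(self.weights))))

    def admissible_initial_state(self, rng: np.random.Generator) -> np.ndarray:
        """Uniform draw inside the per-segment box: for an excited run
        a_k..a_{k+1}-1, node j is bounded by b_{a_k} * prod_{i=a_k}^{j-1} w_i."""
        A = self.inhibited_nodes
        if not A:
            # no inhibited node: fall back to the unit box
            return rng.uniform(0.0, 1.0, size=self.n)
        x0 = np.zeros(self.n)
        for k in range(len(A)):
            start = A[k]
            stop = A[(k + 1) % len(A)]
            steps = (stop - start) % self.n
            if steps == 0:
                steps = self.n
            bound = self.b[start]
            for t in range(steps):
                j = (start + t) % self.n
                x0[j] = rng.uniform(0.0, bound)
                bound *= self.weights[j]
        return x0


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------
@dataclass
class Trajectory:
    """Uniformly sampled trajectory: ``x[k]`` is the state at ``t[k]``."""

    t: np.ndarray
    x: np.ndarray

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0])

    def to_csv(self, path: str | Path, names: Sequence[str] | None = None):
        names = names or [f"x{i+1}" for i in range(self.x.shape[1])]
        header = "time," + ",".join(names)
        np.savetxt(
            path,
            np.column_stack([self.t, self.x]),
            delimiter=",",
            header=header,
            comments="",
        )


@numba.njit(cache=True)
def _euler_tln(W, b, x0, n_steps, dt):  # pragma: no cover - numba kernel
    n = x0.shape[0]
    out = np.empty((n_steps + 1, n))
    x = x0.copy()
    out[0] = x
    for k in range(n_steps):
        drive = np.dot(W, x) + b
        for i in range(n):
            if drive[i] < 0.0:
                drive[i] = 0.0
        x = x + dt * (drive - x)
        for i in range(n):
            if not np.isfinite(x[i]):
                return out[: k + 1], k
        out[k + 1] = x
    return out, -1


def simulate_tln(
    net: TLNNetwork,
    x0: np.ndarray,
    T: float,
    dt: float = 0.01,
) -> Trajectory:
    """Forward-Euler integration of the TLN dynamics.

    States stay nonnegative up to solver tolerance (the drive is clipped at
    zero and the leak pulls towards it); the reported trajectory is clipped
    at exactly zero.
    """
    x0 = np.asarray(x0, dtype=float)
    if x0.shape != (net.n,):
        raise ArgumentError("x0 must have one entry per node")
    if np.any(x0 < 0):
        raise ArgumentError("initial state must be componentwise nonnegative")
    if dt <= 0:
        raise ArgumentError("dt must be positive")
    n_steps = int(round(T / dt))
    out, bad = _euler_tln(
        np.ascontiguousarray(net.W), net.b.astype(float), x0, n_steps, dt
    )
    if bad >= 0:
        raise IntegrationError(
            f"non-finite state at step {bad} (t = {bad * dt:g})", time_index=bad
        )
    t = np.arange(n_steps + 1) * dt
    return Trajectory(t=t, x=np.maximum(out, 0.0))


def classify_trajectory(
    traj: Trajectory,
    converged_tol: float = 1e-4,
    amplitude_floor: float = 1e-3,
    sustain_ratio: float = 0.9,
) -> str:
    """Label a trajectory: converged-fixed-point / sustained-oscillation /
    transient-oscillation / undetermined.

    Operates on quarters of the record: convergence is judged on the last
    quarter's excursion from the final state; a sustained oscillation keeps
    >= ``sustain_ratio`` of the previous quarter's peak-to-trough amplitude.
    """
    m = traj.x.shape[0]
    if m < 8:
        raise ArgumentError("trajectory too short to classify (need >= 8 samples)")
    q = m // 4
    last = traj.x[-q:]
    prev = traj.x[-2 * q : -q]
    early = traj.x[: 2 * q]
    if np.max(np.abs(last - traj.x[-1])) < converged_tol:
        return "converged-fixed-point"
    amp_last = float(np.max(last.max(axis=0) - last.min(axis=0)))
    amp_prev = float(np.max(prev.max(axis=0) - prev.min(axis=0)))
    amp_early = float(np.max(early.max(axis=0) - early.min(axis=0)))
    if amp_last > amplitude_floor and amp_last >= sustain_ratio * amp_prev:
        return "sustained-oscillation"
    if amp_early > amplitude_floor and amp_last < amplitude_floor:
        return "transient-oscillation"
    return "undetermined"


# ---------------------------------------------------------------------------
# Fixed points
# ---------------------------------------------------------------------------
def dag_fixed_point(net: TLNNetwork, g: SignedDigraph, order: Sequence[str] | None = None):
    """Exact fixed point of an acyclic TLN by forward propagation.

    The interaction graph must be a DAG (checked by topological sort; a
    cyclic graph raises :class:`StructureError` naming one cycle).  Nodes are
    processed in topological order: x*_i = [sum_j W_ij x*_j + b_i]_+.  The
    result is flagged as the unique globally asymptotically stable fixed
    point, which multi-start simulation can verify.
    """
    names = list(order) if order is not None else sorted(g.nodes)
    idx = {n: i for i, n in enumerate(names)}
    nxg = g.to_networkx()
    try:
        topo = list(nx.topological_sort(nxg))
    except nx.NetworkXUnfeasible:
        cyc = nx.find_cycle(nxg)
        path = " -> ".join(e[0] for e in cyc) + f" -> {cyc[-1][1]}"
        raise StructureError(f"graph is not acyclic: found cycle {path}")
    x = np.zeros(net.n)
    for name in topo:
        i = idx[name]
        x[i] = max(0.0, float(net.W[i] @ x + net.b[i]))
    return x


@dataclass
class FixedPoint:
    x: np.ndarray
    support: frozenset[int]
    stability: str  # globally-stable-claimed / linearly-stable / unstable / undetermined
    eigenvalues: np.ndarray


@dataclass
class FixedPointSet:
    points: list[FixedPoint]
    degenerate_supports: list[frozenset[int]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.points)

    def stable(self) -> list[FixedPoint]:
        return [
            p
            for p in self.points
            if p.stability in ("linearly-stable", "globally-stable-claimed")
        ]

    def supports(self) -> set[frozenset[int]]:
        return {p.support for p in self.points}


def enumerate_fixed_points(
    net: TLNNetwork, atol: float = 1e-10
) -> FixedPointSet:
    """Exhaustive support enumeration of TLN fixed points.

    For every candidate support sigma the on-support linear system
    (I - W_ss) x_s = b_s is solved; the solution is accepted when it is
    strictly positive on sigma and every off-support node sees net input
    <= 0.  Stability is labelled from the eigenvalues of the on-support
    Jacobian -I + W_ss (boundary modes at threshold are not analysed).
    """
    n = net.n
    if n > _MAX_FIXED_POINT_NODES:
        raise SizeError(
            f"support enumeration limited to {_MAX_FIXED_POINT_NODES} nodes"
        )
    points: list[FixedPoint] = []
    degenerate: list[frozenset[int]] = []
    I = np.eye(n)
    for r in range(n + 1):
        for sigma in itertools.combinations(range(n), r):
            s = list(sigma)
            x = np.zeros(n)
            if s:
                A = I[np.ix_(s, s)] - net.W[np.ix_(s, s)]
                try:
                    xs = np.linalg.solve(A, net.b[s])
                except np.linalg.LinAlgError:
                    degenerate.append(frozenset(sigma))
                    continue
                if np.any(xs <= atol):
                    continue
                x[s] = xs
            # off-support: threshold must be inactive
            drive = net.W @ x + net.b
            off = [i for i in range(n) if i not in sigma]
            if any(drive[i] > atol for i in off):
                continue
            if s:
                eig = np.linalg.eigvals(-I[np.ix_(s, s)] + net.W[np.ix_(s, s)])
            else:
                eig = np.array([], dtype=complex)
            if eig.size and np.max(eig.real) > atol:
                stability = "unstable"
            elif eig.size == 0 or np.max(eig.real) < -atol:
                stability = "linearly-stable"
            else:
                stability = "undetermined"
            points.append(
                FixedPoint(x=x, support=frozenset(sigma), stability=stability, eigenvalues=eig)
            )
    return FixedPointSet(points=points, degenerate_supports=degenerate)


# ---------------------------------------------------------------------------
# Regime classification (single cycle)
# ---------------------------------------------------------------------------
@dataclass
class RegimeClassification:
    """Outcome of the single-cycle structural conditions.

    Carries every quantity the decision rests on, so a caller can recompute
    the inequalities: per-segment weight products, the matching input
    ratios, the geometric-mean weight and the critical value 1/cos(pi/n).
    """

    label: str
    segment_products: np.ndarray | None = None
    input_ratios: np.ndarray | None = None
    geometric_mean: float | None = None
    threshold: float | None = None
    detail: str = ""


def _compare(lhs: float, rhs: float, rtol: float = BOUNDARY_RTOL) -> int:
    """-1 / 0 / +1 for lhs < rhs, within tolerance of rhs, lhs > rhs."""
    if abs(lhs - rhs) <= rtol * max(abs(lhs), abs(rhs)):
        return 0
    return -1 if lhs < rhs else 1


def classify_regime(c: CycleTLN) -> RegimeClassification:
    """Decide the long-term behaviour of a single-cycle TLN.

    * every segment product below its input ratio  -> WEAK_GLOBAL_STABLE
      (unique globally asymptotically stable fixed point, full support);
    * every segment product above its ratio with even nI -> EVEN_BISTABLE
      (two asymptotically stable fixed points on strict complementary
      supports);
    * every segment product above its ratio with odd nI -> geometric-mean
      weight below 1/cos(pi/n) gives ODD_STABLE (unique, stable, not
      globally), above gives ODD_UNSTABLE_OSCILLATORY (unique unstable fixed
      point; bounded dynamics must then cycle);
    * disagreeing segments, or any quantity at its bound within tolerance,
      -> INDETERMINATE_GAP (the theory leaves these cases open).

    Purely excitatory cycles (nI = 0) and the EI pair are OUT_OF_SCOPE: the
    former fails the odd rule outright, the latter always converges.
    """
    nI = c.n_inhibitory
    if nI == 0:
        return RegimeClassification(
            label=OUT_OF_SCOPE,
            detail="no inhibitory node: positive loop, not oscillation-capable",
        )
    if not c.meets_theorem_preconditions():
        return RegimeClassification(
            label=OUT_OF_SCOPE,
            detail="EI pair: always globally stable (eigenvalues -1 ± i sqrt(w1 w2))",
        )
    prods = c.segment_products()
    ratios = c.input_ratios()
    gm = c.geometric_mean_weight()
    thr = 1.0 / np.cos(np.pi / c.n)
    comps = [_compare(p, r) for p, r in zip(prods, ratios)]
    base = dict(
        segment_products=prods, input_ratios=ratios, geometric_mean=gm, threshold=thr
    )
    if any(cmp == 0 for cmp in comps):
        return RegimeClassification(
            label=INDETERMINATE_GAP, detail="segment product at its bound", **base
        )
    if all(cmp < 0 for cmp in comps):
        return RegimeClassification(label=WEAK_GLOBAL_STABLE, **base)
    if all(cmp > 0 for cmp in comps):
        if nI % 2 == 0:
            return RegimeClassification(label=EVEN_BISTABLE, **base)
        gcmp = _compare(gm, thr)
        if gcmp == 0:
            return RegimeClassification(
                label=INDETERMINATE_GAP,
                detail="geometric mean at the critical coupling",
                **base,
            )
        label = ODD_STABLE if gcmp < 0 else ODD_UNSTABLE_OSCILLATORY
        return RegimeClassification(label=label, **base)
    return RegimeClassification(
        label=INDETERMINATE_GAP, detail="segment conditions disagree", **base
    )


def cycle_eigenvalues(c: CycleTLN) -> np.ndarray:
    """Closed-form spectrum of the full-support Jacobian -I + W.

    With rho = (prod w_i)^{1/n}, the eigenvalues are -1 + rho * zeta over the
    n-th roots zeta of (-1)^{nI}.  For odd nI the leading real part is
    -1 + rho cos(pi/n), which crosses zero exactly at the critical coupling
    rho = 1/cos(pi/n).
    """
    n = c.n
    rho = c.geometric_mean_weight()
    k = np.arange(n)
    if c.n_inhibitory % 2 == 1:
        zeta = np.exp(1j * np.pi * (2 * k + 1) / n)
    else:
        zeta = np.exp(2j * np.pi * k / n)
    eig = -1.0 + rho * zeta
    return eig[np.argsort(-eig.real)]


@dataclass
class QuenchPrediction:
    verdict: str  # oscillation-destroyed / modified-threshold / unchanged
    node: int
    next_inhibited: int | None = None
    propagated_input: float | None = None
    downstream_input: float | None = None
    weak_condition_holds: bool | None = None
    detail: str = ""


def quench_condition(c: CycleTLN, node: int, b_extra: float) -> QuenchPrediction:
    """Effect of extra constant input to an *excited* node of the cycle.

    A positive extra input ``b_extra`` propagates down the excitatory run to
    the next inhibited node a*; if b_extra * prod_{j=node}^{a*-1} w_j exceeds
    b_{a*}, that node is silenced permanently — the cycle is broken and
    oscillation is prevented (verdict ``oscillation-destroyed``).

    A negative extra input does not break the cycle but shifts the
    weak-coupling condition for the affected segment: the drive reaching a*
    becomes b_{a_k} prod w - |b_extra| prod_{j=node}^{a*-1} w_j, and the
    verdict ``modified-threshold`` reports whether this modified quantity
    stays below b_{a*} (the modified global-stability condition).

    Zero extra input leaves the classification unchanged.
    """
    A = c.inhibited_nodes
    if not (0 <= node < c.n):
        raise ArgumentError(f"node index {node} out of range")
    if node in A:
        raise ArgumentError(
            f"node {node} is inhibited, not excited; quenching applies to excited nodes"
        )
    if not A:
        raise ArgumentError("cycle has no inhibited node")
    if b_extra == 0:
        return QuenchPrediction(verdict="unchanged", node=node)
    # next inhibited node strictly after `node` in cyclic order
    a_next = min(A, key=lambda a: (a - node) % c.n)
    # product of weights along node .. a_next-1
    prod = c.segment_product(node, a_next)
    if b_extra > 0:
        propagated = b_extra * prod
        destroyed = propagated > c.b[a_next]
        return QuenchPrediction(
            verdict="oscillation-destroyed" if destroyed else "unchanged",
            node=node,
            next_inhibited=a_next,
            propagated_input=propagated,
            downstream_input=float(c.b[a_next]),
            detail="extra drive exceeds the downstream input"
            if destroyed
            else "extra drive stays below the downstream input",
        )
    # negative input: evaluate the modified weak-coupling inequality on the
    # segment containing `node`, which starts at the inhibited node
    # immediately preceding it
    a_prev = min(A, key=lambda a: (node - a) % c.n)
    seg_prod = c.segment_product(a_prev, a_next)
    lhs = c.b[a_prev] * seg_prod - abs(b_extra) * prod
    return QuenchPrediction(
        verdict="modified-threshold",
        node=node,
        next_inhibited=a_next,
        propagated_input=lhs,
        downstream_input=float(c.b[a_next]),
        weak_condition_holds=bool(lhs < c.b[a_next]),
        detail="modified weak-coupling condition "
        + ("holds (globally stable)" if lhs < c.b[a_next] else "violated"),
    )
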