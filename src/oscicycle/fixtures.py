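"""Built-in fixtures: motif graphs, the cortico-basal-ganglia (CBG) graph,
Wilson-Cowan parameter sets, spiking motif configurations, and seeded
random-network generators used by the property tests.

The CBG core graph contains the eight populations retained in the analysis
(D1-SPNs are excluded for their very low Parkinsonian firing rate; cortex is
one node) and exactly the edges required by the six oscillation-capable
loops plus the Proto self-inhibition.  An *extended* variant adds a few
further anatomically motivated projections; it is a reconstruction, not a
printed connectome, and no reported count depends on it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import ArgumentError
from .signed_graph import SignedDigraph, loop_coverage
from .spiking import NeuronModelSpec, PopulationSpec, SpikingNetwork, SynapseSpec
from .tln import CycleTLN
from .wilson_cowan import WCNetwork

# ---------------------------------------------------------------------------
# Motif graphs
# ---------------------------------------------------------------------------
def motif_graph(name: str) -> SignedDigraph:
    """Small named motifs: EI, EEI, EII, III rings (cycles of 2-3 nodes)."""
    name = name.upper()
    rings = {
        "EI": ["E", "I"],
        "EEI": ["E", "E", "I"],
        "EII": ["E", "I", "I"],
        "III": ["I", "I", "I"],
        "EEE": ["E", "E", "E"],
        "II": ["I", "I"],
    }
    if name not in rings:
        raise ArgumentError(f"unknown motif {name!r}; choose from {sorted(rings)}")
    signs = rings[name]
    labels = []
    counts: dict[str, int] = {}
    for s in signs:
        counts[s] = counts.get(s, 0) + 1
        labels.append(f"{s}{counts[s]}")
    nodes = list(zip(labels, signs))
    n = len(labels)
    edges = [(labels[i], labels[(i + 1) % n]) for i in range(n)]
    return SignedDigraph(nodes, edges)


# ---------------------------------------------------------------------------
# CBG network
# ---------------------------------------------------------------------------
CBG_NODES = [
    ("D2", "I"), ("FSN", "I"), ("Proto", "I"), ("Arky", "I"),
    ("GPi", "I"), ("STN", "E"), ("Th", "E"), ("Cortex", "E"),
]

#: the six oscillation-capable loops of the CBG graph (node sequences in
#: cycle order); each has an odd number of inhibitory projections.
CBG_LOOPS: dict[str, tuple[str, ...]] = {
    "Proto-STN": ("Proto", "STN"),
    "STN-GPi-Th-Cortex": ("STN", "GPi", "Th", "Cortex"),
    "STN-Arky-D2-Proto": ("STN", "Arky", "D2", "Proto"),
    "Proto-Arky-D2": ("Proto", "Arky", "D2"),
    "Proto-FSN-D2": ("Proto", "FSN", "D2"),
    "Proto-GPi-Th-Cortex-D2": ("Proto", "GPi", "Th", "Cortex", "D2"),
}

_CBG_CORE_EDGES = [
    # Proto-STN reciprocal loop
    ("Proto", "STN"), ("STN", "Proto"),
    # STN-GPi-Th-Cortex loop (hyperdirect return path)
    ("STN", "GPi"), ("GPi", "Th"), ("Th", "Cortex"), ("Cortex", "STN"),
    # STN-Arky-D2-Proto loop
    ("STN", "Arky"), ("Arky", "D2"), ("D2", "Proto"),
    # Proto-Arky-D2 loop
    ("Proto", "Arky"),
    # Proto-FSN-D2 loop
    ("Proto", "FSN"), ("FSN", "D2"),
    # Proto-GPi-Th-Cortex-D2 loop
    ("Proto", "GPi"), ("Cortex", "D2"),
    # Proto self-inhibition (pallidal collaterals)
    ("Proto", "Proto"),
]

#: additional anatomically plausible projections; reconstructed, not printed
_CBG_EXTENDED_EXTRA = [
    ("Cortex", "FSN"),
    ("Arky", "FSN"),
    ("Proto", "D2"),
]


def cbg_graph(extended: bool = False) -> SignedDigraph:
    """The CBG signed graph (core: exactly the six loops' edges + Proto
    self-loop; extended: plus reconstructed projections)."""
    edges = list(_CBG_CORE_EDGES)
    if extended:
        edges += _CBG_EXTENDED_EXTRA
    return SignedDigraph(CBG_NODES, edges)


@dataclass
class CountsReport:
    """CBG motif-coverage summary computed from the core fixture."""

    total_subnetworks: int
    covered_subnetworks: int
    loops_without_stn: int
    loops_with_gpe: int
    loop_names: list[str] = field(default_factory=list)


def reproduce_counts() -> CountsReport:
    """Recompute the CBG combinatorics from the built-in fixture.

    Counts all induced subnetworks of 2-7 of the 8 nodes, those containing
    at least one of the six oscillation-capable loops, the loops avoiding
    STN, and the loops featuring GPe (touching {Proto, Arky}).
    """
    g = cbg_graph()
    report = loop_coverage(
        g,
        list(CBG_LOOPS.values()),
        kmin=2,
        kmax=7,
        exclude_queries=["STN"],
        include_queries={"GPe": ["Proto", "Arky"]},
    )
    return CountsReport(
        total_subnetworks=report.total,
        covered_subnetworks=report.covered,
        loops_without_stn=report.excluding["STN"],
        loops_with_gpe=report.including["GPe"],
        loop_names=list(CBG_LOOPS),
    )


# ---------------------------------------------------------------------------
# Wilson-Cowan parameter sets
# ---------------------------------------------------------------------------
def wc_fixture(name: str) -> WCNetwork:
    """Named Wilson-Cowan networks.

    ``III``: inhibitory 3-ring, cross weight -15, input 6, zero delay —
    sustained oscillator.  ``EII``: one excitatory node in the ring (E1 ->
    I1 at +15) — transient oscillations only.  ``EI``: reciprocal
    excitatory-inhibitory pair with a 2 ms delay (analogous defaults; the
    printed tables cover III/EII and the basal-ganglia set).  ``BG4``: the
    four-population basal-ganglia subnetwork D2/Arky/Proto/STN with 2 ms
    delays, Proto self-inhibition -8 and STN self-excitation +5 as printed
    (see :func:`bg4_fixture` for the self-loop switch and the Proto-input
    variants).
    """
    name = name.upper()
    if name == "III":
        names = ("I1", "I2", "I3")
        W = np.array([
            [0.0, 0.0, -15.0],
            [-15.0, 0.0, 0.0],
            [0.0, -15.0, 0.0],
        ])
        return WCNetwork(names, W, np.zeros((3, 3)), np.array([6.0, 6.0, 6.0]))
    if name == "EII":
        names = ("E1", "I1", "I2")
        W = np.array([
            [0.0, 0.0, -15.0],
            [15.0, 0.0, 0.0],
            [0.0, -15.0, 0.0],
        ])
        return WCNetwork(names, W, np.zeros((3, 3)), np.array([6.0, 6.0, 6.0]))
    if name == "EI":
        names = ("E1", "I1")
        W = np.array([
            [0.0, -15.0],
            [15.0, 0.0],
        ])
        delays = np.full((2, 2), 2.0)
        return WCNetwork(names, W, delays, np.array([6.0, 6.0]))
    if name == "BG4":
        return bg4_fixture()
    raise ArgumentError(f"unknown Wilson-Cowan fixture {name!r}")


def bg4_fixture(
    proto_input: float = 1.0, stn_self: bool = True
) -> WCNetwork:
    """Four-population basal-ganglia Wilson-Cowan network (D2, Arky, Proto,
    STN).  ``proto_input`` is 1 in the intact and D2->Proto-lesion settings
    and raised to 4 in the STN-output-lesion setting to compensate the lost
    excitatory drive; ``stn_self=False`` zeroes the printed STN
    self-excitation of +5."""
    names = ("D2", "Arky", "Proto", "STN")
    W = np.array([
        #  D2    Arky   Proto   STN
        [0.0, -15.0, 0.0, 0.0],      # D2   <- Arky
        [0.0, 0.0, -15.0, 15.0],     # Arky <- Proto, STN
        [-15.0, 0.0, -8.0, 15.0],    # Proto<- D2, self, STN
        [0.0, 0.0, -15.0, 5.0],      # STN  <- Proto, self
    ])
    if not stn_self:
        W[3, 3] = 0.0
    delays = np.where(W != 0, 2.0, 0.0)
    I_ext = np.array([4.0, 3.0, proto_input, 4.0])
    return WCNetwork(names, W, delays, I_ext)


# ---------------------------------------------------------------------------
# Spiking fixtures
# ---------------------------------------------------------------------------
def _lif_specs() -> dict[str, NeuronModelSpec]:
    return {
        "D2": NeuronModelSpec("LIF", C_m=100.0, g_L=12.5, V_reset=-80.0, V_th=-50.0),
        "FSN": NeuronModelSpec("LIF", C_m=80.0, g_L=10.0, V_reset=-70.0, V_th=-54.0),
        "STN": NeuronModelSpec("LIF", C_m=100.0, g_L=10.0, V_reset=-70.0, V_th=-55.0),
    }


def _adex_spec(fast: bool = True) -> NeuronModelSpec:
    """GPe Proto/Arky AdEx: tonically active, adapting.

    The ``fast`` variant (tau_m = 10 ms, weak spike-triggered adaptation)
    is used in the striato-pallidal loop fixtures, whose rhythm period is
    set by the three-stage loop lag; the slow variant (tau_m = 20 ms,
    strong adaptation) is used where the Proto-STN loop is the oscillator.
    """
    if fast:
        return NeuronModelSpec(
            "AdEx", C_m=60.0, g_L=6.0, V_reset=-60.0, V_th=-40.0,
            Delta_T=2.0, V_T=-54.0, a=2.5, b=10.0, tau_w=20.0,
        )
    return NeuronModelSpec(
        "AdEx", C_m=60.0, g_L=3.0, V_reset=-60.0, V_th=-40.0,
        Delta_T=2.0, V_T=-54.0, a=2.5, b=60.0, tau_w=20.0,
    )


def spiking_motif(
    name: str,
    n_per_pop: int = 300,
) -> SpikingNetwork:
    """Spiking motif fixtures.

    ``proto-fsn-d2`` and ``proto-arky-d2``: three-population loops with
    three inhibitory projections, driven to a Parkinson-like state by
    strong cortical Poisson drive to the striatal D2 population; both
    oscillate in the beta band.  ``stn-experiment``: the four-population
    reduced network (D2, Proto, Arky, STN) used for the STN-inhibition
    sweeps; see :func:`stn_experiment_network` for the mode presets.
    """
    lif = _lif_specs()
    adex = _adex_spec(fast=True)
    name = name.lower()

    def pop(pname, model, sign, **kw):
        return PopulationSpec(
            name=pname, n=n_per_pop, sign=sign, model=model, tau_inh=3.0, **kw
        )

    if name == "proto-fsn-d2":
        pops = [
            pop("D2", lif["D2"], "I", ext_rate=14000.0, ext_J=0.35),
            pop("FSN", lif["FSN"], "I", ext_rate=3000.0, ext_J=0.4),
            pop("Proto", adex, "I", I_e=60.0, ext_rate=2000.0, ext_J=0.3),
        ]
        conns = {
            ("Proto", "FSN"): SynapseSpec(J_syn=0.6, tau_syn=3.0, E_rev=-80.0, delay=1.0, p=0.2),
            ("FSN", "D2"): SynapseSpec(J_syn=1.0, tau_syn=3.0, E_rev=-80.0, delay=4.0, p=0.2),
            ("D2", "Proto"): SynapseSpec(J_syn=0.6, tau_syn=3.0, E_rev=-80.0, delay=4.0, p=0.2),
        }
        return SpikingNetwork(pops, conns)
    if name == "proto-arky-d2":
        pops = [
            pop("D2", lif["D2"], "I", ext_rate=14000.0, ext_J=0.35),
            pop("Arky", adex, "I", I_e=60.0, ext_rate=2000.0, ext_J=0.3),
            pop("Proto", adex, "I", I_e=60.0, ext_rate=2000.0, ext_J=0.3),
        ]
        conns = {
            ("Proto", "Arky"): SynapseSpec(J_syn=0.6, tau_syn=3.0, E_rev=-80.0, delay=1.0, p=0.2),
            ("Arky", "D2"): SynapseSpec(J_syn=1.0, tau_syn=3.0, E_rev=-80.0, delay=4.0, p=0.2),
            ("D2", "Proto"): SynapseSpec(J_syn=0.6, tau_syn=3.0, E_rev=-80.0, delay=4.0, p=0.2),
        }
        return SpikingNetwork(pops, conns)
    if name == "stn-experiment":
        return stn_experiment_network("proto-d2-arky", n_per_pop=n_per_pop)
    raise ArgumentError(f"unknown spiking motif {name!r}")


def stn_experiment_network(
    mode: str, n_per_pop: int = 300
) -> SpikingNetwork:
    """Reduced BG network (D2, Proto, Arky, STN) in one of two drive modes.

    ``proto-d2-arky``: strong cortical Poisson drive to D2 and a negligible
    STN bias (1 pA) make the Proto-Arky-D2 loop the beta oscillator; the
    Proto-STN coupling is present but subordinate.  ``proto-stn``: weak D2
    drive and a stronger STN bias (30 pA) hand the rhythm to the reciprocal
    Proto-STN loop, with slower pallidal membranes / GABA kinetics placing
    it in the beta band.  In both modes the STN-inhibition sweep only
    lowers the STN bias current (toward -99 pA and -50 pA respectively).
    """
    mode = mode.lower()
    if mode not in ("proto-d2-arky", "proto-stn"):
        raise ArgumentError(f"unknown mode {mode!r}")
    lif = _lif_specs()
    if mode == "proto-d2-arky":
        adex = _adex_spec(fast=True)
        tau_i = 3.0
        d2_rate, stn_bias, stn_rate = 14000.0, 1.0, 2500.0
        gpe_Ie = 60.0
        d_loop, d_ps = 4.0, 3.0
        J_stn_proto = 0.3
    else:
        adex = _adex_spec(fast=False)
        tau_i = 8.0
        d2_rate, stn_bias, stn_rate = 2000.0, 30.0, 3000.0
        gpe_Ie = 30.0
        d_loop, d_ps = 7.0, 7.0
        J_stn_proto = 1.2
    pops = [
        PopulationSpec("D2", n_per_pop, "I", lif["D2"], ext_rate=d2_rate, ext_J=0.35, tau_inh=tau_i),
        PopulationSpec("Arky", n_per_pop, "I", adex, I_e=gpe_Ie, ext_rate=2000.0, ext_J=0.3, tau_inh=tau_i),
        PopulationSpec("Proto", n_per_pop, "I", adex, I_e=gpe_Ie, ext_rate=2000.0, ext_J=0.3, tau_inh=tau_i),
        PopulationSpec("STN", n_per_pop, "E", lif["STN"], I_e=stn_bias, ext_rate=stn_rate, ext_J=0.5, tau_inh=tau_i),
    ]
    conns = {
        ("Proto", "Arky"): SynapseSpec(J_syn=0.6, tau_syn=tau_i, E_rev=-80.0, delay=1.0, p=0.2),
        ("Arky", "D2"): SynapseSpec(J_syn=1.0, tau_syn=tau_i, E_rev=-80.0, delay=d_loop, p=0.2),
        ("D2", "Proto"): SynapseSpec(J_syn=0.6, tau_syn=tau_i, E_rev=-80.0, delay=d_loop, p=0.2),
        ("Proto", "STN"): SynapseSpec(J_syn=0.1, tau_syn=tau_i, E_rev=-80.0, delay=d_ps, p=0.2),
        ("STN", "Proto"): SynapseSpec(J_syn=J_stn_proto, tau_syn=1.0, E_rev=0.0, delay=d_ps, p=0.2),
    }
    return SpikingNetwork(pops, conns)


# ---------------------------------------------------------------------------
# Random generators for property tests
# ---------------------------------------------------------------------------
def generate_random_cycle_tln(
    n: int,
    nI: int,
    weight_range: tuple[float, float] = (0.3, 3.0),
    input_range: tuple[float, float] = (0.5, 2.0),
    seed: int | np.random.Generator = 0,
) -> CycleTLN:
    """Seeded random single-cycle TLN: ``nI`` inhibitory nodes placed
    uniformly at random, weights log-uniform in ``weight_range``, inputs
    uniform in ``input_range`` on the inhibited nodes."""
    if not (1 <= nI <= n) or n < 2 or (nI == 1 and n < 3):
        raise ArgumentError(
            f"infeasible cycle ({n=}, {nI=}): need 1 <= nI <= n, n >= 2, "
            "and n >= 3 when nI = 1"
        )
    lo_w, hi_w = weight_range
    lo_b, hi_b = input_range
    if not (0 < lo_w <= hi_w) or not (0 < lo_b <= hi_b):
        raise ArgumentError("weight and input ranges must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    inhibitory = rng.choice(n, size=nI, replace=False)
    signs = tuple("I" if i in set(inhibitory.tolist()) else "E" for i in range(n))
    weights = np.exp(rng.uniform(np.log(lo_w), np.log(hi_w), size=n))
    b = np.zeros(n)
    for i in range(n):
        if signs[(i - 1) % n] == "I":
            b[i] = rng.uniform(lo_b, hi_b)
    return CycleTLN(signs=signs, weights=weights, b=b)


def generate_random_signed_graph(
    n: int,
    edge_prob: float = 0.3,
    inhibitory_prob: float = 0.5,
    acyclic: bool = False,
    self_loops: bool = False,
    seed: int | np.random.Generator = 0,
) -> SignedDigraph:
    """Seeded Erdos-Renyi-style signed digraph for property tests; with
    ``acyclic=True`` edges only run from lower to higher node index."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    names = [f"n{i}" for i in range(n)]
    nodes = [
        (name, "I" if rng.random() < inhibitory_prob else "E") for name in names
    ]
    edges = []
    for i in range(n):
        for j in range(n):
            if i == j and not self_loops:
                continue
            if acyclic and i >= j:
                continue
            if rng.random() < edge_prob:
                edges.append((names[i], names[j]))
    return SignedDigraph(nodes, edges)
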