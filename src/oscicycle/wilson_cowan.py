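"""Delayed Wilson-Cowan rate model of interacting neural populations.

Each population's rate obeys

    tau dr_i/dt = -r_i + F( sum_j w_ij r_j(t - d_ij) + I_i^ext ),

with the shifted sigmoid F(x) = 1/(1+exp(-a(x-theta))) - 1/(1+exp(a*theta)),
so that F(0) = 0 and rates are confined to F's range (a fully inhibited
population can sit marginally below zero, by at most 1/(1+exp(a*theta)),
about 0.011 at the defaults).  Time is in milliseconds
(tau = 20 ms by default, Euler step 0.01 ms) and reported frequencies in Hz.

The module provides the simulator with per-edge transmission delays, the
homogeneous parameter sweeps (delay / weight / input / self-connection) used
to map how network properties shape the oscillation frequency, and 'lesion'
edits (removing projections, overriding inputs) used to dissect which loop
of a basal-ganglia subnetwork generates the rhythm.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import numba

from .exceptions import ArgumentError, IntegrationError
from .metrics import downsample, oscillation_class
from .tln import Trajectory


@dataclass
class WCNetwork:
    """Wilson-Cowan population network.

    ``W[i, j]`` is the signed weight from population j to i; ``delays[i, j]``
    the transmission delay on that projection in ms; ``I_ext`` the constant
    external drive per population.  Defaults tau=20 ms, theta=1.5, a=3.
    """

    names: tuple[str, ...]
    W: np.ndarray
    delays: np.ndarray
    I_ext: np.ndarray
    tau: float = 20.0
    a: float = 3.0
    theta: float = 1.5

    def __post_init__(self):
        self.names = tuple(self.names)
        n = len(self.names)
        self.W = np.asarray(self.W, dtype=float)
        self.delays = np.asarray(self.delays, dtype=float)
        self.I_ext = np.asarray(self.I_ext, dtype=float)
        if self.W.shape != (n, n) or self.delays.shape != (n, n):
            raise ArgumentError("W and delays must be n x n")
        if self.I_ext.shape != (n,):
            raise ArgumentError("I_ext must have one entry per population")
        if np.any(self.delays < 0):
            raise ArgumentError("delays must be nonnegative")
        if self.tau <= 0 or self.a <= 0:
            raise ArgumentError("tau and a must be positive")

    @property
    def n(self) -> int:
        return len(self.names)

    def index(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise ArgumentError(f"unknown population {name!r}")

    @classmethod
    def from_json(cls, path: str | Path) -> "WCNetwork":
        doc = json.loads(Path(path).read_text())
        return cls.from_dict(doc)

    @classmethod
    def from_dict(cls, doc: dict) -> "WCNetwork":
        names = tuple(doc["names"])
        n = len(names)
        return cls(
            names=names,
            W=np.array(doc["W"], dtype=float).reshape(n, n),
            delays=np.array(doc["delays"], dtype=float).reshape(n, n),
            I_ext=np.array(doc["I_ext"], dtype=float),
            tau=float(doc.get("tau", 20.0)),
            a=float(doc.get("a", 3.0)),
            theta=float(doc.get("theta", 1.5)),
        )

    def to_dict(self) -> dict:
        return {
            "names": list(self.names),
            "W": self.W.ravel().tolist(),
            "delays": self.delays.ravel().tolist(),
            "I_ext": self.I_ext.tolist(),
            "tau": self.tau,
            "a": self.a,
            "theta": self.theta,
        }


def wc_activation(x, a: float = 3.0, theta: float = 1.5):
    """Shifted sigmoid F(x) = 1/(1+e^{-a(x-theta)}) - 1/(1+e^{a theta}).

    F(0) = 0, F is strictly increasing, bounded above by 1 - 1/(1+e^{a theta});
    a/4 is the slope at the inflection point theta.
    """
    x = np.asarray(x, dtype=float)
    out = 1.0 / (1.0 + np.exp(-a * (x - theta))) - 1.0 / (1.0 + np.exp(a * theta))
    return float(out) if out.ndim == 0 else out


@numba.njit(cache=True)
def _euler_wc(W, dsteps, I_ext, tau, a, theta, r0, n_steps, dt, record_every):
    # pragma: no cover - numba kernel
    n = W.shape[0]
    offset = 1.0 / (1.0 + np.exp(a * theta))
    hist_len = int(np.max(dsteps)) + 1
    hist = np.empty((hist_len, n))
    for h in range(hist_len):
        hist[h] = r0  # history before t=0 held constant at r0
    n_rec = n_steps // record_every + 1
    out = np.empty((n_rec, n))
    r = r0.copy()
    out[0] = r
    ptr = 0
    rec = 1
    for k in range(1, n_steps + 1):
        new = np.empty(n)
        for i in range(n):
            s = I_ext[i]
            for j in range(n):
                wij = W[i, j]
                if wij != 0.0:
                    h = (ptr - dsteps[i, j]) % hist_len
                    s += wij * hist[h, j]
            F = 1.0 / (1.0 + np.exp(-a * (s - theta))) - offset
            new[i] = r[i] + dt / tau * (-r[i] + F)
            if not np.isfinite(new[i]):
                return out[:rec], k
        r = new
        ptr = (ptr + 1) % hist_len
        hist[ptr] = r
        if k % record_every == 0:
            out[rec] = r
            rec += 1
    return out[:rec], -1


def simulate_wc(
    net: WCNetwork,
    r0: np.ndarray | float = 0.1,
    T: float = 5000.0,
    dt: float = 0.01,
    record_every: int | None = None,
) -> Trajectory:
    """Euler integration with per-edge delay buffers.

    ``r0`` may be a scalar or a vector in [0, 1).  A scalar is expanded with
    a small deterministic per-population stagger (1% steps) — homogeneous
    motifs have an invariant symmetric manifold on which the oscillatory
    instability cannot grow, so an exactly uniform start would mask it.
    Delays are rounded to integer multiples of ``dt``; history before t = 0
    is held constant at ``r0``.  By default the trajectory is recorded at
    every step; ``record_every`` thins the record (the integration step is
    unchanged).
    """
    if dt <= 0:
        raise ArgumentError("dt must be positive")
    if np.isscalar(r0):
        r0 = float(r0) * (1.0 + 0.01 * np.arange(net.n))
    r0 = np.asarray(r0, dtype=float)
    if r0.shape != (net.n,):
        raise ArgumentError("r0 must have one entry per population")
    if np.any(r0 < 0) or np.any(r0 >= 1):
        raise ArgumentError("r0 must lie in [0, 1)")
    if record_every is None:
        record_every = 1
    n_steps = int(round(T / dt))
    dsteps = np.round(net.delays / dt).astype(np.int64)
    out, bad = _euler_wc(
        np.ascontiguousarray(net.W),
        dsteps,
        net.I_ext.astype(float),
        float(net.tau),
        float(net.a),
        float(net.theta),
        r0,
        n_steps,
        float(dt),
        int(record_every),
    )
    if bad >= 0:
        raise IntegrationError(
            f"non-finite rate at step {bad} (t = {bad * dt:g} ms)", time_index=bad
        )
    t = np.arange(out.shape[0]) * (dt * record_every)
    return Trajectory(t=t, x=out)


# ---------------------------------------------------------------------------
# Analysis helpers
# ---------------------------------------------------------------------------
def dominant_frequency(
    traj: Trajectory,
    transient_fraction: float = 0.5,
    fs_analysis: float = 1000.0,
) -> tuple[float, str]:
    """Dominant oscillation frequency (Hz) of a rate trajectory.

    The first ``transient_fraction`` of the record is discarded, the summed
    population rate is downsampled to ``fs_analysis`` and classified; the
    frequency is 0 when no sustained oscillation remains.
    """
    m = traj.x.shape[0]
    start = int(m * transient_fraction)
    sig = traj.x[start:].sum(axis=1)
    fs_native = 1000.0 / traj.dt  # dt in ms
    sig = downsample(sig, fs_native, fs_analysis)
    label, freq = oscillation_class(sig, fs_analysis)
    return (freq if label == "sustained" else 0.0), label


def classify_network(
    net: WCNetwork, T: float = 5000.0, dt: float = 0.01, r0: float | np.ndarray = 0.1
) -> tuple[str, float]:
    """Oscillation class of the network over the *full* record (no transient
    discard, so decaying rhythms are reported as transient) together with
    the sustained dominant frequency in Hz (0 unless sustained)."""
    traj = simulate_wc(net, r0=r0, T=T, dt=dt, record_every=10)
    sig = traj.x.sum(axis=1)
    sig = downsample(sig, 1000.0 / traj.dt, 1000.0)
    label, freq = oscillation_class(sig, 1000.0)
    return label, (freq if label == "sustained" else 0.0)


@dataclass
class SweepResult:
    parameter: str
    grid: np.ndarray
    frequencies: np.ndarray  # Hz; 0 where no sustained oscillation
    classes: list[str] = field(default_factory=list)

    def __post_init__(self):
        if len(self.grid) != len(self.frequencies):
            raise ArgumentError("grid and results must have the same length")


_SWEEP_PARAMS = ("delay", "weight", "input", "self-connection")


def _apply_sweep_value(net: WCNetwork, parameter: str, value: float) -> WCNetwork:
    """Set a parameter homogeneously across all relevant entries."""
    W = net.W.copy()
    delays = net.delays.copy()
    I_ext = net.I_ext.copy()
    off = ~np.eye(net.n, dtype=bool)
    cross = off & (W != 0)
    if parameter == "delay":
        delays[W != 0] = value
    elif parameter == "weight":
        # homogeneous magnitude on all cross connections, signs preserved
        W[cross] = np.sign(W[cross]) * abs(value)
    elif parameter == "input":
        I_ext[:] = value
    elif parameter == "self-connection":
        np.fill_diagonal(W, value)
    else:
        raise ArgumentError(
            f"unknown sweep parameter {parameter!r}; choose from {_SWEEP_PARAMS}"
        )
    return replace(net, W=W, delays=delays, I_ext=I_ext)


def frequency_sweep(
    net: WCNetwork,
    parameter: str,
    grid: Sequence[float],
    T: float = 5000.0,
    dt: float = 0.01,
    r0: float = 0.1,
    record_every: int = 10,
) -> SweepResult:
    """Sweep one parameter homogeneously and measure the dominant frequency.

    In each simulation all synapses (or inputs / self-connections) share the
    swept value.  Returns 0 Hz where the network shows no sustained
    oscillation after the transient is discarded.
    """
    grid = np.asarray(list(grid), dtype=float)
    if grid.size == 0:
        raise ArgumentError("sweep grid is empty")
    freqs = np.empty(len(grid))
    classes = []
    for k, value in enumerate(grid):
        swept = _apply_sweep_value(net, parameter, float(value))
        traj = simulate_wc(swept, r0=r0, T=T, dt=dt, record_every=record_every)
        f, label = dominant_frequency(traj)
        freqs[k] = f
        classes.append(label)
    return SweepResult(parameter=parameter, grid=grid, frequencies=freqs, classes=classes)


def lesion(
    net: WCNetwork,
    edges_to_remove: Sequence[tuple[str, str]] = (),
    input_overrides: dict[str, float] | None = None,
) -> WCNetwork:
    """Copy of the network with projections removed and/or inputs overridden.

    ``edges_to_remove`` lists (source, target) population names whose weight
    is set to zero (the projection must exist); ``input_overrides`` maps a
    population name to its new external input.  The original is unchanged.
    """
    W = net.W.copy()
    I_ext = net.I_ext.copy()
    for src, tgt in edges_to_remove:
        i, j = net.index(tgt), net.index(src)
        if W[i, j] == 0:
            raise ArgumentError(f"no projection {src!r} -> {tgt!r} to remove")
        W[i, j] = 0.0
    for name, value in (input_overrides or {}).items():
        I_ext[net.index(name)] = float(value)
    return replace(net, W=W, I_ext=I_ext)


def input_plane_sweep(
    net: WCNetwork,
    pop_x: str,
    pop_y: str,
    grid_x: Sequence[float],
    grid_y: Sequence[float],
    T: float = 3000.0,
    dt: float = 0.01,
    record_every: int = 10,
) -> np.ndarray:
    """2-D sweep of external inputs to two populations.

    Returns an array of dominant frequencies indexed [iy, ix] (0 where no
    sustained oscillation); used to map competition between two oscillatory
    loops as a function of their drives.
    """
    ix, iy = net.index(pop_x), net.index(pop_y)
    out = np.zeros((len(grid_y), len(grid_x)))
    for a_, gy in enumerate(grid_y):
        for b_, gx in enumerate(grid_x):
            I = net.I_ext.copy()
            I[ix], I[iy] = gx, gy
            traj = simulate_wc(replace(net, I_ext=I), T=T, dt=dt, record_every=record_every)
            f, _ = dominant_frequency(traj)
            out[a_, b_] = f
    return out
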