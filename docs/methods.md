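# Methods

## Scope and model layers

The package connects one exact theory to two progressively more biological
simulation layers:

1. **Signed-graph layer.** Populations are purely excitatory (E) or
   inhibitory (I); an edge inherits its sign from its source node. A
   directed cycle with an odd number of inhibitory edges is a negative
   loop; only negative loops can support oscillations. Cycle enumeration
   uses Johnson's algorithm (`networkx.simple_cycles`), canonicalised by
   rotating the lexicographically smallest node first; cycles are directed,
   so a reversal is a different cycle unless both edge directions exist. A
   node inhibiting itself is a negative loop of length 1; it is enumerated
   and flagged, but reported separately because the single-cycle theory
   below requires length ≥ 2.
2. **Threshold-linear network (TLN).** Leaky integration of rectified
   drive, decay rate fixed at 1 for every node (unequal decay rates change
   the stability conditions and are out of scope).
3. **Wilson-Cowan and spiking layers.** Numerical checks that the
   structural picture survives sigmoidal rate dynamics with transmission
   delays, and noise-driven spiking populations.

## Single-cycle TLN theory

For a cycle with node `i` projecting to `i+1` (mod n) with weight magnitude
`w_i`, signed by the source node, the *inhibited* set A holds the nodes
whose predecessor is inhibitory; exactly these receive a constant positive
input `b`. The classifier evaluates, for consecutive inhibited nodes
`a_k`, `a_{k+1}`:

* weak coupling — every segment product `prod_{i=a_k}^{a_{k+1}-1} w_i`
  strictly below its input ratio `b_{a_{k+1}}/b_{a_k}` — yields a unique
  globally stable fixed point with full support (`WEAK_GLOBAL_STABLE`);
* strong coupling (every product strictly above its ratio) with even
  `n_I` yields two stable fixed points on strict complementary supports
  (`EVEN_BISTABLE`, winner-take-all);
* strong coupling with odd `n_I` is decided by the geometric-mean weight
  against `1/cos(pi/n)`: `ODD_STABLE` below, `ODD_UNSTABLE_OSCILLATORY`
  above (the unique fixed point loses stability and the bounded dynamics
  must enter a limit cycle, quasi-periodic or chaotic attractor).

When `n_I = 1` the single segment wraps the whole cycle: the product is
`prod_i w_i` and the ratio is 1. Inequalities are evaluated with relative
tolerance 1e-9; a quantity within tolerance of its bound, or disagreeing
segments (some above, some below), map to `INDETERMINATE_GAP` — the theory
genuinely leaves these regions open, so the classifier never guesses.
Purely excitatory cycles and the 2-node EI pair are `OUT_OF_SCOPE`: the EI
pair always converges (Jacobian eigenvalues `-1 ± i sqrt(w1 w2)`), which is
why a negative loop alone is not sufficient in this model class.

The closed-form cycle spectrum is `-1 + rho * zeta` with
`rho = (prod w_i)^{1/n}` and `zeta` ranging over the n-th roots of
`(-1)^{n_I}`; for odd `n_I` the leading real part `-1 + rho cos(pi/n)`
crosses zero exactly at the critical coupling. Tests compare this closed
form with a dense eigensolver as an order-free point-set (Hausdorff)
distance, since conjugate pairs with equal real parts have no stable sort
order in floating point.

**Quenching.** Extra constant input `b+` to an excited node propagates
multiplicatively down the excitatory run; once `b+ * prod w` along the run
exceeds the input of the next inhibited node, that node is silenced
permanently, the cycle is functionally broken and oscillation is prevented.
Negative extra input instead tightens the weak-coupling condition; the
predictor reports the modified inequality rather than a binary verdict.

**Fixed points.** `enumerate_fixed_points` solves the restricted linear
system for every candidate support and accepts solutions that are positive
on-support with non-positive off-support drive. Stability is labelled from
the on-support Jacobian `-I + W_ss` only; threshold-boundary modes are not
analysed, so "linearly-stable" refers to the smooth branch. Global
stability is a *claim* attached by the acyclic solver and verified only by
multi-start simulation.

**Integration.** Forward Euler with dt = 0.01 (the rectification makes
higher-order smooth steppers pointless at these scales). Default initial
states are drawn uniformly inside the per-segment admissibility box
`[0, b_{a_k} prod w]`, seeded. Trajectory classification splits the record
into quarters: converged if the last quarter stays within 1e-4 of the final
state; sustained if the last quarter's peak-to-trough amplitude is above
1e-3 and at least 0.9 of the previous quarter's; transient if oscillatory
early but below the floor late.

## Wilson-Cowan layer

`tau dr_i/dt = -r_i + F(sum_j w_ij r_j(t - d_ij) + I_i)` with
`F(x) = 1/(1+e^{-a(x-theta)}) - 1/(1+e^{a theta})`, so `F(0) = 0`; defaults
`tau = 20 ms`, `theta = 1.5`, `a = 3` (slope `a/4` at the inflection).
Euler at dt = 0.01 ms with per-edge integer-step delay ring buffers;
history before t = 0 is the initial state. Rates live in F's range: a fully
inhibited population can sit marginally *below* zero (by at most
`1/(1+e^{a theta})`, about 0.011 at the defaults); no clamping is applied.

Two numerical choices matter:

* **Symmetry breaking.** The homogeneous III and EII rings have an
  invariant manifold `r_1 = r_2 = r_3` on which the structural instability
  cannot grow. A scalar initial state is therefore expanded with a
  deterministic 1% per-population stagger (base value 0.1); without it a
  zero-delay III ring would appear — falsely — unable to oscillate.
* **Frequency readout.** The summed rate is downsampled to 1 kHz, the first
  half of the record is discarded as transient for frequency estimation,
  and the oscillation class over the *full* record distinguishes transient
  from sustained rhythms.

Fixtures: the inhibitory 3-ring (cross weight -15, input 6, zero delay;
sustained oscillator at 40 Hz), the EII ring (E→I at +15; transient only),
an EI pair with 2 ms delays (analogous defaults), and the four-population
basal-ganglia network (D2, Arky, Proto, STN; all cross weights ±15 except
Proto self-inhibition -8 and STN self-excitation +5 as printed, 2 ms
delays). The Proto input is 1 by default and 4 in the STN-output-lesion
setting, compensating the lost excitatory drive. The STN self-excitation
entry is kept as printed but can be zeroed via `bg4_fixture(stn_self=False)`.
Sweeps set the swept quantity homogeneously across all relevant entries, as
in the underlying experiments.

## Spiking layer

D2-SPN, FSN and STN are conductance-based LIF neurons
(`C dV/dt = I_e + I_syn - g_L (V - V_reset)`, 2 ms refractory clamp); GPe
Proto and Arky are AdEx (exponential spike initiation, adaptation current
with jump `b` per spike). The leak reversal equals the reset potential, as
specified for this model family. Alpha-conductance synapses
(`g(t) = J (t/tau) e^{-(t-tau)/tau}`, peak `J` at `t = tau`) are integrated
as exact linear two-state filters between steps; membrane equations use
fixed-step RK4 at dt = 0.1 ms with threshold events resolved at step
boundaries. Synaptic currents are applied as `I_syn = -g (V - E_rev)` so
that input through a high-reversal channel depolarizes; the sign convention
is fixed here, in one place. Every neuron receives an independent Poisson
excitatory train (same rate within a population) plus a constant bias; the
bias on STN is the experimental knob of the inhibition sweeps.

Population rhythms are read from the pooled PSTH (0.1 ms rectangular bins,
block-averaged to 1 kHz) via Welch PSD; beta power is the integral over
13–30 Hz.

**Parameter provenance.** The neuron, synapse and connectivity values of
the built-in fixtures are synthetic defaults in the style of published
basal-ganglia spiking models, chosen once so that the fixtures realise the
intended dynamical regimes; they are not a published parameter table and
are fully configurable. The two oscillator modes of the STN-inhibition
experiment use different kinetic presets, reflecting that each mode models
a differently-tuned preparation: the striato-pallidal
(Proto–Arky–D2) mode uses fast pallidal membranes (tau_m = 10 ms), 3 ms
GABA kinetics and loop delays 4/4/1 ms, giving a ~16 Hz loop rhythm that is
independent of STN; the Proto–STN mode uses slower pallidal membranes
(tau_m = 20 ms), stronger adaptation, 8 ms GABA kinetics and 7 ms delays,
placing the reciprocal-loop rhythm in the beta band. An 8 Hz adaptation
resonance of the AdEx populations (tau_w = 20 ms) competes with the loop
rhythm if the loop is made too slow — the reason the striato-pallidal
preset uses weak spike-triggered adaptation (b = 10 pA).

Population size defaults to 300 neurons per population — small enough for
desk-scale runs, large enough for a clear population rhythm; sizes, rates
and all synaptic parameters are configurable. Simulations are exactly
reproducible given a seed (one seed drives connectivity and all Poisson
realizations).

## What the synthetic conditions do and do not show

The generators and fixtures emulate the *study conditions*: homogeneous
single-cycle TLNs with log-uniform weights in [0.3, 3] and inputs in
[0.5, 2]; motif-scale Wilson-Cowan networks with table parameters; Poisson-
driven spiking motifs in a Parkinson-like high-striatal-drive state. They
do not emulate heterogeneous weights within a projection, multi-cycle TLN
interference, short-term plasticity, or physiological firing-rate
calibration of every population (D2 rates in the spiking motifs are high,
as expected when the striatum is the driven node of the oscillator).
Passing tests therefore demonstrate the structural theory and the
qualitative robustness claims, not quantitative fidelity to any particular
recorded dataset: exact oscillation frequencies depend on delays, weights
and inputs and are deliberately not asserted beyond band membership and
monotone trends.

## Numerical tolerances and edge cases

* Regime inequalities: relative tolerance 1e-9; ties are reported as the
  gap, never resolved by guess.
* Regime/dynamics concordance tests exclude a ±2% band around every
  condition boundary, where finite-horizon simulation cannot decide.
* Fixed-point support solver: supports with singular on-support systems
  are skipped and reported as degenerate; acceptance thresholds 1e-10.
* Acyclic convergence and fixed-point residuals: 1e-6 and 1e-9.
* Welch defaults: Hann window, 50% overlap, segment = min(len/4, 4096),
  mean detrend; dominant frequency excludes the DC bin.
* Spiking delays are rounded to integer steps with a minimum of one step;
  the AdEx exponential argument is capped at 20 to avoid overflow between
  threshold crossings.

## Problem sizes

Default test and reproduction sizes: 200 random cycles for the
concordance check (T = 500 for oscillatory, 5 × T = 300 for weak-coupling
cases), 100 cycles for the spectrum check, 50 random DAGs (n ≤ 8, 3 starts
each), 20 cycles for quenching, six-iteration bisection for the critical
coupling, 5 s Wilson-Cowan records, and 1.5 s spiking sweeps (0.5 s
transient) at 300 neurons per population over five STN bias currents per
mode. These sizes give stable qualitative outcomes across seeds.
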