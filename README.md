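# oscicycle

Structural conditions for oscillations in networks of excitatory and
inhibitory populations: when can a network oscillate, knowing only which
nodes connect to which and the sign of each interaction?

The package is aimed at computational and systems neuroscientists (and
anyone studying signed interaction networks — gene circuits, ecological or
social networks) who want to reason about rhythmogenesis from connectivity
structure alone, and to test those predictions in firing-rate and spiking
simulations. Its running application is the cortico-basal-ganglia (CBG)
network and the pathological beta-band (13–30 Hz) oscillations of
Parkinson's disease.

## The odd inhibitory cycle rule

A directed cycle is *negative* when it contains an odd number of inhibitory
connections. Only negative cycles of two or more nodes can support
oscillations; and structure alone is not enough — coupling must also be
strong enough. For the threshold-linear network (TLN)

$$\dot x_i = -x_i + \Big[\sum_j W_{ij} x_j + b_i\Big]_+ ,\qquad [\,\cdot\,]_+ = \max(\cdot, 0),$$

the package implements two exact structural results:

* **Acyclic graphs.** A TLN whose interaction graph contains no directed
  cycle has a unique globally asymptotically stable fixed point, computed
  exactly by forward propagation in topological order.
* **Single cycles.** For one directed cycle with weights $w_i > 0$, $n_I$
  inhibitory nodes and positive inputs $b$ on the *inhibited* nodes
  (those whose predecessor is inhibitory), the long-term behaviour is
  decided by segment products $\prod_{i=a_k}^{a_{k+1}-1} w_i$ against input
  ratios $b_{a_{k+1}}/b_{a_k}$, and — for odd $n_I$ under strong coupling —
  by the geometric mean $(\prod_i w_i)^{1/n}$ against the critical value
  $1/\cos(\pi/n)$: below it the unique fixed point is stable, above it the
  fixed point is unstable and the bounded dynamics must oscillate. Even
  $n_I$ with strong coupling gives winner-take-all bistability instead.
  Extra excitatory input to an *excited* node can break the cycle and
  quench the oscillation once it out-drives the next inhibited node.

Around this core the package provides: signed-graph cycle enumeration and
the CBG motif-coverage analysis, a delayed Wilson-Cowan simulator with the
motif and basal-ganglia parameter sets (sweeps over delay / weight / input /
self-connection, lesion experiments), a desk-scale spiking model of
basal-ganglia motifs (conductance-based LIF and AdEx neurons, alpha
synapses, Poisson drive) with the STN-inhibition experiment, and shared
Welch-PSD / band-power / oscillation-classification metrics.

## Worked example

Count the oscillation-capable loops of the CBG network (8 populations:
D2-SPN, FSN, GPe Proto, GPe Arky, GPi, STN, thalamus, cortex) and check
which survive STN removal:

```bash
$ oscicycle counts reproduce
{
  "total_subnetworks": 246,
  "covered_subnetworks": 96,
  "loops_without_stn": 3,
  "loops_with_gpe": 5,
  ...
}
```

Of the 246 induced subnetworks with 2–7 nodes, 96 contain at least one of
the six negative loops, three of those loops do not involve the STN, and
five involve the GPe — which is why near-complete GPe suppression, but not
STN suppression, is expected to abolish pathological beta oscillations.

Classify a uniform all-inhibitory triangle with coupling 2.5 (above the
critical value $1/\cos(\pi/3) = 2$):

```bash
$ cat iii.json
{"signs": ["I","I","I"], "weights": [2.5, 2.5, 2.5], "b": [1, 1, 1]}
$ oscicycle tln classify iii.json
{
  "label": "ODD_UNSTABLE_OSCILLATORY",
  "segment_products": [2.5, 2.5, 2.5],
  "input_ratios": [1.0, 1.0, 1.0],
  "geometric_mean_weight": 2.5,
  "critical_coupling": 1.9999999999999996,
  ...
}
$ oscicycle tln simulate iii.json --T 200
{"classification": "sustained-oscillation", "t_end": 200.0}
```

The classifier reads the inequalities (strong coupling, odd inhibitory
count, geometric mean above threshold) and the simulation confirms the
predicted sustained oscillation. Other entry points: `oscicycle wc simulate
--fixture III`, `oscicycle wc sweep --fixture III --param delay --grid
0:10:1`, `oscicycle spiking stn-sweep --mode proto-d2-arky`, `oscicycle
graph analyze`, `oscicycle metrics psd`.

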