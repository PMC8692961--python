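# chemfsa

Compile deterministic finite automata (DFAs) into stochastic chemical
reaction networks (CRNs) that store their state robustly, simulate them
exactly, and measure how reliably they transition.

## The problem

Engineered biomolecular systems — synthetic cells, DNA circuits, molecular
robots — need control programs that move between discrete internal states in
response to stimuli. At the molecule counts typical of prokaryotic cells
(hundreds to thousands of copies of a species), stochastic noise makes a
naive chemical encoding of "the current state" unreliable: partial
transitions leave the system smeared across states. `chemfsa` implements a
compilation scheme in which the automaton state is the identity of the
dominant species among a fixed population of *state molecules*, actively
stabilised by an n-way **approximate majority (AM)** consensus module:

```
S_i + S_j  -> B + B          (k_AM, for all i < j)
S_i + B    -> S_i + S_i      (k_AM)
```

The blank species B holds molecules that have left one state but not yet
committed to another; recruitment by the majority species drives the
population to all-one-species consensus, so small perturbations are erased.

Transitions are driven by input presentations through a two-step *flip*
mechanism. For each transition-table entry δ(q, a) = q′ the compiler emits

```
S_q + Input_a        -> S_q + Flip_{q→q′}    (k_Input)   transition mapping
Flip_{q→q′} + S_q    -> S_{q′}               (k_Flip)    transition
Flip_{q→q′}          -> ∅                    (k_FlipDecay) flip decay
```

With k_Input ≫ k_Flip ≫ k_AM the input is converted to flips before partial
transitions can compete, the flips convert the state population, and the AM
module then restores full consensus on the new state. Flip species are keyed
by the (source, target) state pair and shared across input symbols; the
three reactions above are emitted once per table entry.

Two input interfaces are provided: **consumable** inputs arrive as
instantaneous spikes and are destroyed by the mapping reactions, while
**catalytic** inputs are never consumed — they convert a self-regenerating
buffered input pool (production k_buf+, degradation k_buf−, resting mean
k_buf+/k_buf−) into active input on the rising edge of a square-wave signal.
A no-flip ablation variant (mapping and transition fused into
`Input_a + S_q -> S_{q′}`) is included to demonstrate why the flip step
matters.

Simulation is Gillespie's exact direct method with timed spike and
square-wave perturbations. A run is scored against DFA semantics with a
dominance rule: the system is "in" state q over an inter-presentation
window when the count of S_q, averaged over the middle 50% of sample
points, strictly exceeds 80% of the state-molecule total.

## Worked example: four-bit square roots

The flagship machine computes ⌊√v⌋ of a four-bit number read MSB-first. It
is built by compressing the 4-level binary decision tree of the function —
collapsing every prefix whose completions share one answer into a single
accepting state per answer, minimising the remainder — and adding a Reset
symbol that returns every state to the start. The result has 11 states, 4
of them accepting.

```sh
$ chemfsa compile --sqrt --interface catalytic --out sqrt_crn.json
species:   50
reactions: 174
  approximate_majority 66
  transition_mapping   33
  transition           33
  flip_decay           33
  buffer_regeneration  6
  buffer_conversion    3
```

Simulating the compiled network with 100 state molecules, presenting the
bits of 10 (`1,0,1,0`), a Reset, then the bits of 7 (`0,1,1,1`) as square
waves of 80 catalytic-input molecules:

```sh
$ chemfsa demo sqrt --values 10,7 --seed 0
isqrt(10) -> 3
isqrt(7) -> 2
transitions correct: 10/10
```

The population walks the automaton exactly: after the fourth bit the
accepting species S3 holds all 100 state molecules (⌊√10⌋ = 3), the Reset
presentation returns them to the start state, and the second number ends in
S2 (⌊√7⌋ = 2). All ten presentations (eight bits plus two Resets) produce
the DFA-prescribed state.

The flip ablation on the three-state cycle (three 80-molecule spikes into
100 state molecules) shows why the two-step mechanism matters:

```sh
$ chemfsa demo three-cycle --seeds 20
pooled fraction correct: 1.000
$ chemfsa demo three-cycle --no-flips --seeds 20
pooled fraction correct: 0.183
```

Rate-characterisation sweeps over (k_Input, k_Flip) grids are available via
`chemfsa sweep --config sweep.yaml`, writing a long-format CSV and greyscale
heatmaps (white = all transitions correct).

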