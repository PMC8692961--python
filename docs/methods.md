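# Methods

## Model

A deterministic finite automaton (Q, Σ, δ, q0, F) is realised as a
mass-action CRN over integer molecule counts in an implicit unit volume;
rate constants are used directly as stochastic rate parameters (1/time for
zeroth/first order, 1/(molecule·time) for second order). A fixed population
of N state molecules (default 100) carries the automaton state as the
identity of the dominant state species. Three assumptions underlie the
design:

* **well-mixedness** — the CRN is spatially homogeneous, so Gillespie
  dynamics are exact;
* **timescale separation** — k_Input ≫ k_Flip ≫ k_AM, so an input
  presentation is converted into flip species essentially before flipping
  begins, flips convert the state population before consensus restoration
  competes, and the AM module then re-establishes a 100% representation;
* **presentation spacing** — consecutive inputs are far enough apart that
  the system reaches consensus (and, for catalytic inputs, the buffer
  regenerates) between presentations.

Every emitted reaction preserves the number of state-plus-blank molecules
(pair blanking 2→2B, recruitment B→S, flip transition S_q→S_{q′}), so N is
an exact invariant of any compiled network; this is checked structurally
and at every sample point of simulated runs.

### Compilation accounting

For an n-state machine with |δ| = n·|Σ| table entries and P distinct
(source, target) transition pairs:

| interface  | reactions                    | species              |
|------------|------------------------------|----------------------|
| consumable | C(n,2) + n + 3·|δ|            | n + 1 + P + |Σ|       |
| catalytic  | consumable + 3·|Σ|            | consumable + 2·|Σ|    |
| no-flip    | C(n,2) + n + |δ|              | n + 1 + |Σ|           |

Flip species are keyed by the (source, target) pair — shared across symbols
inducing the same pair, self-pairs included — while mapping/transition/decay
reactions are emitted once per table entry without deduplication. Entries
that share a flip species therefore contribute duplicate reactions; these
are deliberate (a duplicate channel is kinetically identical to doubling
its rate) and arise only for accepting-state self-loops in practice. For
the four-bit square-root machine (11 states, 3 symbols, 33 entries, 29
pairs) this yields 174 reactions and 50 species with the catalytic
interface. Self-transitions compile to real flip machinery: the mapping
reaction consumes input, the transition is a no-op, and the decay removes
the flip, so self-loops damp inputs rather than ignoring them.

## Parameters

| parameter     | default | units              | role |
|---------------|---------|--------------------|------|
| k_AM          | 1       | 1/(molecule·time)  | consensus restoration; the slowest timescale |
| k_Flip        | 10      | 1/(molecule·time)  | flip consumption; 10× faster than AM |
| k_Input       | 100     | 1/(molecule·time)  | input→flip mapping; fastest |
| k_FlipDecay   | 1       | 1/time             | clears leftover flips, removing memory of the last transition |
| k_buf+        | 1       | molecules/time     | buffered-input production |
| k_buf−        | 0.01    | 1/time             | buffered-input degradation; resting pool k_buf+/k_buf− = 100 |
| k_cat         | 10      | 1/(molecule·time)  | catalytic conversion of buffered to active input |
| N (state molecules) | 100 | molecules        | biologically relevant prokaryotic copy-number scale |
| presentation amount | 80 (demos) / 128 (reliability runs) | molecules | must exceed 50% of N to flip the majority |

The (k_Input, k_Flip) defaults sit inside the 100%-success plateau of the
rate sweeps; the sweep harness (`run_sweep`) re-derives that plateau on
log-spaced grids, and the test suite checks a 4×4 grid spanning four orders
of magnitude at N_Input ∈ {64, 128}.

## Input presentation

Consumable inputs are instantaneous spikes (count += amount). Catalytic
inputs are square waves: the catalytic species is *set* to the level on the
rising edge and set to zero on the falling edge — set, not added, because a
non-consumed signal's copy number is clamped by its source. The demo
presentation geometry for catalytic inputs is a 200-time-unit gap between
rising edges with the wave on for 50 units (25% duty). The spike of active
input delivered at a rising edge equals the buffered pool at that moment,
which regenerates toward 100 with time constant 1/k_buf− = 100 *only while
the previous wave is off*; an off-time of 150 units leaves a mean of
100·(1−e^−1.5) ≈ 78 molecules — matching the 80-molecule presentations used
everywhere else — while a 50% duty cycle at shorter gaps would deliver ~53,
barely above the 50-molecule switching threshold. The duty cycle and gap
are configurable.

## Simulation and scoring

The simulator is the plain direct method: exact exponential waiting times,
categorical channel selection by cumulative propensity, full propensity
recomputation after every firing. At an event boundary the reaction clocks
are regenerated; this memoryless restart is exact for Markovian dynamics.
Traces are sampled on a uniform grid (default 1000 points, and at least
100–200 points per inter-presentation interval in the harnesses); the value
at a grid time is the state just after the last firing or event at or
before it. Randomness comes from one numpy PCG64 generator per run;
ensembles derive per-run seeds as seed0 + index, and sweep cells as
seed0 + 10000·cell + replicate, so every figure and table is bit-reproducible.

Detection averages each state species over the middle 50% of sample points
between consecutive presentations (symmetric trimming; the last window ends
at t_end) and reports the unique species whose average *strictly* exceeds
80% of the state-molecule total, or none. Since windowed averages sum to at
most the total, any threshold above 50% admits at most one detected state.
A presentation is scored correct when the detected state equals the state
the DFA prescribes after the input prefix so far — the *unconditional*
expected state, not one conditioned on earlier detections; a none detection
counts as a failed attempt. Under this convention a system stuck in its
start state still matches every n-th expected state of an n-cycle, so the
"dead zone" of the rate sweeps floors at ~1/n rather than 0; the
qualitative plateau/dead-zone contrast is unaffected.

The square-root demo decodes value i from the window following its fourth
bit (presentation 5i+3: four bits plus one Reset per value, MSB-first) by
mapping accepting species S_r to the integer r; a missing or non-accepting
detection decodes to none.

## What the experiments do and do not emulate

All inputs are synthetic by construction — the method is a compiler, not a
data-analysis pipeline. The square-wave catalytic signals emulate a Boolean
gene-expression input (a gene product present or absent at a fixed copy
number). Not modelled: cell growth and division, molecular crowding,
spatial gradients, crosstalk with a host metabolism, degradation of state
species themselves, and the rate-constant constraints of any concrete
chemistry (e.g. DNA strand displacement). Passing tests therefore show the
*design* is robust to intrinsic stochastic noise at realistic copy numbers,
not that a wet-lab realisation at these nominal rates exists.

## Numerical and design choices

* **Homodimeric propensity** uses k·x(x−1)/2; no compiled reaction is
  homodimeric, so this only affects user-authored networks.
* **Decision-tree compression**: bits are MSB-first; the root is never
  collapsed even for a constant function (the machine always consumes at
  least one symbol); accepting self-loops and Reset edges are added *after*
  compression and minimisation, so minimisation operates on the pure
  decision structure. Accepting states are named by output label, internal
  states by their shortest reaching prefix.
* **Buffered inputs start at round(k_buf+/k_buf−)**, their stationary mean,
  avoiding a warm-up transient.
* **Accepting states get no reporter species**; acceptance is read from the
  detected state at the relevant time.
* **Problem sizes**: stochastic checks use 10 seeds for the square-root
  demonstration, 100 seeds for the ablation and consensus/sub-threshold
  properties, 5 replicates × 10 presentations per sweep cell, and 10^4
  stationary samples (spaced 3 relaxation times) for the Poisson
  goodness-of-fit of the buffer pair.

## Limitations

* The direct method recomputes all propensities per firing — fine up to a
  few hundred reactions, but no dependency graph or tau-leaping is provided
  for larger networks.
* Only deterministic automata are supported; a nondeterministic table is
  rejected by validation.
* The reaction list is emitted, never reduced; users wanting a minimal
  network must deduplicate downstream.
* Detection needs a dense enough sample grid; the scorer raises (rather
  than silently degrading) when a window contains no sample points.
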