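"""Compile deterministic finite automata into approximate-majority CRNs.

The compiled network stores the automaton state in the identity of the
dominant state species among a fixed population of state molecules.  Four
reaction modules are emitted:

* **approximate majority (AM)** — pairwise blanking ``S_i + S_j -> B + B``
  (i < j) plus recruitment ``S_i + B -> S_i + S_i``, driving the population
  to consensus on whichever state species holds the majority;
* **transition mapping** — the current state species catalyses conversion of
  an active input into the flip species for the prescribed transition,
  ``S_q + Input_a -> S_q + Flip_{q->q'}``;
* **transition** — flips convert state molecules one at a time,
  ``Flip_{q->q'} + S_q -> S_{q'}``;
* **flip decay** — ``Flip_{q->q'} -> 0`` returns the system to a memoryless
  condition after each transition.

Flip species are keyed by the (source, target) state pair and shared across
input symbols inducing the same pair, but mapping/transition/decay reactions
are emitted once per transition-table entry; entries sharing a flip species
therefore contribute duplicate reactions, which are deliberately kept.

Two input interfaces exist: *consumable* (inputs arrive as instantaneous
spikes and are destroyed by the mapping reactions) and *catalytic* (a
non-consumed input species converts a self-regenerating buffered input into
active input, so the external signal is not depleted).  A no-flip ablation
variant fuses mapping and transition into one direct reaction per entry.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .automata import FSA
from .crn import CRN, Reaction, Species

__all__ = [
    "RateConfig",
    "CompilationReport",
    "compile_am",
    "compile_transitions",
    "compile_for_consumable_inputs",
    "compile_for_catalytic_inputs",
    "compile_without_flips",
    "report",
    "UNDECIDED",
    "flip_name",
    "input_species_name",
]

#: Name of the undecided ("blank") species of the AM module.
UNDECIDED = "B"


@dataclass(frozen=True)
class RateConfig:
    """Rate constants of the compiled network.

    Defaults are the values characterised as lying inside the
    100%-success region for 100 state molecules: the AM restoration rate is
    the slowest timescale, flipping is 10x faster and input-to-flip mapping
    100x faster (k_input >> k_flip >> k_am), so inputs convert to flips
    before partial transitions can compete.  Buffer rates give a resting
    buffered-input pool of k_buf_plus/k_buf_minus = 100 molecules.
    """

    k_am: float = 1.0
    k_input: float = 100.0
    k_flip: float = 10.0
    k_flip_decay: float = 1.0
    k_buf_plus: float = 1.0
    k_buf_minus: float = 0.01
    k_cat: float = 10.0

    def __post_init__(self) -> None:
        for name, value in self.__dict__.items():
            if value < 0:
                raise ValueError(f"{name} must be >= 0, got {value}")


@dataclass
class CompilationReport:
    """Species/reaction totals of a compiled CRN with a per-module breakdown."""

    n_species: int
    n_reactions: int
    per_module: dict[str, int] = field(default_factory=dict)

    def __str__(self) -> str:
        lines = [
            f"species:   {self.n_species}",
            f"reactions: {self.n_reactions}",
        ]
        for module, count in self.per_module.items():
            lines.append(f"  {module:<20s} {count}")
        return "\n".join(lines)


def flip_name(source: str, target: str) -> str:
    return f"Flip_{source}_to_{target}"


def input_species_name(symbol: str, kind: str = "active") -> str:
    """Species name for an input symbol.

    Symbols already starting with ``Input`` (e.g. the cycle machines'
    ``Input0``) are used as-is; anything else gets an ``Input_`` prefix.
    ``kind`` selects the active, buffered or catalytic variant.
    """
    base = symbol if symbol.startswith("Input") else f"Input_{symbol}"
    if kind == "active":
        return base
    if kind == "buffered":
        return f"{base}_buf"
    if kind == "catalytic":
        return f"{base}_cat"
    raise ValueError(f"unknown input species kind {kind!r}")


# ---------------------------------------------------------------------------
# Module emitters
# ---------------------------------------------------------------------------


def compile_am(states: list[str] | tuple[str, ...], k_am: float) -> list[Reaction]:
    """n-way approximate-majority module over the given state species.

    Emits C(n,2) blanking reactions (one per unordered pair, both products
    the undecided species) and n recruitment reactions; n >= 2 required.
    """
    states = list(states)
    n = len(states)
    if n < 2:
        raise ValueError(f"AM module needs at least 2 states, got {n}")
    if k_am < 0:
        raise ValueError("k_am must be >= 0")
    reactions: list[Reaction] = []
    for i in range(n):
        for j in range(i + 1, n):
            reactions.append(
                Reaction([states[i], states[j]], [UNDECIDED, UNDECIDED], k_am)
            )
    for s in states:
        reactions.append(Reaction([s, UNDECIDED], [s, s], k_am))
    return reactions


def compile_transitions(fsa: FSA, rates: RateConfig) -> list[Reaction]:
    """Transition mapping, transition, and flip decay reactions.

    Three reactions per transition-table entry (q, a) -> q'; duplicates
    arising from entries that share a (source, target) flip species are
    emitted and kept.
    """
    _require_total(fsa)
    reactions: list[Reaction] = []
    for q, a, q2 in fsa.transition_entries():
        flip = flip_name(q, q2)
        inp = input_species_name(a)
        reactions.append(Reaction([q, inp], [q, flip], rates.k_input))
        reactions.append(Reaction([flip, q], [q2], rates.k_flip))
        reactions.append(Reaction([flip], [], rates.k_flip_decay))
    return reactions


def _require_total(fsa: FSA) -> None:
    violations = fsa.validate()
    if violations:
        raise ValueError("FSA is not a valid total DFA: " + "; ".join(violations))


def _declare_core_species(crn: CRN, fsa: FSA) -> None:
    for q in fsa.states:
        crn.add_species(Species(q, "state"))
    crn.add_species(Species(UNDECIDED, "undecided"))


def _declare_flip_species(crn: CRN, fsa: FSA) -> None:
    for q, _a, q2 in fsa.transition_entries():
        crn.add_species(Species(flip_name(q, q2), "flip"))


def _set_initial_state(crn: CRN, fsa: FSA, n_state_molecules: int) -> None:
    if n_state_molecules <= 0:
        raise ValueError("n_state_molecules must be positive")
    crn.set_initial_count(fsa.start, n_state_molecules)


def compile_for_consumable_inputs(
    fsa: FSA, rates: RateConfig | None = None, n_state_molecules: int = 100
) -> CRN:
    """Compile with the consumable-input interface.

    Species: one per automaton state, the undecided species, one flip
    species per distinct (source, target) pair, and one active-input species
    per alphabet symbol.  All state molecules start as the start state.
    """
    rates = rates or RateConfig()
    _require_total(fsa)
    crn = CRN()
    _declare_core_species(crn, fsa)
    _declare_flip_species(crn, fsa)
    for a in fsa.alphabet:
        crn.add_species(Species(input_species_name(a), "input_active"))
    for rxn in compile_am(list(fsa.states), rates.k_am):
        crn.add_reaction(rxn)
    for rxn in compile_transitions(fsa, rates):
        crn.add_reaction(rxn)
    _set_initial_state(crn, fsa, n_state_molecules)
    return crn


def compile_for_catalytic_inputs(
    fsa: FSA, rates: RateConfig | None = None, n_state_molecules: int = 100
) -> CRN:
    """Compile with the catalytic (non-consumed) input interface.

    On top of the consumable network, each symbol gains a buffer
    regeneration pair (zeroth-order production at k_buf_plus, first-order
    degradation at k_buf_minus) and a conversion reaction in which the
    catalytic input converts buffered input to active input without being
    consumed.  Buffered inputs start at their steady-state mean
    round(k_buf_plus/k_buf_minus), avoiding a warm-up period.
    """
    rates = rates or RateConfig()
    if rates.k_buf_minus == 0 and rates.k_buf_plus > 0:
        raise ValueError(
            "k_buf_minus = 0 with k_buf_plus > 0: buffered input has no steady state"
        )
    crn = compile_for_consumable_inputs(fsa, rates, n_state_molecules)
    buf_level = (
        round(rates.k_buf_plus / rates.k_buf_minus) if rates.k_buf_plus > 0 else 0
    )
    for a in fsa.alphabet:
        active = input_species_name(a)
        buf = input_species_name(a, "buffered")
        cat = input_species_name(a, "catalytic")
        crn.add_species(Species(buf, "input_buffered"))
        crn.add_species(Species(cat, "input_catalytic"))
        crn.add_reaction(Reaction([], [buf], rates.k_buf_plus))
        crn.add_reaction(Reaction([buf], [], rates.k_buf_minus))
        crn.add_reaction(Reaction([cat, buf], [cat, active], rates.k_cat))
        crn.set_initial_count(buf, buf_level)
    return crn


def compile_without_flips(
    fsa: FSA, rates: RateConfig | None = None, n_state_molecules: int = 100
) -> CRN:
    """Ablation variant without flip species.

    Mapping and transition modules are fused into one direct reaction
    ``Input_a + S_q -> S_{q'}`` per transition-table entry, at k_input; no
    flip species and no decay.  Used to demonstrate that the two-step flip
    mechanism is what stabilises state changes.
    """
    rates = rates or RateConfig()
    _require_total(fsa)
    crn = CRN()
    _declare_core_species(crn, fsa)
    for a in fsa.alphabet:
        crn.add_species(Species(input_species_name(a), "input_active"))
    for rxn in compile_am(list(fsa.states), rates.k_am):
        crn.add_reaction(rxn)
    for q, a, q2 in fsa.transition_entries():
        crn.add_reaction(Reaction([input_species_name(a), q], [q2], rates.k_input))
    _set_initial_state(crn, fsa, n_state_molecules)
    return crn


# ---------------------------------------------------------------------------
# Reporting
# ---------------------------------------------------------------------------


def _classify(rxn: Reaction, roles: dict[str, str]) -> str:
    rroles = [roles.get(s, "other") for s in rxn.reactants]
    proles = [roles.get(s, "other") for s in rxn.products]
    if not rxn.reactants:
        return "buffer_regeneration"
    if rroles == ["input_buffered"] and not rxn.products:
        return "buffer_regeneration"
    if "input_catalytic" in rroles:
        return "buffer_conversion"
    if rroles == ["flip"] and not rxn.products:
        return "flip_decay"
    if sorted(rroles) == ["flip", "state"]:
        return "transition"
    if "input_active" in rroles and "flip" in proles:
        return "transition_mapping"
    if "input_active" in rroles:
        return "direct_transition"
    if set(rroles) <= {"state", "undecided"}:
        return "approximate_majority"
    return "other"


def report(crn: CRN) -> CompilationReport:
    """Count species and emitted reactions (duplicates counted) per module."""
    roles = {s.name: s.role for s in crn.species}
    per_module: dict[str, int] = {}
    for rxn in crn.reactions:
        module = _classify(rxn, roles)
        per_module[module] = per_module.get(module, 0) + 1
    return CompilationReport(
        n_species=len(crn.species),
        n_reactions=len(crn.reactions),
        per_module=per_module,
    )
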