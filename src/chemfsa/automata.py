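"""Deterministic finite automata: data model, execution, and constructors.

Two families of example machines are provided: ``build_cycle_fsa`` builds the
n-state single-input cycle used for rate characterisation, and
``build_function_fsa`` compresses the binary decision tree of an L-bit
Boolean-word function into a minimal DFA whose accepting states are labelled
by the function's output values — the construction behind the four-bit
square-root machine (:func:`build_sqrt_fsa`).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from itertools import product
from typing import Callable, Hashable, Iterable, Mapping, Sequence

__all__ = [
    "FSA",
    "DecisionTreeSpec",
    "build_cycle_fsa",
    "build_function_fsa",
    "build_sqrt_fsa",
    "sqrt4_decision_spec",
    "minimize_dfa",
    "RESET",
]

#: Conventional name of the reset input symbol.
RESET = "Reset"


@dataclass(frozen=True)
class FSA:
    """A deterministic finite automaton (Q, Sigma, delta, q0, F).

    ``delta`` must be total: an entry for every (state, symbol) pair.
    States and symbols are plain strings so the automaton serialises cleanly
    and its states can double as chemical species names.
    """

    states: tuple[str, ...]
    alphabet: tuple[str, ...]
    delta: Mapping[tuple[str, str], str]
    start: str
    accepting: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        object.__setattr__(self, "states", tuple(self.states))
        object.__setattr__(self, "alphabet", tuple(self.alphabet))
        object.__setattr__(self, "delta", dict(self.delta))
        object.__setattr__(self, "accepting", frozenset(self.accepting))

    # -- semantics --------------------------------------------------------

    def validate(self) -> list[str]:
        """Return violations of determinism/totality/membership (empty iff ok)."""
        violations: list[str] = []
        states = set(self.states)
        if len(states) != len(self.states):
            violations.append("duplicate state identifiers")
        if len(set(self.alphabet)) != len(self.alphabet):
            violations.append("duplicate alphabet symbols")
        if self.start not in states:
            violations.append(f"start state {self.start!r} not in Q")
        for f in sorted(self.accepting):
            if f not in states:
                violations.append(f"accepting state {f!r} not in Q")
        for q, a in product(self.states, self.alphabet):
            if (q, a) not in self.delta:
                violations.append(f"delta undefined for ({q!r}, {a!r})")
        for (q, a), q2 in self.delta.items():
            if q not in states or a not in set(self.alphabet):
                violations.append(f"delta entry ({q!r}, {a!r}) outside Q x Sigma")
            elif q2 not in states:
                violations.append(f"delta({q!r}, {a!r}) = {q2!r} not in Q")
        return violations

    def step(self, state: str, symbol: str) -> str:
        if symbol not in self.alphabet:
            raise KeyError(f"unknown input symbol {symbol!r}")
        return self.delta[(state, symbol)]

    def run(self, word: Iterable[str]) -> str:
        """Final state after reading ``word`` from the start state."""
        state = self.start
        for symbol in word:
            state = self.step(state, symbol)
        return state

    def transition_entries(self) -> list[tuple[str, str, str]]:
        """All delta entries as (state, symbol, next_state), in a stable order."""
        return [(q, a, self.delta[(q, a)]) for q in self.states for a in self.alphabet]

    # -- serialisation ----------------------------------------------------

    def to_json(self) -> str:
        return json.dumps(
            {
                "states": list(self.states),
                "alphabet": list(self.alphabet),
                "delta": [[q, a, q2] for (q, a), q2 in sorted(self.delta.items())],
                "start": self.start,
                "accepting": sorted(self.accepting),
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str, complete_with_self_loops: bool = False) -> "FSA":
        """Load from JSON; with the flag set, missing delta entries become self-loops."""
        payload = json.loads(text)
        delta = {(q, a): q2 for q, a, q2 in payload["delta"]}
        if complete_with_self_loops:
            for q in payload["states"]:
                for a in payload["alphabet"]:
                    delta.setdefault((q, a), q)
        fsa = cls(
            states=tuple(payload["states"]),
            alphabet=tuple(payload["alphabet"]),
            delta=delta,
            start=payload["start"],
            accepting=frozenset(payload.get("accepting", [])),
        )
        violations = fsa.validate()
        if violations:
            raise ValueError("invalid FSA: " + "; ".join(violations))
        return fsa


def fsa_validate(fsa: FSA) -> list[str]:
    return fsa.validate()


def fsa_run(fsa: FSA, word: Iterable[str]) -> str:
    return fsa.run(word)


# ---------------------------------------------------------------------------
# Constructors
# ---------------------------------------------------------------------------


def build_cycle_fsa(n: int, symbol: str = "Input0") -> FSA:
    """n-state cycle over a single input symbol: S0 -> S1 -> ... -> S0.

    Each presentation of the input advances the machine one step around the
    cycle.  Requires ``n >= 2``.  No accepting states are designated.
    """
    if n < 2:
        raise ValueError(f"cycle needs at least 2 states, got {n}")
    states = tuple(f"S{i}" for i in range(n))
    delta = {(states[i], symbol): states[(i + 1) % n] for i in range(n)}
    return FSA(states=states, alphabet=(symbol,), delta=delta, start=states[0])


@dataclass(frozen=True)
class DecisionTreeSpec:
    """Specification of an L-bit word function to compress into a DFA.

    ``output_fn`` maps each L-bit string (as a tuple of '0'/'1' symbols,
    most-significant bit first) to a hashable output label.  If
    ``reset_symbol`` is set, the alphabet gains a symbol that returns every
    state to the start.
    """

    word_length: int
    output_fn: Callable[[tuple[str, ...]], Hashable]
    reset_symbol: str | None = RESET

    def __post_init__(self) -> None:
        if self.word_length < 1:
            raise ValueError("word_length must be >= 1")

    def outputs_for_prefix(self, prefix: tuple[str, ...]) -> set[Hashable]:
        """Set of output labels over all completions of ``prefix``."""
        rest = self.word_length - len(prefix)
        return {
            self.output_fn(prefix + completion)
            for completion in product(("0", "1"), repeat=rest)
        }


def minimize_dfa(
    states: Sequence[str],
    alphabet: Sequence[str],
    delta: Mapping[tuple[str, str], str],
    start: str,
    labels: Mapping[str, Hashable],
) -> dict[str, str]:
    """Moore partition refinement; returns a state -> representative map.

    Only states carrying the same ``labels`` value may merge (accepting
    states labelled with distinct outputs stay distinct).  The representative
    of each block is its first member in ``states`` order.
    """
    # initial partition by label
    blocks: dict[Hashable, list[str]] = {}
    for q in states:
        blocks.setdefault(labels[q], []).append(q)
    partition = list(blocks.values())
    while True:
        block_of = {q: i for i, block in enumerate(partition) for q in block}
        refined: list[list[str]] = []
        for block in partition:
            sigs: dict[tuple[int, ...], list[str]] = {}
            for q in block:
                sig = tuple(block_of[delta[(q, a)]] for a in alphabet)
                sigs.setdefault(sig, []).append(q)
            refined.extend(sigs.values())
        if len(refined) == len(partition):
            break
        partition = refined
    return {q: block[0] for block in partition for q in block}


def build_function_fsa(spec: DecisionTreeSpec) -> FSA:
    """Compress the decision tree of an L-bit function into a minimal DFA.

    The machine accepts "early": any prefix whose completions all share one
    output label collapses into the single accepting state for that label
    (one accepting state per label reached this way).  The root is never
    collapsed, so at least one symbol is always consumed.  Residual internal
    states are merged by DFA minimisation, accepting states gain self-loops
    on both bits, and — if the spec carries a reset symbol — every state
    gains a reset edge back to the start.

    Internal states are named by their shortest reaching prefix (the root is
    ``Init``); accepting states are named ``S<label>``.
    """
    L = spec.word_length

    def state_name(prefix: tuple[str, ...]) -> str:
        return "Init" if not prefix else "N" + "".join(prefix)

    def accept_name(label: Hashable) -> str:
        return f"S{label}"

    # Walk the prefix tree breadth-first, collapsing decided prefixes into
    # per-label accepting states.  The root is always kept internal.
    internal: list[tuple[str, ...]] = []
    accept_labels: list[Hashable] = []
    delta01: dict[tuple[str, str], str] = {}
    frontier: list[tuple[str, ...]] = [()]
    while frontier:
        prefix = frontier.pop(0)
        internal.append(prefix)
        for bit in ("0", "1"):
            child = prefix + (bit,)
            outs = spec.outputs_for_prefix(child)
            if len(outs) == 1:
                (label,) = outs
                if label not in accept_labels:
                    accept_labels.append(label)
                delta01[(state_name(prefix), bit)] = accept_name(label)
            else:
                delta01[(state_name(prefix), bit)] = state_name(child)
                frontier.append(child)

    internal_names = [state_name(p) for p in internal]
    accept_names = [accept_name(l) for l in accept_labels]
    states = internal_names + accept_names
    for name in accept_names:  # self-loops, present during minimisation too
        delta01[(name, "0")] = name
        delta01[(name, "1")] = name

    labels: dict[str, Hashable] = {q: None for q in internal_names}
    labels.update({accept_name(l): ("accept", l) for l in accept_labels})
    rep = minimize_dfa(states, ("0", "1"), delta01, "Init", labels)

    reachable: list[str] = []

    def visit(q: str) -> None:
        if q not in reachable:
            reachable.append(q)
            for bit in ("0", "1"):
                visit(rep[delta01[(q, bit)]])

    visit(rep["Init"])
    min_states = tuple(q for q in states if q in set(reachable))
    min_delta = {
        (q, bit): rep[delta01[(q, bit)]] for q in min_states for bit in ("0", "1")
    }
    alphabet: tuple[str, ...] = ("0", "1")
    if spec.reset_symbol is not None:
        alphabet = alphabet + (spec.reset_symbol,)
        start = rep["Init"]
        for q in min_states:
            min_delta[(q, spec.reset_symbol)] = start
    return FSA(
        states=min_states,
        alphabet=alphabet,
        delta=min_delta,
        start=rep["Init"],
        accepting=frozenset(n for n in accept_names if n in set(min_states)),
    )


def bits_of(value: int, width: int) -> tuple[str, ...]:
    """MSB-first binary expansion of ``value`` as '0'/'1' symbols."""
    if not 0 <= value < 2**width:
        raise ValueError(f"value {value} does not fit in {width} bits")
    return tuple(format(value, f"0{width}b"))


def sqrt4_decision_spec(with_reset: bool = True) -> DecisionTreeSpec:
    """Decision-tree spec for the floor square root of a four-bit number."""

    def output(word: tuple[str, ...]) -> int:
        return math.isqrt(int("".join(word), 2))

    return DecisionTreeSpec(
        word_length=4,
        output_fn=output,
        reset_symbol=RESET if with_reset else None,
    )


def build_sqrt_fsa(with_reset: bool = True) -> FSA:
    """The four-bit square-root automaton (11 states, 4 accepting).

    Reading a four-bit number MSB-first, the machine lands in accepting
    state ``S{isqrt(v)}``; it commits as soon as the remaining bits cannot
    change the answer (e.g. after the prefix ``11``).  With the reset symbol
    it can compute square roots repeatedly.
    """
    return build_function_fsa(sqrt4_decision_spec(with_reset))
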