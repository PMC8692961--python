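"""Abstract chemical reaction network model with stochastic mass-action semantics.

A :class:`CRN` is an ordered list of species and an ordered list of (at most
bimolecular) mass-action reactions together with integer initial molecule
counts.  Counts-based semantics are used throughout: the volume is implicitly
1, so rate constants are applied directly as stochastic rate parameters
(units 1/time for zeroth/first order, 1/(molecule*time) for second order).

Duplicate reactions are legal and kept distinct in the reaction list; a
duplicated channel is kinetically equivalent to doubling its rate constant,
and preserving duplicates keeps compiled reaction counts faithful to the
per-transition-entry emission convention used by the compiler.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

__all__ = [
    "Species",
    "Reaction",
    "CRN",
    "SystemState",
    "propensity",
    "ROLES",
]

#: Recognised species roles.  ``state`` species carry the automaton state,
#: ``undecided`` is the blank species B of the approximate-majority module,
#: ``flip`` species are transition carriers, and the three ``input_*`` roles
#: distinguish active, buffered and catalytic input species.
ROLES = frozenset(
    {
        "state",
        "undecided",
        "flip",
        "input_active",
        "input_buffered",
        "input_catalytic",
        "other",
    }
)


@dataclass(frozen=True)
class Species:
    """A chemical species, identified by a unique name and a fixed role."""

    name: str
    role: str = "other"

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("species name must be non-empty")
        if self.role not in ROLES:
            raise ValueError(f"unknown species role {self.role!r}")


@dataclass(frozen=True)
class Reaction:
    """A mass-action reaction with at most two reactants and two products.

    ``reactants`` and ``products`` are multisets represented as sorted
    tuples of species names; either side may be empty (written ``0`` in the
    text serialisation).
    """

    reactants: tuple[str, ...]
    products: tuple[str, ...]
    rate_constant: float

    def __init__(
        self,
        reactants: Iterable[str],
        products: Iterable[str],
        rate_constant: float,
    ) -> None:
        object.__setattr__(self, "reactants", tuple(sorted(reactants)))
        object.__setattr__(self, "products", tuple(sorted(products)))
        object.__setattr__(self, "rate_constant", float(rate_constant))
        if len(self.reactants) > 2 or len(self.products) > 2:
            raise ValueError(
                "reactions are at most bimolecular: "
                f"{len(self.reactants)} reactants, {len(self.products)} products"
            )
        if not self.rate_constant >= 0:
            raise ValueError(f"rate constant must be >= 0, got {rate_constant}")

    def __str__(self) -> str:
        lhs = " + ".join(self.reactants) if self.reactants else "0"
        rhs = " + ".join(self.products) if self.products else "0"
        # repr() is shortest-round-trip for floats, keeping write->read lossless
        return f"{lhs} ->{{{self.rate_constant!r}}} {rhs}"


def propensity(reaction: Reaction, counts: Mapping[str, int]) -> float:
    """Stochastic mass-action propensity of ``reaction`` at the given counts.

    Zeroth order gives the bare rate constant; ``A -> ...`` gives ``k*x_A``;
    ``A + B -> ...`` gives ``k*x_A*x_B``; the homodimeric ``2A -> ...`` uses
    the combinatorial convention ``k*x_A*(x_A-1)/2``.
    """
    for name in reaction.reactants:
        if name not in counts:
            raise KeyError(f"species {name!r} missing from counts")
    r = reaction.reactants
    k = reaction.rate_constant
    if len(r) == 0:
        return k
    if len(r) == 1:
        return k * counts[r[0]]
    if r[0] == r[1]:
        x = counts[r[0]]
        return k * x * (x - 1) / 2.0
    return k * counts[r[0]] * counts[r[1]]


@dataclass
class SystemState:
    """Instantaneous state of a stochastic trajectory: time + molecule counts."""

    time: float
    counts: dict[str, int]


@dataclass
class CRN:
    """An abstract chemical reaction network.

    Species are kept in insertion order; reactions are an ordered list in
    which duplicates are permitted and meaningful.  Species referenced by a
    reaction added through :meth:`add_reaction` are auto-registered with role
    ``other`` if not declared beforehand.
    """

    species: list[Species] = field(default_factory=list)
    reactions: list[Reaction] = field(default_factory=list)
    initial_counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        names = [s.name for s in self.species]
        if len(names) != len(set(names)):
            raise ValueError("duplicate species names")

    # -- construction -----------------------------------------------------

    def species_names(self) -> list[str]:
        return [s.name for s in self.species]

    def has_species(self, name: str) -> bool:
        return any(s.name == name for s in self.species)

    def add_species(self, species: Species) -> Species:
        """Declare a species; re-declaring an identical one is a no-op."""
        for existing in self.species:
            if existing.name == species.name:
                if existing.role != species.role:
                    raise ValueError(
                        f"species {species.name!r} already declared with role "
                        f"{existing.role!r}"
                    )
                return existing
        self.species.append(species)
        self.initial_counts.setdefault(species.name, 0)
        return species

    def add_reaction(self, reaction: Reaction) -> "CRN":
        """Append ``reaction``; duplicates accumulate rather than merge."""
        for name in (*reaction.reactants, *reaction.products):
            if not self.has_species(name):
                self.add_species(Species(name, "other"))
        self.reactions.append(reaction)
        return self

    def set_initial_count(self, name: str, count: int) -> None:
        if not self.has_species(name):
            raise KeyError(f"unknown species {name!r}")
        if count < 0 or count != int(count):
            raise ValueError(f"initial count must be a nonnegative integer, got {count}")
        self.initial_counts[name] = int(count)

    def initial_state(self) -> SystemState:
        return SystemState(0.0, {s.name: self.initial_counts.get(s.name, 0) for s in self.species})

    # -- validation -------------------------------------------------------

    def validate(self) -> list[str]:
        """Return a list of invariant violations (empty iff well-formed)."""
        violations: list[str] = []
        names = self.species_names()
        seen: set[str] = set()
        for n in names:
            if n in seen:
                violations.append(f"duplicate species name {n!r}")
            seen.add(n)
        for i, rxn in enumerate(self.reactions):
            if len(rxn.reactants) > 2:
                violations.append(f"reaction {i} has {len(rxn.reactants)} reactants (max 2)")
            if len(rxn.products) > 2:
                violations.append(f"reaction {i} has {len(rxn.products)} products (max 2)")
            if rxn.rate_constant < 0:
                violations.append(f"reaction {i} has negative rate constant")
            for name in (*rxn.reactants, *rxn.products):
                if name not in seen:
                    violations.append(f"reaction {i} references undeclared species {name!r}")
        for name, count in self.initial_counts.items():
            if name not in seen:
                violations.append(f"initial count for undeclared species {name!r}")
            if count < 0 or count != int(count):
                violations.append(f"negative or non-integer initial count for {name!r}")
        return violations

    # -- serialisation ----------------------------------------------------

    def to_text(self) -> str:
        """Line-oriented reaction-list form, one ``A + B ->{k} C + D`` per line."""
        return "\n".join(str(r) for r in self.reactions) + "\n"

    def to_json(self) -> str:
        """Structured JSON form carrying roles, initial counts and reactions."""
        payload = {
            "species": [{"name": s.name, "role": s.role} for s in self.species],
            "initial_counts": dict(self.initial_counts),
            "reactions": [
                {
                    "reactants": list(r.reactants),
                    "products": list(r.products),
                    "rate_constant": r.rate_constant,
                }
                for r in self.reactions
            ],
        }
        return json.dumps(payload, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "CRN":
        payload = json.loads(text)
        crn = cls()
        for s in payload["species"]:
            crn.add_species(Species(s["name"], s.get("role", "other")))
        for r in payload["reactions"]:
            crn.add_reaction(Reaction(r["reactants"], r["products"], r["rate_constant"]))
        for name, count in payload.get("initial_counts", {}).items():
            crn.set_initial_count(name, count)
        return crn

    @classmethod
    def from_text(cls, text: str) -> "CRN":
        crn = cls()
        for lineno, raw in enumerate(text.splitlines(), 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            crn.add_reaction(parse_reaction(line, lineno=lineno))
        return crn


_REACTION_RE = re.compile(r"^(?P<lhs>.+?)\s*->\s*\{(?P<rate>[^}]+)\}\s*(?P<rhs>.+)$")


def _parse_side(side: str) -> tuple[str, ...]:
    side = side.strip()
    if side == "0":
        return ()
    return tuple(term.strip() for term in side.split("+"))


def parse_reaction(line: str, lineno: int | None = None) -> Reaction:
    """Parse one ``A + B ->{k} C + D`` line (``0`` denotes an empty side)."""
    m = _REACTION_RE.match(line.strip())
    if m is None:
        where = f" (line {lineno})" if lineno is not None else ""
        raise ValueError(f"cannot parse reaction{where}: {line!r}")
    return Reaction(
        _parse_side(m.group("lhs")),
        _parse_side(m.group("rhs")),
        float(m.group("rate")),
    )
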