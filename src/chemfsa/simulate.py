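"""Exact stochastic simulation of a CRN under timed input perturbations.

The integrator is Gillespie's direct method: between perturbation events the
jump process is simulated exactly, and at each event boundary the reaction
clocks are regenerated (a memoryless restart, which is exact for Markovian
mass-action dynamics).  Two perturbation kinds are supported:

* :class:`SpikeEvent` — an instantaneous addition of molecules, used to
  present consumable inputs;
* :class:`SquareWaveEvent` — the species count is *set* to a level on the
  rising edge and set to zero on the falling edge, used for non-consumed
  catalytic inputs whose copy number is clamped by the environment.

Traces are sampled on a uniform grid; the value at a grid time is the state
just after the last reaction or event at or before that time.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .crn import CRN

__all__ = [
    "SpikeEvent",
    "SquareWaveEvent",
    "EventSchedule",
    "Trace",
    "simulate",
    "simulate_ensemble",
]


@dataclass(frozen=True)
class SpikeEvent:
    """Instantaneous addition of ``amount`` molecules of ``species`` at ``time``."""

    time: float
    species: str
    amount: int

    def __post_init__(self) -> None:
        if self.amount <= 0:
            raise ValueError("spike amount must be positive")
        if self.time < 0:
            raise ValueError("spike time must be nonnegative")


@dataclass(frozen=True)
class SquareWaveEvent:
    """Clamp ``species`` to ``level`` on [t_on, t_off), then back to zero."""

    species: str
    t_on: float
    t_off: float
    level: int

    def __post_init__(self) -> None:
        if self.t_off <= self.t_on:
            raise ValueError("t_off must exceed t_on")
        if self.level <= 0:
            raise ValueError("square-wave level must be positive")


@dataclass
class EventSchedule:
    """Timed perturbations plus the logical input-presentation sequence.

    ``presentations`` records, in order, the (start time, input symbol) of
    each input presentation (spike times or square-wave rising edges); the
    evaluation module scores one expected state transition per presentation.
    """

    spikes: list[SpikeEvent] = field(default_factory=list)
    waves: list[SquareWaveEvent] = field(default_factory=list)
    presentations: list[tuple[float, str]] = field(default_factory=list)

    @property
    def presentation_times(self) -> list[float]:
        return [t for t, _ in self.presentations]

    @property
    def symbols(self) -> list[str]:
        return [a for _, a in self.presentations]

    def validate(self) -> None:
        if sorted(self.presentation_times) != self.presentation_times:
            raise ValueError("presentations must be sorted by time")
        by_species: dict[str, list[SquareWaveEvent]] = {}
        for w in self.waves:
            by_species.setdefault(w.species, []).append(w)
        for species, waves in by_species.items():
            waves = sorted(waves, key=lambda w: w.t_on)
            for a, b in zip(waves, waves[1:]):
                if b.t_on < a.t_off:
                    raise ValueError(f"overlapping square waves on {species!r}")

    def boundaries(self) -> list[tuple[float, str, str, int]]:
        """All perturbations flattened to (time, op, species, value), sorted.

        ``op`` is ``add`` (spike) or ``set`` (wave edge).
        """
        events: list[tuple[float, str, str, int]] = []
        for s in self.spikes:
            events.append((s.time, "add", s.species, s.amount))
        for w in self.waves:
            events.append((w.t_on, "set", w.species, w.level))
            events.append((w.t_off, "set", w.species, 0))
        events.sort(key=lambda e: e[0])
        return events

    # -- serialisation ----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "spikes": [
                {"time": s.time, "species": s.species, "amount": s.amount}
                for s in self.spikes
            ],
            "waves": [
                {
                    "species": w.species,
                    "t_on": w.t_on,
                    "t_off": w.t_off,
                    "level": w.level,
                }
                for w in self.waves
            ],
            "presentations": [[t, a] for t, a in self.presentations],
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "EventSchedule":
        return cls(
            spikes=[SpikeEvent(**s) for s in payload.get("spikes", [])],
            waves=[SquareWaveEvent(**w) for w in payload.get("waves", [])],
            presentations=[(float(t), a) for t, a in payload.get("presentations", [])],
        )

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "EventSchedule":
        return cls.from_dict(yaml.safe_load(text))

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=1)

    @classmethod
    def from_json(cls, text: str) -> "EventSchedule":
        return cls.from_dict(json.loads(text))


@dataclass
class Trace:
    """One stochastic run sampled on a uniform time grid."""

    sample_times: np.ndarray
    counts: np.ndarray  # shape (n_samples, n_species)
    species: list[str]
    seed: int
    schedule: EventSchedule

    def series(self, species: str) -> np.ndarray:
        return self.counts[:, self.species.index(species)]

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.counts, columns=self.species)
        df.insert(0, "time", self.sample_times)
        return df

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def _compile_reactions(crn: CRN):
    """Index the reaction list into flat arrays for fast propensity updates."""
    index = {s.name: i for i, s in enumerate(crn.species)}
    n_species = len(crn.species)
    n_rxn = len(crn.reactions)
    k = np.empty(n_rxn)
    r1 = np.full(n_rxn, -1, dtype=np.int64)
    r2 = np.full(n_rxn, -1, dtype=np.int64)
    stoich = np.zeros((n_rxn, n_species), dtype=np.int64)
    for j, rxn in enumerate(crn.reactions):
        k[j] = rxn.rate_constant
        reactants = [index[s] for s in rxn.reactants]
        if len(reactants) >= 1:
            r1[j] = reactants[0]
        if len(reactants) == 2:
            r2[j] = reactants[1]
        for s in reactants:
            stoich[j, s] -= 1
        for s in rxn.products:
            stoich[j, index[s]] += 1
    return index, k, r1, r2, stoich


def simulate(
    crn: CRN,
    schedule: EventSchedule | None = None,
    t_end: float = 1.0,
    seed: int = 0,
    n_samples: int = 1000,
) -> Trace:
    """Run one exact SSA trajectory of ``crn`` under ``schedule``.

    Identical arguments produce an identical :class:`Trace`.  Raises if the
    CRN fails validation or the schedule references unknown species.
    """
    violations = crn.validate()
    if violations:
        raise ValueError("invalid CRN: " + "; ".join(violations))
    schedule = schedule or EventSchedule()
    schedule.validate()

    index, k, r1, r2, stoich = _compile_reactions(crn)
    boundaries = [e for e in schedule.boundaries() if e[0] <= t_end]
    for _, _, species, _ in boundaries:
        if species not in index:
            raise KeyError(f"schedule references unknown species {species!r}")

    x = np.zeros(len(crn.species), dtype=np.int64)
    for name, count in crn.initial_counts.items():
        x[index[name]] = count

    # propensity helpers: a = k * f(x[r1]) * g(x[r2])
    has1 = r1 >= 0
    has2 = r2 >= 0
    homo = has2 & (r1 == r2)
    r1c = np.where(has1, r1, 0)
    r2c = np.where(has2, r2, 0)

    def propensities() -> np.ndarray:
        f1 = np.where(has1, x[r1c], 1.0)
        x2 = x[r2c].astype(float)
        f2 = np.where(has2, np.where(homo, np.maximum(x2 - 1.0, 0.0) * 0.5, x2), 1.0)
        return k * f1 * f2

    sample_times = np.linspace(0.0, t_end, n_samples)
    samples = np.zeros((n_samples, len(x)), dtype=np.int64)
    si = 0  # next sample index to fill

    def record_until(t_new: float) -> None:
        nonlocal si
        hi = int(np.searchsorted(sample_times, t_new, side="left"))
        if hi > si:
            samples[si:hi] = x
            si = hi

    rng = np.random.default_rng(seed)
    t = 0.0
    bi = 0  # next boundary index
    while t < t_end:
        t_next = boundaries[bi][0] if bi < len(boundaries) else t_end
        a = propensities()
        a0 = float(a.sum())
        if a0 > 0.0:
            t_cand = t + rng.exponential(1.0 / a0)
        else:
            t_cand = np.inf
        if t_cand < t_next:
            # fire one reaction
            record_until(t_cand)
            t = t_cand
            j = int(np.searchsorted(np.cumsum(a), rng.random() * a0, side="right"))
            j = min(j, len(a) - 1)
            x += stoich[j]
        else:
            record_until(t_next)
            t = t_next
            if bi < len(boundaries):
                # apply every boundary scheduled at this instant
                while bi < len(boundaries) and boundaries[bi][0] == t:
                    _, op, species, value = boundaries[bi]
                    if op == "add":
                        x[index[species]] += value
                    else:
                        x[index[species]] = value
                    bi += 1
            else:
                break
    samples[si:] = x
    return Trace(
        sample_times=sample_times,
        counts=samples,
        species=[s.name for s in crn.species],
        seed=seed,
        schedule=schedule,
    )


def simulate_ensemble(
    crn: CRN,
    schedule: EventSchedule | None,
    t_end: float,
    seeds: Sequence[int],
    n_samples: int = 1000,
) -> tuple[list[Trace], pd.DataFrame]:
    """Independent runs for each seed plus pointwise mean/sd per species.

    The summary frame has columns ``time`` and ``<species>_mean`` /
    ``<species>_sd`` for every species, on the common sample grid.
    """
    if len(seeds) == 0:
        raise ValueError("need at least one seed")
    traces = [simulate(crn, schedule, t_end, seed, n_samples) for seed in seeds]
    stack = np.stack([tr.counts for tr in traces])  # (n_runs, n_samples, n_species)
    mean = stack.mean(axis=0)
    sd = stack.std(axis=0, ddof=0)
    summary = pd.DataFrame({"time": traces[0].sample_times})
    for i, name in enumerate(traces[0].species):
        summary[f"{name}_mean"] = mean[:, i]
        summary[f"{name}_sd"] = sd[:, i]
    return traces, summary


def ensemble_summary_csv(summary: pd.DataFrame, path) -> None:
    summary.to_csv(path, index=False)
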