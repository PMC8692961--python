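"""State detection and transition-correctness scoring.

A compiled automaton is "in" a state when that state's species dominates:
its count, averaged over the middle 50% of sample points between two input
presentations, strictly exceeds 80% of the total number of state molecules
(both fractions configurable).  A presentation's transition is correct when
the detected state in the following inter-presentation window equals the
state prescribed by the automaton's transition function on the input prefix
so far; correctness of a run is successes/attempts, and the rate-sweep
harness pools attempts over replicates per parameter cell.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from typing import Sequence

import numpy as np
import pandas as pd

from .automata import FSA
from .compiler import RateConfig, compile_for_consumable_inputs
from .simulate import EventSchedule, SpikeEvent, Trace, simulate

__all__ = [
    "DetectionConfig",
    "CorrectnessReport",
    "SweepGrid",
    "detect_state",
    "score_transitions",
    "run_sweep",
    "sweep_heatmap",
]


@dataclass(frozen=True)
class DetectionConfig:
    """Parameters of the dominance-detection rule.

    ``dominance_threshold`` must exceed 0.5 so at most one state can ever be
    detected (windowed averages sum to at most the molecule total).
    ``window`` is the centred fraction of each inter-presentation interval
    that is averaged; 0.5 keeps the middle 50% of sample points.
    """

    dominance_threshold: float = 0.8
    window: float = 0.5

    def __post_init__(self) -> None:
        if not 0.5 < self.dominance_threshold <= 1.0:
            raise ValueError("dominance_threshold must lie in (0.5, 1]")
        if not 0.0 < self.window <= 1.0:
            raise ValueError("window must lie in (0, 1]")


@dataclass
class CorrectnessReport:
    """Per-presentation transition outcomes for one trace.

    ``rows`` holds (expected state, detected state or None, success flag)
    per presentation, in order.
    """

    rows: list[tuple[str, str | None, bool]]

    @property
    def n_attempted(self) -> int:
        return len(self.rows)

    @property
    def n_successful(self) -> int:
        return sum(1 for _, _, ok in self.rows if ok)

    @property
    def fraction_correct(self) -> float:
        if not self.rows:
            raise ValueError("no transitions attempted")
        return self.n_successful / self.n_attempted


def detect_state(
    trace: Trace,
    interval: tuple[float, float],
    config: DetectionConfig = DetectionConfig(),
    state_species: Sequence[str] | None = None,
    total: int | None = None,
) -> str | None:
    """Dominant state over the middle window of ``interval``, or ``None``.

    With window fraction w, samples with time in
    ``[t_a + (1-w)/2 * d, t_a + (1+w)/2 * d)`` (d = t_b - t_a) are averaged
    per state species; the unique species whose average strictly exceeds
    ``dominance_threshold * total`` is returned.
    """
    t_a, t_b = interval
    if not t_a < t_b:
        raise ValueError("interval must satisfy t_a < t_b")
    if state_species is None:
        state_species = trace.species
    lo = t_a + (1.0 - config.window) / 2.0 * (t_b - t_a)
    hi = t_a + (1.0 + config.window) / 2.0 * (t_b - t_a)
    mask = (trace.sample_times >= lo) & (trace.sample_times < hi)
    if not mask.any():
        raise ValueError(
            "no sample points fall in the detection window "
            f"[{lo:g}, {hi:g}); increase n_samples"
        )
    averages = {s: float(trace.series(s)[mask].mean()) for s in state_species}
    if total is None:
        total = int(round(sum(averages.values())))
    for species, avg in averages.items():
        if avg > config.dominance_threshold * total:
            return species
    return None


def score_transitions(
    trace: Trace,
    fsa: FSA,
    schedule: EventSchedule | None = None,
    config: DetectionConfig = DetectionConfig(),
) -> CorrectnessReport:
    """Score every input presentation of ``schedule`` against DFA semantics.

    The expected state after the k-th presentation is the DFA state reached
    on the first k symbols from the start state, independent of earlier
    detection outcomes.  Detection windows run from each presentation time
    to the next (the last one ends at the end of the trace); a ``None``
    detection counts as a failed attempt.
    """
    schedule = schedule or trace.schedule
    if not schedule.presentations:
        raise ValueError("schedule has no input presentations to score")
    t_end = float(trace.sample_times[-1])
    times = schedule.presentation_times + [t_end]
    state_species = [q for q in fsa.states if q in trace.species]
    total = int(trace.counts[0, [trace.species.index(s) for s in state_species]].sum())
    rows: list[tuple[str, str | None, bool]] = []
    state = fsa.start
    for k, (t_a, symbol) in enumerate(schedule.presentations):
        state = fsa.step(state, symbol)
        detected = detect_state(
            trace, (t_a, times[k + 1]), config, state_species, total
        )
        rows.append((state, detected, detected == state))
    return CorrectnessReport(rows)


# ---------------------------------------------------------------------------
# Rate-parameter sweep
# ---------------------------------------------------------------------------


@dataclass
class SweepGrid:
    """Axes of a rate-characterisation sweep over n-state cycle machines."""

    k_input_values: Sequence[float]
    k_flip_values: Sequence[float]
    n_input_values: Sequence[int] = (128,)
    cycle_lengths: Sequence[int] = (3,)
    replicates: int = 5
    presentations: int = 10
    spacing: float = 0.25

    def __post_init__(self) -> None:
        for axis in (self.k_input_values, self.k_flip_values, self.n_input_values):
            if any(v <= 0 for v in axis):
                raise ValueError("sweep axis values must be positive")


def cycle_spike_schedule(
    n_presentations: int, spacing: float, amount: int, symbol: str = "Input0"
) -> EventSchedule:
    """Evenly spaced consumable-input spikes starting one spacing in."""
    times = [spacing * (k + 1) for k in range(n_presentations)]
    return EventSchedule(
        spikes=[SpikeEvent(t, symbol, amount) for t in times],
        presentations=[(t, symbol) for t in times],
    )


def run_sweep(
    grid: SweepGrid,
    rates_base: RateConfig = RateConfig(),
    n_state_molecules: int = 100,
    seed0: int = 0,
    config: DetectionConfig = DetectionConfig(),
    n_samples: int | None = None,
) -> pd.DataFrame:
    """Pooled transition correctness per (cycle, N_input, k_input, k_flip) cell.

    Each replicate run presents ``grid.presentations`` evenly spaced spikes
    to a freshly compiled consumable cycle CRN; successes are pooled over
    replicates.  Returns a long-format frame with one row per replicate and
    columns cycle_length, n_input, k_input, k_flip, replicate, attempted,
    successful, fraction.  Per-cell seeds derive deterministically from
    ``seed0``, the cell index and the replicate index.
    """
    from .automata import build_cycle_fsa

    if n_samples is None:
        # >= 200 samples per inter-presentation interval keeps detection stable
        n_samples = 200 * (grid.presentations + 1)
    records = []
    cells = list(
        product(
            grid.cycle_lengths,
            grid.n_input_values,
            grid.k_input_values,
            grid.k_flip_values,
        )
    )
    for cell_index, (n_states, n_input, k_input, k_flip) in enumerate(cells):
        fsa = build_cycle_fsa(n_states)
        rates = RateConfig(
            k_am=rates_base.k_am,
            k_input=k_input,
            k_flip=k_flip,
            k_flip_decay=rates_base.k_flip_decay,
            k_buf_plus=rates_base.k_buf_plus,
            k_buf_minus=rates_base.k_buf_minus,
            k_cat=rates_base.k_cat,
        )
        crn = compile_for_consumable_inputs(fsa, rates, n_state_molecules)
        schedule = cycle_spike_schedule(grid.presentations, grid.spacing, n_input)
        t_end = grid.spacing * (grid.presentations + 1)
        for replicate in range(grid.replicates):
            seed = seed0 + 10_000 * cell_index + replicate
            try:
                trace = simulate(crn, schedule, t_end, seed, n_samples)
                rep = score_transitions(trace, fsa, schedule, config)
                attempted, successful = rep.n_attempted, rep.n_successful
                error = ""
            except Exception as exc:  # failed cells recorded, not fatal
                attempted = successful = 0
                error = str(exc)
            records.append(
                {
                    "cycle_length": n_states,
                    "n_input": n_input,
                    "k_input": k_input,
                    "k_flip": k_flip,
                    "replicate": replicate,
                    "seed": seed,
                    "attempted": attempted,
                    "successful": successful,
                    "fraction": successful / attempted if attempted else np.nan,
                    "error": error,
                }
            )
    return pd.DataFrame.from_records(records)


def pooled_fractions(sweep: pd.DataFrame) -> pd.DataFrame:
    """Pool replicate successes per cell: fraction = sum(successful)/sum(attempted)."""
    grouped = (
        sweep.groupby(["cycle_length", "n_input", "k_input", "k_flip"])[
            ["attempted", "successful"]
        ]
        .sum()
        .reset_index()
    )
    grouped["fraction"] = grouped["successful"] / grouped["attempted"]
    return grouped


def sweep_heatmap(sweep: pd.DataFrame, cycle_length: int, n_input: int, path) -> None:
    """Greyscale heatmap (white = 1.0, black = 0.0) on log-scaled rate axes."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    pooled = pooled_fractions(sweep)
    sub = pooled[
        (pooled.cycle_length == cycle_length) & (pooled.n_input == n_input)
    ]
    pivot = sub.pivot(index="k_input", columns="k_flip", values="fraction")
    fig, ax = plt.subplots(figsize=(4, 3.2))
    mesh = ax.pcolormesh(
        pivot.columns.to_numpy(),
        pivot.index.to_numpy(),
        pivot.to_numpy(),
        cmap="gray",
        vmin=0.0,
        vmax=1.0,
        shading="nearest",
    )
    ax.set_xscale("log")
    ax.set_yscale("log")
    ax.set_xlabel("k_flip")
    ax.set_ylabel("k_input")
    ax.set_title(f"cycle={cycle_length}, N_input={n_input}")
    fig.colorbar(mesh, ax=ax, label="fraction correct")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
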