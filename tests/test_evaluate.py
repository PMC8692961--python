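"""Detection rule, correctness scoring, and the sweep harness."""

import numpy as np
import pytest

from chemfsa.automata import build_cycle_fsa
from chemfsa.evaluate import (
    CorrectnessReport,
    DetectionConfig,
    SweepGrid,
    cycle_spike_schedule,
    detect_state,
    pooled_fractions,
    run_sweep,
    score_transitions,
)
from chemfsa.simulate import EventSchedule, Trace


def make_trace(species, rows, t_end=1.0, presentations=()):
    """Hand-built trace: ``rows`` is a list of (fraction_of_t_end, counts)."""
    times = np.linspace(0.0, t_end, 200)
    counts = np.zeros((len(times), len(species)), dtype=np.int64)
    for frac, values in rows:
        counts[times >= frac * t_end] = values
    schedule = EventSchedule(presentations=list(presentations))
    return Trace(times, counts, list(species), seed=0, schedule=schedule)


STATES = ["S0", "S1", "S2"]


def test_detect_constant_dominant_state():
    trace = make_trace(STATES, [(0.0, [0, 100, 0])])
    assert detect_state(trace, (0.0, 1.0), state_species=STATES, total=100) == "S1"


def test_detect_dominance_is_strict_at_80_percent():
    above = make_trace(STATES, [(0.0, [19, 81, 0])])
    exactly = make_trace(STATES, [(0.0, [20, 80, 0])])
    assert detect_state(above, (0.0, 1.0), state_species=STATES, total=100) == "S1"
    assert detect_state(exactly, (0.0, 1.0), state_species=STATES, total=100) is None


def test_detect_even_split_is_undecided():
    trace = make_trace(STATES, [(0.0, [50, 50, 0])])
    assert detect_state(trace, (0.0, 1.0), state_species=STATES, total=100) is None


def test_detect_uses_middle_window_only():
    # dominant only inside [0.25, 0.75): outer quarters are a different state
    trace = make_trace(
        STATES, [(0.0, [100, 0, 0]), (0.25, [0, 100, 0]), (0.75, [100, 0, 0])]
    )
    assert detect_state(trace, (0.0, 1.0), state_species=STATES, total=100) == "S1"


def test_detect_at_most_one_state_for_any_threshold_above_half():
    rng = np.random.default_rng(0)
    for _ in range(20):
        split = rng.multinomial(100, [1 / 3] * 3)
        trace = make_trace(STATES, [(0.0, split)])
        config = DetectionConfig(dominance_threshold=0.51)
        found = [
            s
            for s in STATES
            if detect_state(trace, (0.0, 1.0), config, [s], 100) == s
        ]
        assert len(found) <= 1


def test_detect_empty_window_instructs_larger_n_samples():
    trace = make_trace(STATES, [(0.0, [100, 0, 0])])
    with pytest.raises(ValueError, match="n_samples"):
        detect_state(trace, (0.5, 0.501), state_species=STATES, total=100)


def test_score_all_windows_correct_is_one():
    fsa = build_cycle_fsa(3)
    trace = make_trace(
        STATES,
        [(0.0, [100, 0, 0]), (0.25, [0, 100, 0]), (0.65, [0, 0, 100])],
        presentations=[(0.25, "Input0"), (0.65, "Input0")],
    )
    report = score_transitions(trace, fsa)
    assert report.rows == [("S1", "S1", True), ("S2", "S2", True)]
    assert report.fraction_correct == 1.0


def test_score_half_wrong_is_half():
    fsa = build_cycle_fsa(3)
    # second window stays in S1 instead of advancing to S2
    trace = make_trace(
        STATES,
        [(0.0, [100, 0, 0]), (0.25, [0, 100, 0])],
        presentations=[(0.25, "Input0"), (0.65, "Input0")],
    )
    report = score_transitions(trace, fsa)
    assert report.fraction_correct == 0.5
    assert report.rows[1] == ("S2", "S1", False)


def test_fraction_correct_definition():
    report = CorrectnessReport(
        [("S1", "S1", True), ("S2", None, False), ("S0", "S0", True)]
    )
    assert report.n_attempted == 3
    assert report.n_successful == 2
    assert report.fraction_correct == pytest.approx(2 / 3)


def test_scoring_requires_presentations(three_cycle_crn):
    from chemfsa.simulate import simulate

    trace = simulate(three_cycle_crn, None, 1.0, 0, 100)
    with pytest.raises(ValueError, match="presentations"):
        score_transitions(trace, build_cycle_fsa(3))


# -- integration with the simulator ---------------------------------------


def test_fraction_stable_under_sampling_density(three_cycle_crn):
    from chemfsa.simulate import simulate

    fsa = build_cycle_fsa(3)
    schedule = cycle_spike_schedule(10, 0.25, 128)
    fractions = []
    for n_samples in (2200, 4400):
        trace = simulate(three_cycle_crn, schedule, 2.75, seed=17, n_samples=n_samples)
        fractions.append(score_transitions(trace, fsa, schedule).fraction_correct)
    assert fractions[0] == fractions[1]


def test_subthreshold_input_scores_no_better_than_suprathreshold():
    grid = SweepGrid(
        k_input_values=[100.0],
        k_flip_values=[10.0],
        n_input_values=[40, 128],
        cycle_lengths=[3],
        replicates=5,
    )
    pooled = pooled_fractions(run_sweep(grid, seed0=5))
    low = pooled[pooled.n_input == 40].fraction.item()
    high = pooled[pooled.n_input == 128].fraction.item()
    assert low <= high


def test_sweep_output_shape_and_metadata():
    grid = SweepGrid(
        k_input_values=[1.0, 100.0],
        k_flip_values=[1.0, 10.0, 100.0],
        replicates=2,
        presentations=3,
    )
    sweep = run_sweep(grid, seed0=1)
    assert len(sweep) == 2 * 3 * 2
    assert set(sweep.columns) >= {
        "cycle_length", "n_input", "k_input", "k_flip",
        "replicate", "seed", "attempted", "successful", "fraction",
    }
    assert (sweep.attempted == 3).all()
    assert sweep.seed.is_unique
    # rerun with the same seed0 reproduces the table exactly
    again = run_sweep(grid, seed0=1)
    assert sweep.equals(again)


def test_sweep_heatmap_writes_png(tmp_path):
    from chemfsa.evaluate import sweep_heatmap

    grid = SweepGrid(
        k_input_values=[1.0, 100.0],
        k_flip_values=[1.0, 10.0],
        replicates=1,
        presentations=2,
    )
    sweep = run_sweep(grid, seed0=3)
    out = tmp_path / "heatmap.png"
    sweep_heatmap(sweep, cycle_length=3, n_input=128, path=out)
    assert out.stat().st_size > 0
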