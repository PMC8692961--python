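"""Compiler module emission: reaction counts, species inventory, invariants.

Closed-form expectations for a total DFA with n states, |delta| = n*|Sigma|
entries and P distinct (source, target) pairs:

* AM module: C(n,2) blanking + n recruitment reactions;
* transitions: 3 reactions per delta entry (mapping, transition, decay);
* consumable species: n states + undecided + P flips + |Sigma| inputs;
* catalytic adds 3 reactions and 2 species per symbol.
"""

from math import comb

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chemfsa.automata import FSA, build_cycle_fsa
from chemfsa.compiler import (
    UNDECIDED,
    RateConfig,
    compile_am,
    compile_for_catalytic_inputs,
    compile_for_consumable_inputs,
    compile_transitions,
    compile_without_flips,
    flip_name,
    report,
)
from chemfsa.experiments import generate_random_dfa


def distinct_pairs(fsa):
    """Brute-force enumeration of (source, target) pairs over the full table."""
    return {(q, fsa.delta[(q, a)]) for q in fsa.states for a in fsa.alphabet}


# -- AM module -------------------------------------------------------------


@pytest.mark.parametrize("n, expected", [(2, 3), (3, 6), (11, 66)])
def test_am_reaction_count(n, expected):
    reactions = compile_am([f"S{i}" for i in range(n)], 1.0)
    assert len(reactions) == expected == comb(n, 2) + n


def test_am_reaction_shapes():
    reactions = compile_am(["S0", "S1", "S2"], 2.0)
    blanking = [r for r in reactions if r.products == (UNDECIDED, UNDECIDED)]
    recruit = [r for r in reactions if UNDECIDED in r.reactants]
    assert len(blanking) == 3 and len(recruit) == 3
    for r in recruit:  # S_i + B -> S_i + S_i
        (state,) = set(r.reactants) - {UNDECIDED}
        assert r.products == (state, state)
    assert all(r.rate_constant == 2.0 for r in reactions)


def test_am_rejects_single_state():
    with pytest.raises(ValueError):
        compile_am(["S0"], 1.0)


# -- transition modules ----------------------------------------------------


def test_three_cycle_transitions(three_cycle_fsa):
    reactions = compile_transitions(three_cycle_fsa, RateConfig())
    assert len(reactions) == 9
    flips = {s for r in reactions for s in (*r.reactants, *r.products) if s.startswith("Flip")}
    assert len(flips) == 3


def test_sqrt_transitions_shared_flip_species(sqrt_fsa):
    reactions = compile_transitions(sqrt_fsa, RateConfig())
    assert len(reactions) == 3 * 33
    flips = {s for r in reactions for s in (*r.reactants, *r.products) if s.startswith("Flip")}
    assert len(flips) == 29  # pair-keyed: shared across symbols, self-pairs included
    assert len(distinct_pairs(sqrt_fsa)) == 29


def test_self_loop_compiles_to_real_flip_machinery():
    fsa = FSA(states=("S0", "S1"), alphabet=("a",),
              delta={("S0", "a"): "S0", ("S1", "a"): "S0"}, start="S0")
    reactions = compile_transitions(fsa, RateConfig())
    assert len(reactions) == 6
    assert flip_name("S0", "S0") in {s for r in reactions for s in r.products}


def test_transitions_reject_partial_fsa():
    partial = FSA(states=("S0", "S1"), alphabet=("a",),
                  delta={("S0", "a"): "S1"}, start="S0")
    with pytest.raises(ValueError):
        compile_transitions(partial, RateConfig())


# -- whole-network compilation --------------------------------------------


def test_consumable_three_cycle_counts(three_cycle_crn):
    rep = report(three_cycle_crn)
    assert (rep.n_species, rep.n_reactions) == (8, 15)
    assert rep.per_module["approximate_majority"] == 6


def test_consumable_sqrt_counts(sqrt_fsa):
    rep = report(compile_for_consumable_inputs(sqrt_fsa))
    assert (rep.n_species, rep.n_reactions) == (44, 165)


def test_catalytic_three_cycle_counts(three_cycle_fsa):
    rep = report(compile_for_catalytic_inputs(three_cycle_fsa))
    assert (rep.n_species, rep.n_reactions) == (10, 18)


def test_noflip_three_cycle_counts(three_cycle_fsa):
    rep = report(compile_without_flips(three_cycle_fsa))
    assert (rep.n_species, rep.n_reactions) == (5, 9)
    assert rep.per_module["direct_transition"] == 3


def test_noflip_sqrt_reaction_count(sqrt_fsa):
    assert report(compile_without_flips(sqrt_fsa)).n_reactions == 66 + 33


def test_initial_state_holds_all_state_molecules(three_cycle_crn):
    counts = three_cycle_crn.initial_counts
    assert counts["S0"] == 100
    assert all(counts[s] == 0 for s in counts if s != "S0")


def test_buffered_inputs_start_at_steady_state(three_cycle_fsa):
    crn = compile_for_catalytic_inputs(three_cycle_fsa, RateConfig())
    assert crn.initial_counts["Input0_buf"] == 100  # round(k_buf+/k_buf-)


def test_catalytic_rejects_zero_degradation(three_cycle_fsa):
    rates = RateConfig(k_buf_minus=0.0)
    with pytest.raises(ValueError, match="steady state"):
        compile_for_catalytic_inputs(three_cycle_fsa, rates)


def test_report_on_empty_crn():
    from chemfsa.crn import CRN

    rep = report(CRN())
    assert (rep.n_species, rep.n_reactions) == (0, 0)


# -- property-based count formulas and structural invariants ---------------


@settings(max_examples=50, deadline=None, derandomize=True)
@given(
    n_states=st.integers(2, 8),
    n_symbols=st.integers(1, 3),
    seed=st.integers(0, 2**20),
)
def test_count_formulas_on_random_dfas(n_states, n_symbols, seed):
    fsa = generate_random_dfa(n_states, n_symbols, seed)
    n, n_delta = n_states, n_states * n_symbols
    pairs = len(distinct_pairs(fsa))

    cons = compile_for_consumable_inputs(fsa, RateConfig(), 50)
    assert len(cons.reactions) == comb(n, 2) + n + 3 * n_delta
    assert len(cons.species) == n + 1 + pairs + n_symbols

    cat = compile_for_catalytic_inputs(fsa, RateConfig(), 50)
    assert len(cat.reactions) == len(cons.reactions) + 3 * n_symbols
    assert len(cat.species) == len(cons.species) + 2 * n_symbols

    assert cat.validate() == []
    state_like = {q for q in fsa.states} | {UNDECIDED}
    for rxn in cat.reactions:
        assert len(rxn.reactants) <= 2 and len(rxn.products) <= 2
        # state + undecided molecule conservation, reaction by reaction
        balance = sum(s in state_like for s in rxn.products) - sum(
            s in state_like for s in rxn.reactants
        )
        assert balance == 0


def test_am_reaction_count_is_quadratic():
    counts = [len(compile_am([f"S{i}" for i in range(n)], 1.0)) for n in (5, 10, 20)]
    assert counts == [comb(n, 2) + n for n in (5, 10, 20)]
    # doubling n roughly quadruples the pairwise term
    assert counts[2] / counts[1] > 3
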