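"""Shared fixtures and independent brute-force oracles for the suite."""

from __future__ import annotations

import itertools

import pytest

from gemcurate import apply_medium, generate_fixture
from gemcurate.fba import FBAProblem, VIABILITY_ABS_TOL, reference_biomass
from gemcurate.fixtures import FixtureSpec, motif_fixtures


@pytest.fixture(scope="session")
def basic_fixture():
    return generate_fixture(FixtureSpec(seed=11))


@pytest.fixture(scope="session")
def basic_model(basic_fixture):
    return apply_medium(basic_fixture.model, basic_fixture.medium)


@pytest.fixture(scope="session")
def motifs():
    return motif_fixtures()


# ---------------------------------------------------------------------------
# independent oracles (plain FBA loops, no pruning, no MILP)
# ---------------------------------------------------------------------------

def brute_force_essentials(model, threshold=0.01):
    """Unpruned per-gene FBA loop."""
    problem = FBAProblem(model)
    ref = reference_biomass(problem)
    cutoff = threshold * ref - VIABILITY_ABS_TOL
    out = set()
    for g in sorted(model.genes - model.background_deletions):
        state = problem.solve(frozenset((g,)))
        b = state.objective if state.status == "optimal" else 0.0
        if b < cutoff:
            out.add(g)
    return frozenset(out)


def brute_force_sl_pairs(model, threshold=0.01):
    """Unpruned all-pairs FBA loop over individually viable genes."""
    problem = FBAProblem(model)
    ref = reference_biomass(problem)
    cutoff = threshold * ref - VIABILITY_ABS_TOL

    def biomass(dels):
        state = problem.solve(frozenset(dels))
        return state.objective if state.status == "optimal" else 0.0

    genes = sorted(model.genes - model.background_deletions)
    viable = [g for g in genes if biomass({g}) >= cutoff]
    pairs = set()
    for a, b in itertools.combinations(viable, 2):
        if biomass({a, b}) < cutoff:
            pairs.add(frozenset((a, b)))
    return frozenset(pairs)


def brute_force_restorations(model, deletions, pool, max_additions, threshold=0.01):
    """Minimal addition subsets by direct subset enumeration + FBA."""
    from gemcurate.restore import apply_candidates

    problem = FBAProblem(model)
    ref = reference_biomass(problem)
    cutoff = threshold * ref - VIABILITY_ABS_TOL
    dels = frozenset(deletions)
    base = problem.solve(dels)
    if base.status == "optimal" and base.objective >= cutoff:
        return {frozenset()}
    found = set()
    for card in range(1, max_additions + 1):
        for combo in itertools.combinations(pool.candidates, card):
            if any(prev <= frozenset(c.id for c in combo) for prev in found):
                continue
            edited = apply_candidates(model, combo)
            state = FBAProblem(edited).solve(dels)
            b = state.objective if state.status == "optimal" else 0.0
            if b >= cutoff:
                found.add(frozenset(c.id for c in combo))
        if found:
            break
    return found
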