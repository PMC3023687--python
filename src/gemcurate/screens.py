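"""Exhaustive deletion screens: single-gene/-reaction essentiality and
synthetic-lethal pair enumeration.

A gene is essential when its single deletion drops the biomass optimum
below the viability threshold; a synthetic-lethal (SL) pair is two
individually viable genes whose joint deletion is lethal.  The pair
screen prunes only in ways proven neutral: genes absent from every GPR
cannot change the feasible set, and a pair whose inactivated-reaction
set equals that of one member alone inherits that member's (viable)
verdict.  Mutants with identical inactivated-reaction sets share one LP.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping

from .fba import FBAProblem, VIABILITY_FRACTION, VIABILITY_ABS_TOL, reference_biomass
from .model import MetabolicModel

__all__ = ["ScreenResult", "SLPairSet", "essential_genes", "essential_reactions", "find_sl_pairs"]


@dataclass(frozen=True)
class ScreenResult:
    medium: str
    essential_genes: frozenset[str]
    essential_reactions: frozenset[str]
    viable_genes: frozenset[str]
    biomass: Mapping[str, float]
    reference_biomass: float = 0.0


@dataclass(frozen=True)
class SLPairSet:
    medium: str
    pairs: frozenset[frozenset[str]]
    biomass: Mapping[frozenset, float] = field(default_factory=dict)

    def __contains__(self, pair) -> bool:
        return frozenset(pair) in self.pairs


class _Screener:
    """Shared machinery: one FBAProblem, one reference, an LP cache
    keyed on the set of force-disabled reactions."""

    def __init__(self, model: MetabolicModel, threshold_fraction: float):
        self.problem = FBAProblem(model)
        self.model = model
        self.reference = reference_biomass(self.problem)
        self.cutoff = threshold_fraction * self.reference - VIABILITY_ABS_TOL
        self._cache: dict[frozenset[int], float] = {}

    def biomass_for(self, deletions: frozenset[str]) -> float:
        dels = deletions | self.model.background_deletions
        inactive = self.problem.inactive_reactions(dels)
        if inactive in self._cache:
            return self._cache[inactive]
        state = self.problem.solve(dels)
        value = state.objective if state.status == "optimal" else 0.0
        self._cache[inactive] = value
        return value

    def viable(self, deletions: frozenset[str]) -> bool:
        return self.biomass_for(deletions) >= self.cutoff


def essential_genes(
    model: MetabolicModel,
    medium_name: str = "",
    threshold_fraction: float = VIABILITY_FRACTION,
    include_background: bool = False,
) -> ScreenResult:
    """Single-gene deletion screen over every model gene.

    Background-deletion genes are already absent from the strain and
    are skipped unless ``include_background``.
    """
    sc = _Screener(model, threshold_fraction)
    genes = sorted(model.genes if include_background else model.genes - model.background_deletions)
    biomass: dict[str, float] = {}
    ess, via = set(), set()
    for g in genes:
        b = sc.biomass_for(frozenset((g,)))
        biomass[g] = b
        (via if b >= sc.cutoff else ess).add(g)
    return ScreenResult(
        medium=medium_name,
        essential_genes=frozenset(ess),
        essential_reactions=frozenset(),
        viable_genes=frozenset(via),
        biomass=biomass,
        reference_biomass=sc.reference,
    )


def essential_reactions(
    model: MetabolicModel,
    medium_name: str = "",
    threshold_fraction: float = VIABILITY_FRACTION,
) -> ScreenResult:
    """Single-reaction knockout screen (bounds clamped to zero)."""
    sc = _Screener(model, threshold_fraction)
    biomass: dict[str, float] = {}
    ess = set()
    for r in model.reactions:
        state = sc.problem.solve(disabled_reactions=[r.id])
        b = state.objective if state.status == "optimal" else 0.0
        biomass[r.id] = b
        if b < sc.cutoff:
            ess.add(r.id)
    return ScreenResult(
        medium=medium_name,
        essential_genes=frozenset(),
        essential_reactions=frozenset(ess),
        viable_genes=frozenset(),
        biomass=biomass,
        reference_biomass=sc.reference,
    )


def find_sl_pairs(
    model: MetabolicModel,
    medium_name: str = "",
    threshold_fraction: float = VIABILITY_FRACTION,
    strategy: str = "exhaustive",
    prune: bool = True,
    single_screen: ScreenResult | None = None,
    include_background: bool = False,
) -> SLPairSet:
    """Enumerate all synthetic-lethal pairs among individually viable genes.

    ``strategy`` is kept for interface stability; exhaustive
    enumeration (with neutral pruning) is the reference implementation.
    """
    if strategy not in ("exhaustive", "bilevel"):
        raise ValueError(f"unknown SL strategy {strategy!r}")
    sc = _Screener(model, threshold_fraction)
    if single_screen is None:
        single_screen = essential_genes(
            model, medium_name, threshold_fraction, include_background=include_background
        )
    candidates = sorted(single_screen.viable_genes)
    pairs: set[frozenset[str]] = set()
    biomass: dict[frozenset, float] = {}
    bg = model.background_deletions
    inact_single = {
        g: sc.problem.inactive_reactions(frozenset((g,)) | bg) for g in candidates
    }
    for a, b in itertools.combinations(candidates, 2):
        pair = frozenset((a, b))
        if prune:
            inact_pair = sc.problem.inactive_reactions(pair | bg)
            # the pair disables nothing beyond one member alone -> viable
            if inact_pair == inact_single[a] or inact_pair == inact_single[b]:
                continue
        value = sc.biomass_for(pair)
        if value < sc.cutoff:
            pairs.add(pair)
            biomass[pair] = value
    return SLPairSet(medium=medium_name, pairs=frozenset(pairs), biomass=biomass)
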