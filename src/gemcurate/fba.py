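"""Flux balance analysis and viability calls.

FBA maximizes the biomass flux v_biomass subject to steady-state mass
balance (S v = 0) and flux bounds; gene deletions act through the GPR
rules: a reaction whose GPR evaluates inactive under the deletion set
has its bounds clamped to [0, 0].  A mutant is called viable (G) when
its maximal biomass reaches at least 1% of the wild-type optimum —
the standard viability threshold for in-silico lethality calls.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
from scipy import sparse

from ._solver import LPResult, solve_lp
from .model import MetabolicModel, ModelValidationError

__all__ = [
    "FluxState",
    "ViabilityCall",
    "FBAProblem",
    "max_biomass",
    "is_viable",
    "VIABILITY_FRACTION",
    "VIABILITY_ABS_TOL",
]

#: viability threshold as a fraction of the wild-type biomass optimum
VIABILITY_FRACTION = 0.01
#: absolute tolerance guarding the strict-< threshold comparison
VIABILITY_ABS_TOL = 1e-6


@dataclass(frozen=True)
class FluxState:
    status: str  # optimal | infeasible | unbounded
    objective: float | None
    fluxes: Mapping[str, float] | None


@dataclass(frozen=True)
class ViabilityCall:
    mutant_biomass: float
    reference_biomass: float
    threshold_fraction: float
    verdict: str  # "G" or "NG"

    @property
    def viable(self) -> bool:
        return self.verdict == "G"


class FBAProblem:
    """A model prepared for repeated FBA under varying deletions.

    Builds the sparse stoichiometric matrix once; each solve only
    re-derives the bound vector.  Reactions are ordered by their
    position in the model (stable), metabolites likewise, so repeated
    runs are bit-reproducible.
    """

    def __init__(self, model: MetabolicModel):
        if model.biomass_reaction_id is None:
            raise ModelValidationError("FBA requires a designated biomass reaction")
        self.model = model
        self.rxn_ids = [r.id for r in model.reactions]
        self.rxn_pos = {rid: i for i, rid in enumerate(self.rxn_ids)}
        met_ids = [m.id for m in model.metabolites]
        met_pos = {mid: i for i, mid in enumerate(met_ids)}
        rows, cols, vals = [], [], []
        for j, r in enumerate(model.reactions):
            for mid, coeff in r.stoichiometry.items():
                rows.append(met_pos[mid])
                cols.append(j)
                vals.append(coeff)
        self.s_matrix = sparse.csr_matrix(
            (vals, (rows, cols)), shape=(len(met_ids), len(self.rxn_ids))
        )
        self.base_bounds = [(r.lower_bound, r.upper_bound) for r in model.reactions]
        self.c = np.zeros(len(self.rxn_ids))
        self.c[self.rxn_pos[model.biomass_reaction_id]] = 1.0
        # genes -> reactions they may inactivate (GPR mentions them)
        self._gene_rxns: dict[str, list[int]] = {}
        for j, r in enumerate(model.reactions):
            for g in r.gpr.genes():
                self._gene_rxns.setdefault(g, []).append(j)

    def inactive_reactions(self, deletions: frozenset[str]) -> frozenset[int]:
        """Indices of reactions whose GPR evaluates inactive."""
        affected: set[int] = set()
        for g in deletions:
            affected.update(self._gene_rxns.get(g, ()))
        return frozenset(
            j for j in affected if not self.model.reactions[j].gpr.evaluate(deletions)
        )

    def solve(
        self,
        deletions: Iterable[str] = (),
        disabled_reactions: Iterable[str] = (),
        extra_bounds: Mapping[str, tuple[float, float]] | None = None,
        want_fluxes: bool = False,
    ) -> FluxState:
        dels = frozenset(deletions) | self.model.background_deletions
        bounds = list(self.base_bounds)
        for j in self.inactive_reactions(dels):
            bounds[j] = (0.0, 0.0)
        for rid in disabled_reactions:
            bounds[self.rxn_pos[rid]] = (0.0, 0.0)
        if extra_bounds:
            for rid, bd in extra_bounds.items():
                bounds[self.rxn_pos[rid]] = bd
        res: LPResult = solve_lp(
            self.c, self.s_matrix, np.zeros(self.s_matrix.shape[0]), bounds
        )
        if res.status != "optimal":
            return FluxState(res.status, None, None)
        fluxes = (
            {rid: float(res.x[i]) for i, rid in enumerate(self.rxn_ids)}
            if want_fluxes
            else None
        )
        return FluxState("optimal", float(res.objective), fluxes)


def max_biomass(
    model: MetabolicModel,
    deletions: Iterable[str] = (),
    disabled_reactions: Iterable[str] = (),
    want_fluxes: bool = False,
) -> FluxState:
    """Maximize biomass for the (possibly deleted) strain.

    The model is expected to already carry its medium (see
    ``apply_medium``); background deletions recorded there are unioned
    into ``deletions``.
    """
    return FBAProblem(model).solve(
        deletions, disabled_reactions=disabled_reactions, want_fluxes=want_fluxes
    )


def reference_biomass(problem: FBAProblem) -> float:
    """Wild-type (background-only) optimum; errors if not positive."""
    ref = problem.solve()
    if ref.status != "optimal" or ref.objective is None or ref.objective <= 0:
        raise ModelValidationError(
            "wild-type reference biomass is not positive; cannot screen "
            f"(status {ref.status}, objective {ref.objective})"
        )
    return ref.objective


def is_viable(
    model: MetabolicModel,
    deletions: Iterable[str] = (),
    threshold_fraction: float = VIABILITY_FRACTION,
    _problem: FBAProblem | None = None,
    _reference: float | None = None,
) -> ViabilityCall:
    """Viability call at the 1% threshold: NG iff the mutant optimum is
    strictly below threshold_fraction x wild-type (with tolerance)."""
    problem = _problem or FBAProblem(model)
    ref = _reference if _reference is not None else reference_biomass(problem)
    state = problem.solve(deletions)
    mutant = state.objective if state.status == "optimal" else 0.0
    verdict = "NG" if mutant < threshold_fraction * ref - VIABILITY_ABS_TOL else "G"
    return ViabilityCall(mutant, ref, threshold_fraction, verdict)
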