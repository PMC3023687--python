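"""Network gap detection: blocked reactions and problem metabolites.

A reaction is blocked when no feasible flux state gives it nonzero
flux; a metabolite is no-production (no-consumption) when no feasible
state net-produces (net-consumes) it.  Both are characterized directly
by small LP sweeps — flux variability for reactions, and a temporary
sink/source test per metabolite — which is an exactly verifiable
equivalent of the classical MILP gap-finding formulation.  Problem
metabolites are split into roots and downstream casualties: a problem
metabolite is downstream if repairing some other single problem
metabolite (adding a sink or source for it) clears it, and a root
otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse

from ._solver import solve_lp
from .model import GLOBAL_BOUND, MetabolicModel

__all__ = ["GapReport", "find_blocked_reactions", "find_gap_metabolites"]

_FLUX_TOL = 1e-9


@dataclass(frozen=True)
class GapReport:
    blocked_reactions: frozenset[str]
    no_production: frozenset[str]
    no_consumption: frozenset[str]
    root_flags: dict  # metabolite id -> "root" | "downstream"


class _Variability:
    """max/min flux per reaction (and per auxiliary sink) via LPs."""

    def __init__(self, model: MetabolicModel, any_uptake: bool):
        self.model = model
        self.rxn_ids = [r.id for r in model.reactions]
        met_ids = [m.id for m in model.metabolites]
        self.met_pos = {mid: i for i, mid in enumerate(met_ids)}
        rows, cols, vals = [], [], []
        for j, r in enumerate(model.reactions):
            for mid, coeff in r.stoichiometry.items():
                rows.append(self.met_pos[mid])
                cols.append(j)
                vals.append(coeff)
        self.n_mets = len(met_ids)
        self.n_rxns = len(self.rxn_ids)
        self.entries = (rows, cols, vals)
        self.bounds = []
        for r in model.reactions:
            if any_uptake and r.is_exchange:
                self.bounds.append((-GLOBAL_BOUND, GLOBAL_BOUND))
            else:
                self.bounds.append((r.lower_bound, r.upper_bound))

    def _matrix(self, extra_cols: list[dict[str, float]]):
        rows, cols, vals = map(list, self.entries)
        for k, stoich in enumerate(extra_cols):
            for mid, coeff in stoich.items():
                rows.append(self.met_pos[mid])
                cols.append(self.n_rxns + k)
                vals.append(coeff)
        n = self.n_rxns + len(extra_cols)
        return sparse.csr_matrix((vals, (rows, cols)), shape=(self.n_mets, n))

    def extremes(
        self,
        objective_col: int,
        extra_cols: list[dict[str, float]] | None = None,
        extra_bounds: list[tuple[float, float]] | None = None,
    ) -> tuple[float, float]:
        extra_cols = extra_cols or []
        a = self._matrix(extra_cols)
        bounds = self.bounds + (extra_bounds or [])
        c = np.zeros(a.shape[1])
        c[objective_col] = 1.0
        b = np.zeros(self.n_mets)
        hi = solve_lp(c, a, b, bounds, maximize=True)
        lo = solve_lp(c, a, b, bounds, maximize=False)
        hi_v = hi.objective if hi.status == "optimal" else 0.0
        lo_v = lo.objective if lo.status == "optimal" else 0.0
        return lo_v, hi_v


def find_blocked_reactions(
    model: MetabolicModel, medium_scope: str = "fixed_medium"
) -> frozenset[str]:
    """Reactions that cannot carry nonzero flux.

    ``medium_scope='any_uptake'`` opens every exchange in both
    directions first, so only structurally blocked reactions remain.
    """
    if medium_scope not in ("fixed_medium", "any_uptake"):
        raise ValueError(f"unknown medium scope {medium_scope!r}")
    var = _Variability(model, any_uptake=medium_scope == "any_uptake")
    blocked = set()
    for j, rid in enumerate(var.rxn_ids):
        lo, hi = var.extremes(j)
        if abs(lo) <= _FLUX_TOL and abs(hi) <= _FLUX_TOL:
            blocked.add(rid)
    return frozenset(blocked)


def _problem_metabolites(var: _Variability) -> tuple[set[str], set[str]]:
    """Metabolites with no net production / no net consumption, via a
    temporary unit sink (met ->) and source (-> met) per metabolite."""
    no_prod, no_cons = set(), set()
    for m in var.model.metabolites:
        # sink: consumes m; positive flux possible iff m is producible
        _, hi = var.extremes(
            var.n_rxns, extra_cols=[{m.id: -1.0}], extra_bounds=[(0.0, GLOBAL_BOUND)]
        )
        if hi <= _FLUX_TOL:
            no_prod.add(m.id)
        # source: produces m; positive flux possible iff m is consumable
        _, hi = var.extremes(
            var.n_rxns, extra_cols=[{m.id: 1.0}], extra_bounds=[(0.0, GLOBAL_BOUND)]
        )
        if hi <= _FLUX_TOL:
            no_cons.add(m.id)
    return no_prod, no_cons


def _fix_column(met_id: str, kind: str) -> dict[str, float]:
    # repairing a no-consumption metabolite = give it a sink; a
    # no-production metabolite = give it a source
    return {met_id: -1.0} if kind == "no_consumption" else {met_id: 1.0}


def _probe_column(met_id: str, kind: str) -> dict[str, float]:
    # probing consumability = feed the metabolite in (source) and see if
    # it can leave; probing producibility = drain it (sink)
    return {met_id: 1.0} if kind == "no_consumption" else {met_id: -1.0}


def find_gap_metabolites(model: MetabolicModel, any_uptake: bool = True) -> GapReport:
    """Full gap report with root/downstream assignment.

    For each problem metabolite r we add its repair (sink for
    no-consumption, source for no-production) and re-test every other
    problem metabolite; any metabolite cleared by some other single
    repair is downstream, the rest are roots.
    """
    var = _Variability(model, any_uptake=any_uptake)
    no_prod, no_cons = _problem_metabolites(var)
    problems: list[tuple[str, str]] = sorted(
        [(m, "no_consumption") for m in no_cons] + [(m, "no_production") for m in no_prod]
    )
    cleared_by_other: set[tuple[str, str]] = set()
    for r_met, r_kind in problems:
        fix = _fix_column(r_met, r_kind)
        for m_met, m_kind in problems:
            if m_met == r_met:
                continue
            test = _probe_column(m_met, m_kind)
            # with r repaired, can m now be produced/consumed?
            _, hi = var.extremes(
                var.n_rxns + 1,
                extra_cols=[fix, test],
                extra_bounds=[(0.0, GLOBAL_BOUND), (0.0, GLOBAL_BOUND)],
            )
            if hi > _FLUX_TOL:
                cleared_by_other.add((m_met, m_kind))
    root_flags: dict[str, str] = {}
    for m_met, m_kind in problems:
        flag = "downstream" if (m_met, m_kind) in cleared_by_other else "root"
        # a metabolite may be both no-production and no-consumption;
        # keep "root" if either facet is a root
        if root_flags.get(m_met) == "root":
            continue
        root_flags[m_met] = flag
    blocked = find_blocked_reactions(
        model, "any_uptake" if any_uptake else "fixed_medium"
    )
    return GapReport(
        blocked_reactions=blocked,
        no_production=frozenset(no_prod),
        no_consumption=frozenset(no_cons),
        root_flags=root_flags,
    )
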