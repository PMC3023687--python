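"""Minimal suppression sets that turn a falsely viable mutant lethal.

Given a mutant that grows in silico but not in vivo (a GNG or GSL
mismatch), find the smallest set of genes or reactions whose
suppression drives the mutant's maximal biomass below the viability
threshold.  The reaction-level variant is the classical growth-match
suppression search; the gene-level variant works directly on gene
indicator variables w_k coupled to reaction fluxes through
summed-indicator GPR bound rows

    (sum_k w_k) * LB_j  <=  v_j  <=  (sum_k w_k) * UB_j,

one row per CNF clause, so no auxiliary per-reaction binaries are
needed.  The search is the bilevel program

    min_w  [ max_v  v_biomass  s.t.  S v = 0, GPR bound rows, bounds ]
    s.t.   sum_k (1 - w_k) <= n,  w binary,

solved as a single-level MILP by dualizing the inner LP; products of
w with inner duals are linearized exactly via big-M, with dual
variables bounded by a cap that is checked post hoc.  Every reported
solution is re-verified by a direct FBA with the suppressions applied
(a strong-duality consistency check).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable
import itertools
import warnings

import numpy as np
from scipy import sparse

from ._solver import solve_milp
from .fba import FBAProblem, VIABILITY_ABS_TOL, VIABILITY_FRACTION, reference_biomass
from .gpr import CNFCapacityError, fictitious_gene, to_cnf, FICTITIOUS_PREFIX
from .model import MetabolicModel

__all__ = [
    "SuppressionProblem",
    "SuppressionSolution",
    "min_gene_suppressions",
    "min_reaction_suppressions",
    "enumerate_alternatives",
    "exhaustive_suppressions",
    "DUAL_CAP",
]

#: bound on inner dual variables used to linearize w x dual products
DUAL_CAP = 1e4
_DUALITY_TOL = 1e-6


@dataclass(frozen=True)
class SuppressionProblem:
    model: MetabolicModel
    deletions: frozenset[str]
    level: str  # "gene" | "reaction"
    n: int
    threshold_fraction: float = VIABILITY_FRACTION
    exclude: frozenset[str] = frozenset()
    #: drop candidates whose lone suppression already kills the wild type;
    #: those can never yield a global modification
    filter_wt_essential: bool = True

    def __post_init__(self):
        if self.level not in ("gene", "reaction"):
            raise ValueError(f"level must be 'gene' or 'reaction', got {self.level!r}")
        if self.n < 1:
            raise ValueError("n must be at least 1")


@dataclass(frozen=True)
class SuppressionSolution:
    suppressed: frozenset[str]
    level: str
    biomass: float  # inner-optimal biomass reported by the MILP
    verified_biomass: float  # direct FBA with suppressions applied
    w: dict = field(default_factory=dict)
    verdict: str | None = None  # filled by vetting: "global"|"conditional"

    @property
    def cardinality(self) -> int:
        return len(self.suppressed)


# ---------------------------------------------------------------------------
# candidate universes and GPR rows
# ---------------------------------------------------------------------------

def _gene_rows(
    model: MetabolicModel,
    problem: FBAProblem,
    dead: frozenset[int],
    fixed_off: frozenset[str],
    candidates: set[str],
):
    """Per-reaction CNF clause rows over candidate genes.

    Returns (rows, fallback_reactions): each row is
    (rxn_index, candidate_genes_in_clause, n_fixed_active).  Clauses
    with no candidate genes are redundant with the base bounds and are
    dropped.  Reactions whose GPR blows past the CNF cap fall back to a
    reaction-level indicator (their fictitious gene).
    """
    rows: list[tuple[int, tuple[str, ...], int]] = []
    for j, r in enumerate(model.reactions):
        if j in dead:
            continue
        if r.gpr.is_empty:
            fict = fictitious_gene(r.id)
            if fict in candidates:
                rows.append((j, (fict,), 0))
            continue
        try:
            clauses = to_cnf(r.gpr)
        except CNFCapacityError:
            warnings.warn(
                f"GPR of {r.id} exceeds the CNF cap; using a reaction-level "
                "indicator for it",
                stacklevel=3,
            )
            fict = fictitious_gene(r.id)
            candidates.add(fict)
            rows.append((j, (fict,), 0))
            continue
        for clause in clauses:
            cand = tuple(sorted(g for g in clause if g in candidates))
            fixed_active = sum(1 for g in clause if g not in candidates and g not in fixed_off)
            if cand:
                rows.append((j, cand, fixed_active))
    return rows


def _default_gene_candidates(
    problem: SuppressionProblem, dead: frozenset[int]
) -> set[str]:
    model = problem.model
    fixed_off = problem.deletions | model.background_deletions
    cands: set[str] = set()
    for j, r in enumerate(model.reactions):
        if j in dead:
            continue
        cands |= r.gpr.genes()
    cands -= fixed_off
    cands -= problem.exclude
    # fictitious genes for bare reactions, so suppression treats every
    # reaction uniformly (exchanges, biomass and ATPM stay exempt)
    exempt = {model.biomass_reaction_id, model.atpm_reaction_id}
    for j, r in enumerate(model.reactions):
        if j in dead or not r.gpr.is_empty or r.is_exchange or r.id in exempt:
            continue
        if r.id not in problem.exclude:
            cands.add(fictitious_gene(r.id))
    return cands


def _default_reaction_candidates(
    problem: SuppressionProblem, dead: frozenset[int]
) -> set[str]:
    model = problem.model
    exempt = {model.biomass_reaction_id, model.atpm_reaction_id}
    return {
        r.id
        for j, r in enumerate(model.reactions)
        if j not in dead and not r.is_exchange and r.id not in exempt
        and r.id not in problem.exclude
    }


# ---------------------------------------------------------------------------
# the dualized single-level MILP
# ---------------------------------------------------------------------------

class BilevelSuppressor:
    """Builds and repeatedly solves the dualized bilevel MILP for one
    suppression problem, supporting integer cuts between solves."""

    def __init__(self, problem: SuppressionProblem, dual_cap: float = DUAL_CAP):
        self.problem = problem
        self.dual_cap = dual_cap
        model = problem.model
        self.fba = FBAProblem(model)
        self.reference = reference_biomass(self.fba)
        self.cutoff = problem.threshold_fraction * self.reference - VIABILITY_ABS_TOL
        fixed_off = problem.deletions | model.background_deletions
        self.dead = self.fba.inactive_reactions(fixed_off)

        if problem.level == "gene":
            cands = _default_gene_candidates(problem, self.dead)
        else:
            cands = {
                fictitious_gene(rid)
                for rid in _default_reaction_candidates(problem, self.dead)
            }
        if problem.filter_wt_essential:
            cands = {c for c in cands if not self._kills_wild_type(c)}
        if problem.level == "gene":
            self.rows = _gene_rows(model, self.fba, self.dead, fixed_off, cands)
        else:
            rxn_pos = self.fba.rxn_pos
            self.rows = [
                (rxn_pos[c[len(FICTITIOUS_PREFIX):]], (c,), 0) for c in sorted(cands)
            ]
        self.candidates = sorted(cands)
        self.cuts: list[frozenset[str]] = []
        self._build_static()

    def _kills_wild_type(self, cand: str) -> bool:
        if cand.startswith(FICTITIOUS_PREFIX):
            state = self.fba.solve(disabled_reactions=[cand[len(FICTITIOUS_PREFIX):]])
        else:
            state = self.fba.solve(frozenset((cand,)))
        b = state.objective if state.status == "optimal" else 0.0
        return b < self.cutoff

    # -- construction -------------------------------------------------
    def _build_static(self):
        model = self.problem.model
        fba = self.fba
        n_rxn = len(model.reactions)
        n_met = fba.s_matrix.shape[0]
        rows = self.rows
        cand_pos = {g: i for i, g in enumerate(self.candidates)}
        C = len(self.candidates)
        R = len(rows)
        # product variables: one per (row, candidate gene in that row)
        self.prod_index: list[tuple[int, int]] = []  # (row index, cand index)
        for ri, (_, genes, _) in enumerate(rows):
            for g in genes:
                self.prod_index.append((ri, cand_pos[g]))
        P = len(self.prod_index)

        # variable layout
        self.off_w = 0
        self.off_lam = C
        self.off_mu = self.off_lam + n_met
        self.off_nu = self.off_mu + R
        self.off_alpha = self.off_nu + R
        self.off_beta = self.off_alpha + n_rxn
        self.off_zmu = self.off_beta + n_rxn
        self.off_znu = self.off_zmu + P
        self.n_vars = self.off_znu + P
        D = self.dual_cap

        lb_j = np.array([r.lower_bound for r in model.reactions])
        ub_j = np.array([r.upper_bound for r in model.reactions])
        for j in self.dead:
            lb_j[j] = 0.0
            ub_j[j] = 0.0
        self.lb_j, self.ub_j = lb_j, ub_j

        # objective: the dual objective of the inner LP
        obj = np.zeros(self.n_vars)
        for ri, (j, _genes, a) in enumerate(rows):
            obj[self.off_mu + ri] = a * ub_j[j]
            obj[self.off_nu + ri] = -a * lb_j[j]
        obj[self.off_alpha : self.off_alpha + n_rxn] = ub_j
        obj[self.off_beta : self.off_beta + n_rxn] = -lb_j
        for p, (ri, _ci) in enumerate(self.prod_index):
            j = rows[ri][0]
            obj[self.off_zmu + p] = ub_j[j]
            obj[self.off_znu + p] = -lb_j[j]
        self.objective = obj

        # equality block: dual feasibility, one row per reaction
        eq_r, eq_c, eq_v = [], [], []
        s_csc = fba.s_matrix.tocsc()
        for j in range(n_rxn):
            col = s_csc.getcol(j).tocoo()
            for i, val in zip(col.row, col.data):
                eq_r.append(j)
                eq_c.append(self.off_lam + i)
                eq_v.append(val)
            eq_r.append(j)
            eq_c.append(self.off_alpha + j)
            eq_v.append(1.0)
            eq_r.append(j)
            eq_c.append(self.off_beta + j)
            eq_v.append(-1.0)
        for ri, (j, _genes, _a) in enumerate(rows):
            eq_r.extend((j, j))
            eq_c.extend((self.off_mu + ri, self.off_nu + ri))
            eq_v.extend((1.0, -1.0))
        self.a_eq = sparse.csr_matrix(
            (eq_v, (eq_r, eq_c)), shape=(n_rxn, self.n_vars)
        )
        self.b_eq = fba.c.copy()  # c_j: 1 on biomass, 0 elsewhere

        # inequality block: linearization of z = w * dual
        ub_r, ub_c, ub_v, ub_b = [], [], [], []
        row_n = 0

        def add_row(entries, rhs):
            nonlocal row_n
            for cidx, val in entries:
                ub_r.append(row_n)
                ub_c.append(cidx)
                ub_v.append(val)
            ub_b.append(rhs)
            row_n += 1

        for p, (ri, ci) in enumerate(self.prod_index):
            for off_z, off_d in ((self.off_zmu, self.off_mu), (self.off_znu, self.off_nu)):
                z = off_z + p
                d = off_d + ri
                w = self.off_w + ci
                add_row([(z, 1.0), (d, -1.0)], 0.0)          # z <= dual
                add_row([(z, 1.0), (w, -D)], 0.0)            # z <= D w
                add_row([(d, 1.0), (z, -1.0), (w, D)], D)    # z >= dual - D(1-w)
        # cardinality: sum (1 - w) <= card  ->  -sum w <= card - C
        for ci in range(C):
            ub_r.append(row_n)
            ub_c.append(self.off_w + ci)
            ub_v.append(-1.0)
        self.card_row = row_n
        ub_b.append(0.0)  # rhs patched per solve
        row_n += 1
        self.a_ub_static = sparse.csr_matrix(
            (ub_v, (ub_r, ub_c)), shape=(row_n, self.n_vars)
        )
        self.b_ub_static = np.array(ub_b)

        bounds = [(0.0, 1.0)] * C
        bounds += [(-D, D)] * n_met
        bounds += [(0.0, D)] * (2 * R)
        bounds += [(0.0, D)] * (2 * n_rxn)
        bounds += [(0.0, D)] * (2 * P)
        self.bounds = bounds
        integrality = np.zeros(self.n_vars)
        integrality[:C] = 1
        self.integrality = integrality
        self.cand_pos = cand_pos

    # -- solving ------------------------------------------------------
    def solve_once(self, card: int):
        """One MILP solve at the given suppression budget; returns
        (objective biomass, support) or None if infeasible."""
        C = len(self.candidates)
        b_ub = self.b_ub_static.copy()
        b_ub[self.card_row] = card - C
        a_ub = self.a_ub_static
        if self.cuts:
            cut_r, cut_c, cut_v = [], [], []
            for q, support in enumerate(self.cuts):
                for g in support:
                    cut_r.append(q)
                    cut_c.append(self.off_w + self.cand_pos[g])
                    cut_v.append(-1.0)
            cut_m = sparse.csr_matrix(
                (cut_v, (cut_r, cut_c)), shape=(len(self.cuts), self.n_vars)
            )
            a_ub = sparse.vstack([a_ub, cut_m]).tocsr()
            b_ub = np.concatenate([b_ub, -np.ones(len(self.cuts))])
        res = solve_milp(
            self.objective,
            self.integrality,
            self.bounds,
            a_eq=self.a_eq,
            b_eq=self.b_eq,
            a_ub=a_ub,
            b_ub=b_ub,
            maximize=False,
        )
        if res.status != "optimal":
            return None
        w = res.x[: C]
        support = frozenset(g for g, ci in self.cand_pos.items() if w[ci] < 0.5)
        # capped duals only matter where they carry objective weight;
        # cost-free duals (e.g. on dead reactions) may float to the cap
        weighted = (np.abs(res.x) > 0.99 * self.dual_cap) & (self.objective != 0.0)
        weighted[: C] = False
        if weighted.any():
            warnings.warn(
                "an inner dual variable is within 1% of the dual cap; the "
                "reported inner optimum may be unreliable",
                stacklevel=2,
            )
        return float(res.objective), support

    def verify(self, support: frozenset[str]) -> float:
        """Direct FBA with the suppressions applied (no duality)."""
        genes = {g for g in support if not g.startswith(FICTITIOUS_PREFIX)}
        rxns = [g[len(FICTITIOUS_PREFIX):] for g in support if g.startswith(FICTITIOUS_PREFIX)]
        dels = self.problem.deletions | frozenset(genes)
        state = self.fba.solve(dels, disabled_reactions=rxns)
        return state.objective if state.status == "optimal" else 0.0

    def mutant_biomass(self) -> float:
        state = self.fba.solve(self.problem.deletions)
        return state.objective if state.status == "optimal" else 0.0


def _public_ids(support: frozenset[str], level: str) -> frozenset[str]:
    if level == "reaction":
        return frozenset(g[len(FICTITIOUS_PREFIX):] for g in support)
    return support


def _solve_problem(
    problem: SuppressionProblem, max_alternates: int
) -> list[SuppressionSolution]:
    bl = BilevelSuppressor(problem)
    mutant = bl.mutant_biomass()
    if mutant < bl.cutoff:
        return [
            SuppressionSolution(
                suppressed=frozenset(), level=problem.level,
                biomass=mutant, verified_biomass=mutant,
            )
        ]
    solutions: list[SuppressionSolution] = []
    for card in range(1, problem.n + 1):
        while len(solutions) < max_alternates:
            res = bl.solve_once(card)
            if res is None:
                break
            obj, support = res
            if obj >= bl.cutoff:
                break  # even the best remaining w keeps the mutant viable
            verified = bl.verify(support)
            if abs(verified - obj) > max(_DUALITY_TOL, 1e-6 * max(1.0, abs(obj))):
                warnings.warn(
                    f"bilevel optimum {obj:.8f} disagrees with direct FBA "
                    f"{verified:.8f} for suppression {sorted(support)}",
                    stacklevel=2,
                )
            if verified < bl.cutoff:
                solutions.append(
                    SuppressionSolution(
                        suppressed=_public_ids(support, problem.level),
                        level=problem.level,
                        biomass=obj,
                        verified_biomass=verified,
                        w={g: 0 for g in sorted(support)},
                    )
                )
            bl.cuts.append(support)
        if solutions:
            break  # minimal cardinality reached
    return solutions


def min_gene_suppressions(
    model: MetabolicModel,
    deletions: Iterable[str],
    n: int = 2,
    threshold_fraction: float = VIABILITY_FRACTION,
    max_alternates: int = 10,
    exclude: Iterable[str] = (),
) -> list[SuppressionSolution]:
    """Minimal gene suppression sets rendering the mutant non-viable.

    The candidate universe is every gene carried by an active reaction,
    excluding the mutant's own deletions and the strain background;
    reactions without a GPR participate through a fictitious gene.
    """
    problem = SuppressionProblem(
        model, frozenset(deletions), "gene", n, threshold_fraction, frozenset(exclude)
    )
    return _solve_problem(problem, max_alternates)


def min_reaction_suppressions(
    model: MetabolicModel,
    deletions: Iterable[str],
    n: int = 2,
    threshold_fraction: float = VIABILITY_FRACTION,
    max_alternates: int = 10,
    exclude: Iterable[str] = (),
) -> list[SuppressionSolution]:
    """Minimal reaction suppression sets rendering the mutant non-viable."""
    problem = SuppressionProblem(
        model, frozenset(deletions), "reaction", n, threshold_fraction, frozenset(exclude)
    )
    return _solve_problem(problem, max_alternates)


def enumerate_alternatives(
    problem: SuppressionProblem, k: int
) -> list[SuppressionSolution]:
    """Up to k same-cardinality suppression sets via integer cuts."""
    return _solve_problem(problem, max_alternates=k)


# ---------------------------------------------------------------------------
# exhaustive enumerator (reference / fallback for small n)
# ---------------------------------------------------------------------------

def exhaustive_suppressions(
    model: MetabolicModel,
    deletions: Iterable[str],
    level: str,
    n: int = 2,
    threshold_fraction: float = VIABILITY_FRACTION,
    exclude: Iterable[str] = (),
) -> list[SuppressionSolution]:
    """Brute-force subset search over the same candidate universe.

    Exact for any n, practical for n <= 2; doubles as the independent
    check of the bilevel route.
    """
    problem = SuppressionProblem(
        model, frozenset(deletions), level, n, threshold_fraction, frozenset(exclude)
    )
    bl = BilevelSuppressor(problem)
    mutant = bl.mutant_biomass()
    if mutant < bl.cutoff:
        return [
            SuppressionSolution(
                suppressed=frozenset(), level=level,
                biomass=mutant, verified_biomass=mutant,
            )
        ]
    out: list[SuppressionSolution] = []
    raw_supports: list[frozenset[str]] = []
    for card in range(1, n + 1):
        for combo in itertools.combinations(bl.candidates, card):
            support = frozenset(combo)
            if any(prev <= support for prev in raw_supports):
                continue
            b = bl.verify(support)
            if b < bl.cutoff:
                raw_supports.append(support)
                out.append(
                    SuppressionSolution(
                        suppressed=_public_ids(support, level),
                        level=level,
                        biomass=b,
                        verified_biomass=b,
                    )
                )
        if out:
            break
    return out
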