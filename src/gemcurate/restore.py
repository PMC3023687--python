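"""Growth restoration for falsely lethal mutants (NGG / SLG / auxotrophy).

A mutant that dies in silico but grows in vivo points to a missing
capability.  Three mechanisms can supply it, mirroring standard
gap-filling practice: (i) relaxing an irreversibility constraint
(LB 0 -> -1000), (ii) adding a reaction from an external candidate
database (KEGG-style equations), and (iii) adding transport and/or
exchange reactions so a metabolite can be imported or exported.  The
search is a MILP: one binary per candidate gates its flux through
big-M bounds (M = 1000, the global flux bound, so gating is exact);
minimize the number of switched-on candidates subject to the mutant
reaching the viability threshold.  All minimal-cardinality solutions
(up to a cap) are enumerated with integer cuts and each is re-verified
by plain FBA on the edited model.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import sparse

from ._solver import solve_milp
from .edits import Modification
from .fba import FBAProblem, VIABILITY_ABS_TOL, VIABILITY_FRACTION, reference_biomass
from .model import GLOBAL_BOUND, MetabolicModel, Metabolite, Reaction

__all__ = [
    "Candidate",
    "CandidatePool",
    "RestorationSolution",
    "build_candidate_pool",
    "parse_reaction_database",
    "restore_growth",
    "resolve_medium",
]


@dataclass(frozen=True)
class Candidate:
    """One switchable model addition."""

    id: str
    kind: str  # reversibility_relaxation | reaction_addition | transport_addition | exchange_addition
    reaction: Reaction | None = None  # new column (None for relaxations)
    target_reaction: str | None = None  # for relaxations
    new_metabolites: tuple[Metabolite, ...] = ()

    def as_modification(self) -> Modification:
        if self.kind == "reversibility_relaxation":
            return Modification(kind=self.kind, payload={"reaction_id": self.target_reaction})
        return Modification(
            kind=self.kind,
            payload={"reaction": self.reaction, "metabolites": self.new_metabolites},
        )


@dataclass(frozen=True)
class CandidatePool:
    candidates: tuple[Candidate, ...]

    def __len__(self) -> int:
        return len(self.candidates)

    def __iter__(self):
        return iter(self.candidates)

    def subset(self, kinds: Iterable[str]) -> "CandidatePool":
        ks = set(kinds)
        return CandidatePool(tuple(c for c in self.candidates if c.kind in ks))


@dataclass(frozen=True)
class RestorationSolution:
    additions: tuple[Candidate, ...]
    biomass: float  # MILP-reported mutant biomass after the additions
    verified_biomass: float  # direct FBA on the edited model
    verdict: str | None = None

    @property
    def cardinality(self) -> int:
        return len(self.additions)

    def modifications(self) -> list[Modification]:
        return [c.as_modification() for c in self.additions]


# ---------------------------------------------------------------------------
# candidate database parsing and pool construction
# ---------------------------------------------------------------------------

_ARROW_RE = re.compile(r"<=>|=>|<->|->")
_TERM_RE = re.compile(r"^(?:(\d+(?:\.\d+)?)\s+)?(\S+)$")


def parse_reaction_equation(rxn_id: str, equation: str) -> Reaction:
    """Parse ``"2 A + B <=> C"`` into a Reaction; ``=>`` is irreversible."""
    m = _ARROW_RE.search(equation)
    if m is None:
        raise ValueError(f"no reaction arrow in equation {equation!r}")
    reversible = m.group(0) in ("<=>", "<->")
    left, right = equation[: m.start()], equation[m.end():]
    stoich: dict[str, float] = {}

    def add_side(side: str, sign: float):
        side = side.strip()
        if not side:
            return
        for term in side.split(" + "):
            term = term.strip()
            tm = _TERM_RE.match(term)
            if tm is None:
                raise ValueError(f"cannot parse term {term!r} in {equation!r}")
            coeff = float(tm.group(1)) if tm.group(1) else 1.0
            met = tm.group(2)
            stoich[met] = stoich.get(met, 0.0) + sign * coeff

    add_side(left, -1.0)
    add_side(right, +1.0)
    stoich = {k: v for k, v in stoich.items() if v != 0.0}
    return Reaction(
        id=rxn_id,
        stoichiometry=stoich,
        lower_bound=-GLOBAL_BOUND if reversible else 0.0,
        upper_bound=GLOBAL_BOUND,
    )


def parse_reaction_database(path) -> list[Reaction]:
    """Read a flat TSV of candidate reactions: id <TAB> equation
    [<TAB> compartment].  Metabolite ids carry compartment suffixes."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected 'id<TAB>equation'")
            try:
                out.append(parse_reaction_equation(parts[0], parts[1]))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    return out


def build_candidate_pool(
    model: MetabolicModel,
    db_reactions: Sequence[Reaction] = (),
    enable_relaxations: bool = True,
    enable_transports: bool = True,
    enable_exchanges: bool = True,
    admit_unknown_metabolites: bool = False,
    extra_compounds: Sequence[Metabolite] = (),
) -> CandidatePool:
    """Assemble the switchable additions for a restoration search.

    Relaxation candidates are all irreversible non-exchange reactions;
    transport candidates connect each non-cytosolic species of a
    compound to its cytosolic form; exchange candidates let an
    extracellular species cross the boundary.  Database reactions whose
    metabolites are unknown to the model are excluded unless
    ``admit_unknown_metabolites`` (then the new species are added with
    the reaction).
    """
    cands: list[Candidate] = []
    existing = {r.id for r in model.reactions}
    exempt = {model.biomass_reaction_id, model.atpm_reaction_id}
    if enable_relaxations:
        for r in model.reactions:
            if r.lower_bound == 0.0 and not r.is_exchange and r.id not in exempt:
                cands.append(
                    Candidate(
                        id=f"relax:{r.id}",
                        kind="reversibility_relaxation",
                        target_reaction=r.id,
                    )
                )
    known = {m.id for m in model.metabolites}
    extra_by_id = {m.id: m for m in extra_compounds}
    for rxn in db_reactions:
        if rxn.id in existing:
            continue
        unknown = [m for m in rxn.stoichiometry if m not in known]
        if unknown and not admit_unknown_metabolites:
            continue
        new_mets = tuple(
            extra_by_id.get(mid, Metabolite(id=mid, compartment=_compartment_of(mid)))
            for mid in unknown
        )
        cands.append(
            Candidate(
                id=f"db:{rxn.id}", kind="reaction_addition",
                reaction=rxn, new_metabolites=new_mets,
            )
        )
    # group species by compound stem across compartments
    stems: dict[str, dict[str, str]] = {}
    for m in model.metabolites:
        stems.setdefault(_stem_of(m.id), {})[m.compartment] = m.id
    for m in extra_compounds:
        stems.setdefault(_stem_of(m.id), {})[m.compartment] = m.id
    if enable_transports:
        for stem, by_comp in sorted(stems.items()):
            cyt = by_comp.get("c")
            for comp, mid in sorted(by_comp.items()):
                if comp == "c" or cyt is None:
                    continue
                rid = f"T_{stem}_{comp}"
                if rid in existing:
                    continue
                cands.append(
                    Candidate(
                        id=f"transport:{rid}",
                        kind="transport_addition",
                        reaction=Reaction(
                            id=rid,
                            stoichiometry={mid: -1.0, cyt: 1.0},
                            lower_bound=-GLOBAL_BOUND,
                            upper_bound=GLOBAL_BOUND,
                        ),
                        new_metabolites=tuple(
                            mm for mm in extra_compounds if mm.id in (mid, cyt)
                        ),
                    )
                )
    if enable_exchanges:
        has_exchange = {
            next(iter(r.stoichiometry)) for r in model.reactions if r.is_exchange
        }
        for stem, by_comp in sorted(stems.items()):
            ext = by_comp.get("e")
            if ext is None or ext in has_exchange:
                continue
            rid = f"EX_{stem}_cand"
            if rid in existing:
                continue
            cands.append(
                Candidate(
                    id=f"exchange:{rid}",
                    kind="exchange_addition",
                    reaction=Reaction(
                        id=rid,
                        stoichiometry={ext: -1.0},
                        lower_bound=-GLOBAL_BOUND,
                        upper_bound=GLOBAL_BOUND,
                    ),
                    new_metabolites=tuple(mm for mm in extra_compounds if mm.id == ext),
                )
            )
    return CandidatePool(tuple(cands))


def _stem_of(met_id: str) -> str:
    return met_id.rsplit("_", 1)[0] if "_" in met_id else met_id


def _compartment_of(met_id: str) -> str:
    return met_id.rsplit("_", 1)[1] if "_" in met_id else "c"


# ---------------------------------------------------------------------------
# the restoration MILP
# ---------------------------------------------------------------------------

def apply_candidates(
    model: MetabolicModel, additions: Iterable[Candidate]
) -> MetabolicModel:
    """Model copy with the chosen candidates switched on permanently."""
    updated, added, mets = [], [], []
    for c in additions:
        if c.kind == "reversibility_relaxation":
            r = model.reaction(c.target_reaction)
            updated.append(r.with_bounds(-GLOBAL_BOUND, r.upper_bound))
        else:
            added.append(c.reaction)
            mets.extend(c.new_metabolites)
    return model.with_reactions(updated=updated, added=added, added_metabolites=mets)


def restore_growth(
    model: MetabolicModel,
    deletions: Iterable[str],
    pool: CandidatePool,
    max_additions: int = 2,
    threshold_fraction: float = VIABILITY_FRACTION,
    max_alternates: int = 10,
) -> list[RestorationSolution]:
    """All minimal-cardinality addition sets restoring mutant viability.

    Returns an empty list (with no exception) when no subset of up to
    ``max_additions`` candidates reaches the threshold.
    """
    if max_additions < 1:
        raise ValueError("max_additions must be at least 1")
    fba = FBAProblem(model)
    ref = reference_biomass(fba)
    cutoff = threshold_fraction * ref - VIABILITY_ABS_TOL
    dels = frozenset(deletions)
    mutant = fba.solve(dels)
    if mutant.status == "optimal" and mutant.objective >= cutoff:
        return [
            RestorationSolution(
                additions=(), biomass=mutant.objective,
                verified_biomass=mutant.objective,
            )
        ]

    # variables: fluxes of model reactions, fluxes of candidate columns,
    # binaries y per candidate
    base_model = model
    n_rxn = len(model.reactions)
    cands = list(pool.candidates)
    n_c = len(cands)
    new_met_ids: list[str] = []
    met_pos = {m.id: i for i, m in enumerate(model.metabolites)}
    for c in cands:
        for m in c.new_metabolites:
            if m.id not in met_pos:
                met_pos[m.id] = len(met_pos)
                new_met_ids.append(m.id)
    n_met = len(met_pos)

    dead = fba.inactive_reactions(dels | model.background_deletions)
    v_bounds = []
    for j, r in enumerate(model.reactions):
        v_bounds.append((0.0, 0.0) if j in dead else (r.lower_bound, r.upper_bound))

    rows, cols, vals = [], [], []
    s_coo = fba.s_matrix.tocoo()
    rows.extend(s_coo.row)
    cols.extend(s_coo.col)
    vals.extend(s_coo.data)
    off_cand = n_rxn
    off_y = n_rxn + n_c
    n_vars = off_y + n_c
    cand_bounds: list[tuple[float, float]] = []
    ub_r, ub_c, ub_v, ub_b = [], [], [], []
    row_n = 0

    def add_ub(entries, rhs):
        nonlocal row_n
        for cidx, val in entries:
            ub_r.append(row_n)
            ub_c.append(cidx)
            ub_v.append(val)
        ub_b.append(rhs)
        row_n += 1

    for k, c in enumerate(cands):
        y = off_y + k
        if c.kind == "reversibility_relaxation":
            j = fba.rxn_pos[c.target_reaction]
            cand_bounds.append((0.0, 0.0))  # unused slack column
            if j in dead:
                continue
            # v_j >= -1000 y  (relaxes the zero lower bound when y = 1)
            add_ub([(j, -1.0), (y, -GLOBAL_BOUND)], 0.0)
            v_bounds[j] = (-GLOBAL_BOUND, v_bounds[j][1])  # wide; row gates it
        else:
            for mid, coeff in c.reaction.stoichiometry.items():
                rows.append(met_pos[mid])
                cols.append(off_cand + k)
                vals.append(coeff)
            lbk, ubk = c.reaction.lower_bound, c.reaction.upper_bound
            cand_bounds.append((min(lbk, 0.0), max(ubk, 0.0)))
            # y gates the candidate flux: lb*y <= v_c <= ub*y
            add_ub([(off_cand + k, 1.0), (y, -ubk)], 0.0)
            add_ub([(off_cand + k, -1.0), (y, lbk)], 0.0)
    a_eq = sparse.csr_matrix((vals, (rows, cols)), shape=(n_met, n_vars))
    b_eq = np.zeros(n_met)

    # biomass must reach the threshold
    bio = fba.rxn_pos[model.biomass_reaction_id]
    add_ub([(bio, -1.0)], -(threshold_fraction * ref))

    obj = np.zeros(n_vars)
    obj[off_y:] = 1.0
    integrality = np.zeros(n_vars)
    integrality[off_y:] = 1
    bounds = v_bounds + cand_bounds + [(0.0, 1.0)] * n_c

    # cardinality cap
    card_entries = [(off_y + k, 1.0) for k in range(n_c)]
    add_ub(card_entries, float(max_additions))

    solutions: list[RestorationSolution] = []
    cuts: list[tuple[int, ...]] = []
    best_card: int | None = None
    while len(solutions) < max_alternates:
        extra_r, extra_c, extra_v, extra_b = [], [], [], []
        q = 0
        for chosen in cuts:
            for k in chosen:
                extra_r.append(row_n + q)
                extra_c.append(off_y + k)
                extra_v.append(1.0)
            extra_b.append(len(chosen) - 1.0)
            q += 1
        if best_card is not None:
            for k in range(n_c):
                extra_r.append(row_n + q)
                extra_c.append(off_y + k)
                extra_v.append(1.0)
            extra_b.append(float(best_card))
            q += 1
        a_ub = sparse.csr_matrix(
            (ub_v + extra_v, (ub_r + extra_r, ub_c + extra_c)),
            shape=(row_n + q, n_vars),
        )
        b_ub = np.array(ub_b + extra_b)
        res = solve_milp(
            obj, integrality, bounds, a_eq=a_eq, b_eq=b_eq, a_ub=a_ub, b_ub=b_ub
        )
        if res.status != "optimal":
            break
        y = res.x[off_y:]
        chosen = tuple(k for k in range(n_c) if y[k] > 0.5)
        if best_card is None:
            best_card = len(chosen)
        elif len(chosen) > best_card:
            break
        edited = apply_candidates(base_model, [cands[k] for k in chosen])
        state = FBAProblem(edited).solve(dels)
        verified = state.objective if state.status == "optimal" else 0.0
        milp_bio = float(res.x[bio])
        if verified >= cutoff:
            solutions.append(
                RestorationSolution(
                    additions=tuple(cands[k] for k in chosen),
                    biomass=milp_bio,
                    verified_biomass=verified,
                )
            )
        cuts.append(chosen)
    return solutions


# ---------------------------------------------------------------------------
# medium-level fixes
# ---------------------------------------------------------------------------

def resolve_medium(
    model: MetabolicModel,
    deletions: Iterable[str],
    compound: str,
    uptake_level: float = 0.5,
    threshold_fraction: float = VIABILITY_FRACTION,
) -> list[Modification]:
    """Fix a falsely lethal mutant by amending the medium, not the model.

    Tries, in order: opening the compound's existing exchange; adding a
    new exchange for an extracellular species; adding an exchange plus
    a transport step for an internal-only species.  Returns the
    modification list that flips the mutant viable, or an empty list.
    """
    from .phenotypes import open_supplement_uptake

    dels = frozenset(deletions)
    fba = FBAProblem(model)
    ref = reference_biomass(fba)
    cutoff = threshold_fraction * ref - VIABILITY_ABS_TOL
    try:
        supplemented = open_supplement_uptake(model, compound, uptake_level)
    except ValueError:
        return []
    state = FBAProblem(supplemented).solve(dels)
    if state.status != "optimal" or state.objective < cutoff:
        return []
    mods: list[Modification] = [
        Modification(
            kind="medium_component",
            payload={"compound": compound, "uptake_level": uptake_level},
        )
    ]
    new_rxns = {r.id for r in supplemented.reactions} - {r.id for r in model.reactions}
    for rid in sorted(new_rxns):
        r = supplemented.reaction(rid)
        kind = "exchange_addition" if r.is_exchange else "transport_addition"
        new_mets = tuple(
            m for m in supplemented.metabolites
            if not model.has_metabolite(m.id) and m.id in r.stoichiometry
        )
        mods.append(
            Modification(kind=kind, payload={"reaction": r, "metabolites": new_mets})
        )
    return mods
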