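"""Metabolic model containers, SBML (fbc) I/O, validation, media.

The in-memory containers are deliberately small: a model is metabolites,
reactions (stoichiometry + bounds + GPR), a declared gene set, and the
designated biomass and ATP-maintenance reactions.  Flux bounds follow
the BiGG convention: the global bound is 1000 mmol gDW^-1 h^-1, an
irreversible reaction has LB = 0, and uptake through an exchange
reaction written as ``met_e <=>`` is negative flux, so an uptake limit
L sets LB = -L.
"""

from __future__ import annotations

import configparser
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import libsbml

from .gpr import GPRExpr, parse_gpr

__all__ = [
    "Metabolite",
    "Reaction",
    "MetabolicModel",
    "MediumSpec",
    "ModelValidationError",
    "SBMLFormatError",
    "read_model",
    "write_model",
    "apply_medium",
    "GLOBAL_BOUND",
    "MINIMAL_TRACE_COMPOUNDS",
]

#: global flux bound (mmol gDW^-1 h^-1) for reversible reactions
GLOBAL_BOUND = 1000.0

#: trace compounds opened at a low level in the minimal-medium preset
MINIMAL_TRACE_COMPOUNDS = (
    "4abz", "btn", "inost", "nac", "pnto_R", "thm",
)


class ModelValidationError(ValueError):
    """Model violates a structural invariant (dangling ids, bad bounds)."""


class SBMLFormatError(ValueError):
    """SBML document could not be interpreted; names the offending element."""


@dataclass(frozen=True)
class Metabolite:
    id: str
    name: str = ""
    compartment: str = "c"
    is_biomass_component: bool = False


@dataclass(frozen=True)
class Reaction:
    """A stoichiometric reaction with flux bounds and an optional GPR.

    ``stoichiometry`` maps metabolite id -> signed coefficient
    (negative = consumed).  Exchange reactions are single-metabolite
    boundary reactions; transport reactions move a species between
    compartments.
    """

    id: str
    stoichiometry: Mapping[str, float]
    lower_bound: float = -GLOBAL_BOUND
    upper_bound: float = GLOBAL_BOUND
    gpr: GPRExpr = field(default_factory=GPRExpr.empty)
    name: str = ""

    @property
    def is_exchange(self) -> bool:
        return len(self.stoichiometry) == 1

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0

    def with_bounds(self, lb: float, ub: float) -> "Reaction":
        return replace(self, lower_bound=lb, upper_bound=ub)

    def with_gpr(self, gpr: GPRExpr) -> "Reaction":
        return replace(self, gpr=gpr)


@dataclass(frozen=True)
class MetabolicModel:
    """An immutable genome-scale (or toy) metabolic model.

    Edits produce new instances (see ``with_reactions``), which keeps
    screening results safe to cache per model object.
    """

    id: str
    metabolites: tuple[Metabolite, ...]
    reactions: tuple[Reaction, ...]
    genes: frozenset[str]
    biomass_reaction_id: str | None = None
    atpm_reaction_id: str | None = None
    background_deletions: frozenset[str] = frozenset()
    compartments: tuple[str, ...] = ()

    def __post_init__(self):
        object.__setattr__(self, "_met_index", {m.id: m for m in self.metabolites})
        object.__setattr__(self, "_rxn_index", {r.id: r for r in self.reactions})

    # -- lookups ------------------------------------------------------
    def metabolite(self, met_id: str) -> Metabolite:
        return self._met_index[met_id]

    def reaction(self, rxn_id: str) -> Reaction:
        return self._rxn_index[rxn_id]

    def has_metabolite(self, met_id: str) -> bool:
        return met_id in self._met_index

    def has_reaction(self, rxn_id: str) -> bool:
        return rxn_id in self._rxn_index

    @property
    def biomass_reaction(self) -> Reaction:
        if self.biomass_reaction_id is None:
            raise ModelValidationError("model has no biomass reaction designated")
        return self.reaction(self.biomass_reaction_id)

    def exchanges(self) -> list[Reaction]:
        return [r for r in self.reactions if r.is_exchange]

    # -- editing ------------------------------------------------------
    def with_reactions(
        self,
        updated: Iterable[Reaction] = (),
        added: Iterable[Reaction] = (),
        removed: Iterable[str] = (),
        added_metabolites: Iterable[Metabolite] = (),
        added_genes: Iterable[str] = (),
    ) -> "MetabolicModel":
        """Return a copy with reactions replaced/added/removed."""
        upd = {r.id: r for r in updated}
        rem = set(removed)
        rxns = [upd.get(r.id, r) for r in self.reactions if r.id not in rem]
        for r in added:
            if r.id in self._rxn_index or any(x.id == r.id for x in rxns):
                raise ModelValidationError(f"duplicate reaction id {r.id!r}")
            rxns.append(r)
        mets = list(self.metabolites)
        known = set(self._met_index)
        for m in added_metabolites:
            if m.id not in known:
                mets.append(m)
                known.add(m.id)
        genes = self.genes | frozenset(added_genes)
        for r in rxns:
            genes |= r.gpr.genes()
        return replace(
            self,
            metabolites=tuple(mets),
            reactions=tuple(rxns),
            genes=genes,
        )

    # -- validation ---------------------------------------------------
    def validate(self) -> list[str]:
        """Check structural invariants; raises on errors, returns warnings."""
        warnings: list[str] = []
        if not self.reactions:
            warnings.append("model has no reactions")
        met_ids = set(self._met_index)
        if len(met_ids) != len(self.metabolites):
            raise ModelValidationError("duplicate metabolite ids")
        if len(self._rxn_index) != len(self.reactions):
            raise ModelValidationError("duplicate reaction ids")
        comp_set = set(self.compartments) or {m.compartment for m in self.metabolites}
        for m in self.metabolites:
            if m.compartment not in comp_set:
                raise ModelValidationError(
                    f"metabolite {m.id!r} uses undeclared compartment {m.compartment!r}"
                )
        for r in self.reactions:
            if r.lower_bound > r.upper_bound:
                raise ModelValidationError(
                    f"reaction {r.id!r} has LB {r.lower_bound} > UB {r.upper_bound}"
                )
            if not r.stoichiometry and not r.is_exchange:
                raise ModelValidationError(f"reaction {r.id!r} has empty stoichiometry")
            for met_id in r.stoichiometry:
                if met_id not in met_ids:
                    raise ModelValidationError(
                        f"reaction {r.id!r} references unknown metabolite {met_id!r}"
                    )
            undeclared = r.gpr.genes() - self.genes
            if undeclared:
                raise ModelValidationError(
                    f"reaction {r.id!r} GPR references undeclared genes {sorted(undeclared)}"
                )
        for label, rid in (
            ("biomass", self.biomass_reaction_id),
            ("ATPM", self.atpm_reaction_id),
        ):
            if rid is not None and rid not in self._rxn_index:
                raise ModelValidationError(f"{label} reaction id {rid!r} not in model")
        return warnings


# ---------------------------------------------------------------------------
# media
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MediumSpec:
    """A growth-medium description applied to exchange bounds.

    ``uptake_limits`` maps exchange reaction id -> maximum uptake rate
    (mmol gDW^-1 h^-1); positive numbers, applied as LB = -limit.
    ``background_deletions`` is the strain's fixed gene knockouts
    (e.g. the his3/leu2/met15/ura3 auxotrophic background), unioned into
    every downstream deletion query.  ``supplements`` are compounds
    opened at a low, non-limiting rate to feed those auxotrophies.
    """

    name: str = "custom"
    uptake_limits: Mapping[str, float] = field(default_factory=dict)
    atpm_flux: float = 1.0
    background_deletions: frozenset[str] = frozenset()
    supplements: Mapping[str, float] = field(default_factory=dict)
    supplement_level: float = 0.5

    def __post_init__(self):
        for rid, lim in {**self.uptake_limits, **self.supplements}.items():
            if lim < 0:
                raise ValueError(f"uptake limit for {rid!r} must be non-negative")
        if self.atpm_flux < 0:
            raise ValueError("ATPM flux must be non-negative")

    @staticmethod
    def from_file(path) -> "MediumSpec":
        """Load a medium config (INI sections: medium, uptake,
        supplements, background_deletions)."""
        cp = configparser.ConfigParser()
        cp.optionxform = str  # exchange ids are case-sensitive
        with open(path) as fh:
            cp.read_file(fh)
        name = cp.get("medium", "name", fallback="custom")
        atpm = cp.getfloat("medium", "atpm_flux", fallback=1.0)
        level = cp.getfloat("medium", "supplement_level", fallback=0.5)
        uptake = {k: float(v) for k, v in cp.items("uptake")} if cp.has_section("uptake") else {}
        supp = (
            {k: float(v) for k, v in cp.items("supplements")}
            if cp.has_section("supplements")
            else {}
        )
        bg = (
            frozenset(k for k, _ in cp.items("background_deletions"))
            if cp.has_section("background_deletions")
            else frozenset()
        )
        return MediumSpec(
            name=name,
            uptake_limits=uptake,
            atpm_flux=atpm,
            background_deletions=bg,
            supplements=supp,
            supplement_level=level,
        )

    def to_file(self, path) -> None:
        cp = configparser.ConfigParser()
        cp.optionxform = str
        cp["medium"] = {
            "name": self.name,
            "atpm_flux": repr(self.atpm_flux),
            "supplement_level": repr(self.supplement_level),
        }
        cp["uptake"] = {k: repr(v) for k, v in sorted(self.uptake_limits.items())}
        cp["supplements"] = {k: repr(v) for k, v in sorted(self.supplements.items())}
        cp["background_deletions"] = {g: "" for g in sorted(self.background_deletions)}
        with open(path, "w") as fh:
            cp.write(fh)

    def with_uptake(self, rxn_id: str, limit: float) -> "MediumSpec":
        up = dict(self.uptake_limits)
        up[rxn_id] = limit
        return replace(self, uptake_limits=up)


def apply_medium(model: MetabolicModel, medium: MediumSpec) -> MetabolicModel:
    """Return a copy of the model constrained to the medium.

    All exchange uptakes are first closed (LB = 0), then the medium's
    uptake limits and supplements are opened; the ATPM flux is fixed.
    Background deletions are recorded on the model for downstream
    screens to union into every deletion query.  Idempotent.
    """
    all_limits = dict(medium.uptake_limits)
    for rid, lim in medium.supplements.items():
        all_limits.setdefault(rid, lim)
    rxn_ids = {r.id for r in model.reactions}
    unknown = [rid for rid in all_limits if rid not in rxn_ids]
    if unknown:
        raise ModelValidationError(
            f"medium {medium.name!r} references unknown exchange reactions: {sorted(unknown)}"
        )
    updated = []
    for r in model.reactions:
        if r.is_exchange:
            limit = all_limits.get(r.id, 0.0)
            updated.append(r.with_bounds(-limit, max(r.upper_bound, 0.0)))
    new = model.with_reactions(updated=updated)
    if model.atpm_reaction_id is not None:
        atpm = new.reaction(model.atpm_reaction_id)
        new = new.with_reactions(updated=[atpm.with_bounds(medium.atpm_flux, medium.atpm_flux)])
    return replace(new, background_deletions=frozenset(medium.background_deletions))


# ---------------------------------------------------------------------------
# SBML I/O
# ---------------------------------------------------------------------------

def read_model(path, dialect: str = "fbc") -> MetabolicModel:
    """Read an SBML model; ``dialect`` selects fbc-v2 gene associations
    (canonical) or legacy notes-field ``GENE_ASSOCIATION:`` strings."""
    doc = libsbml.readSBMLFromFile(str(path))
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        err = doc.getErrorWithSeverity(0, libsbml.LIBSBML_SEV_ERROR)
        raise SBMLFormatError(f"SBML parse failure: {err.getMessage().strip()}")
    sbml_model = doc.getModel()
    if sbml_model is None:
        raise SBMLFormatError("document contains no <model> element")

    compartments = tuple(
        sbml_model.getCompartment(i).getId() for i in range(sbml_model.getNumCompartments())
    )
    mets = []
    for i in range(sbml_model.getNumSpecies()):
        sp = sbml_model.getSpecies(i)
        if sp.getBoundaryCondition():
            continue
        mets.append(
            Metabolite(id=sp.getId(), name=sp.getName(), compartment=sp.getCompartment())
        )

    fbc = sbml_model.getPlugin("fbc")
    declared_genes: set[str] = set()
    gene_labels: dict[str, str] = {}
    if fbc is not None:
        for i in range(fbc.getNumGeneProducts()):
            gp = fbc.getGeneProduct(i)
            label = gp.getLabel() or gp.getId()
            gene_labels[gp.getId()] = label
            declared_genes.add(label)

    biomass_id = None
    if fbc is not None and fbc.getNumObjectives() > 0:
        obj = fbc.getActiveObjective() or fbc.getObjective(0)
        if obj is not None and obj.getNumFluxObjectives() > 0:
            biomass_id = obj.getFluxObjective(0).getReaction()

    param_values = {
        sbml_model.getParameter(i).getId(): sbml_model.getParameter(i).getValue()
        for i in range(sbml_model.getNumParameters())
    }

    rxns = []
    atpm_id = None
    boundary = {
        sbml_model.getSpecies(i).getId()
        for i in range(sbml_model.getNumSpecies())
        if sbml_model.getSpecies(i).getBoundaryCondition()
    }
    for i in range(sbml_model.getNumReactions()):
        rx = sbml_model.getReaction(i)
        stoich: dict[str, float] = {}
        for k in range(rx.getNumReactants()):
            sr = rx.getReactant(k)
            if sr.getSpecies() in boundary:
                continue
            stoich[sr.getSpecies()] = stoich.get(sr.getSpecies(), 0.0) - sr.getStoichiometry()
        for k in range(rx.getNumProducts()):
            sr = rx.getProduct(k)
            if sr.getSpecies() in boundary:
                continue
            stoich[sr.getSpecies()] = stoich.get(sr.getSpecies(), 0.0) + sr.getStoichiometry()
        stoich = {m: c for m, c in stoich.items() if c != 0.0}

        lb, ub = -GLOBAL_BOUND, GLOBAL_BOUND
        rfbc = rx.getPlugin("fbc")
        if rfbc is not None and rfbc.isSetLowerFluxBound():
            lb = param_values.get(rfbc.getLowerFluxBound(), lb)
            ub = param_values.get(rfbc.getUpperFluxBound(), ub)
        elif rx.isSetKineticLaw():
            kl = rx.getKineticLaw()
            for pname, current in (("LOWER_BOUND", lb), ("UPPER_BOUND", ub)):
                p = kl.getParameter(pname)
                if p is not None:
                    if pname == "LOWER_BOUND":
                        lb = p.getValue()
                    else:
                        ub = p.getValue()
        elif not rx.getReversible():
            lb = 0.0

        gpr_expr = GPRExpr.empty()
        if dialect == "fbc" and rfbc is not None and rfbc.isSetGeneProductAssociation():
            assoc = rfbc.getGeneProductAssociation().getAssociation()
            gpr_expr = _association_to_expr(assoc, gene_labels)
        else:
            notes = rx.getNotesString() if rx.isSetNotes() else ""
            gpr_expr = _gpr_from_notes(notes)
        rid = rx.getId()
        name_u = (rx.getName() or rid).upper()
        if "ATPM" in rid.upper() or "MAINTENANCE" in name_u:
            atpm_id = atpm_id or rid
        rxns.append(
            Reaction(
                id=rid,
                stoichiometry=stoich,
                lower_bound=lb,
                upper_bound=ub,
                gpr=gpr_expr,
                name=rx.getName(),
            )
        )
        declared_genes |= gpr_expr.genes()

    if biomass_id is None:
        for r in rxns:
            if "biomass" in r.id.lower():
                biomass_id = r.id
                break

    model = MetabolicModel(
        id=sbml_model.getId() or "model",
        metabolites=tuple(mets),
        reactions=tuple(rxns),
        genes=frozenset(declared_genes),
        biomass_reaction_id=biomass_id,
        atpm_reaction_id=atpm_id,
        compartments=compartments,
    )
    model.validate()
    return model


def _association_to_expr(assoc, gene_labels: dict[str, str]) -> GPRExpr:
    if assoc is None:
        return GPRExpr.empty()
    if isinstance(assoc, libsbml.GeneProductRef):
        ref = assoc.getGeneProduct()
        return GPRExpr.leaf(gene_labels.get(ref, ref))
    children = [
        _association_to_expr(assoc.getAssociation(i), gene_labels)
        for i in range(assoc.getNumAssociations())
    ]
    if isinstance(assoc, libsbml.FbcAnd):
        return GPRExpr.and_(children)
    if isinstance(assoc, libsbml.FbcOr):
        return GPRExpr.or_(children)
    raise SBMLFormatError(f"unsupported gene association node {type(assoc).__name__}")


def _gpr_from_notes(notes: str) -> GPRExpr:
    for line in notes.splitlines():
        text = line.strip()
        for tag in ("GENE_ASSOCIATION:", "GENE ASSOCIATION:"):
            if tag in text:
                raw = text.split(tag, 1)[1]
                raw = raw.replace("</p>", "").replace("</body>", "").replace("</html>", "")
                return parse_gpr(raw.strip())
    return GPRExpr.empty()


def write_model(model: MetabolicModel, path) -> None:
    """Write the model as SBML L3V1 with the fbc-v2 package."""
    model.validate()
    ns = libsbml.SBMLNamespaces(3, 1, "fbc", 2)
    doc = libsbml.SBMLDocument(ns)
    doc.setPackageRequired("fbc", False)
    sm = doc.createModel()
    sm.setId(model.id)
    mplug = sm.getPlugin("fbc")
    mplug.setStrict(True)

    comps = model.compartments or tuple(sorted({m.compartment for m in model.metabolites}))
    for cid in comps:
        c = sm.createCompartment()
        c.setId(cid)
        c.setConstant(True)

    for m in model.metabolites:
        sp = sm.createSpecies()
        sp.setId(m.id)
        sp.setName(m.name)
        sp.setCompartment(m.compartment)
        sp.setHasOnlySubstanceUnits(False)
        sp.setBoundaryCondition(False)
        sp.setConstant(False)

    gene_param_ids: dict[str, str] = {}
    for idx, g in enumerate(sorted(model.genes)):
        if not g:
            raise SBMLFormatError("cannot serialize empty gene identifier")
        gp = mplug.createGeneProduct()
        gid = f"G_{idx}"
        gp.setId(gid)
        gp.setLabel(g)
        gp.setName(g)
        gene_param_ids[g] = gid

    bound_param_ids: dict[float, str] = {}

    def bound_param(value: float) -> str:
        if value not in bound_param_ids:
            p = sm.createParameter()
            pid = f"fb_{len(bound_param_ids)}"
            p.setId(pid)
            p.setValue(value)
            p.setConstant(True)
            bound_param_ids[value] = pid
        return bound_param_ids[value]

    for r in model.reactions:
        rx = sm.createReaction()
        rx.setId(r.id)
        rx.setName(r.name)
        rx.setReversible(r.lower_bound < 0)
        rx.setFast(False)
        for met_id, coeff in sorted(r.stoichiometry.items()):
            sr = rx.createReactant() if coeff < 0 else rx.createProduct()
            sr.setSpecies(met_id)
            sr.setStoichiometry(abs(coeff))
            sr.setConstant(True)
        rfbc = rx.getPlugin("fbc")
        rfbc.setLowerFluxBound(bound_param(r.lower_bound))
        rfbc.setUpperFluxBound(bound_param(r.upper_bound))
        if not r.gpr.is_empty:
            gpa = rfbc.createGeneProductAssociation()
            _fill_association(gpa, r.gpr, gene_param_ids)

    if model.biomass_reaction_id is not None:
        obj = mplug.createObjective()
        obj.setId("obj")
        obj.setType("maximize")
        fo = obj.createFluxObjective()
        fo.setReaction(model.biomass_reaction_id)
        fo.setCoefficient(1.0)
        mplug.setActiveObjectiveId("obj")

    if not libsbml.writeSBMLToFile(doc, str(path)):
        raise SBMLFormatError(f"failed to write SBML to {path}")


def _fill_association(container, expr: GPRExpr, gene_param_ids: dict[str, str]) -> None:
    """Build the fbc association tree node by node (the infix-string
    route rewrites identifiers containing digits, so it is avoided)."""
    if expr.op == "gene":
        ref = container.createGeneProductRef()
        ref.setGeneProduct(gene_param_ids[expr.gene])
        return
    node = container.createAnd() if expr.op == "and" else container.createOr()
    for child in expr.children:
        _fill_association(node, child, gene_param_ids)
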