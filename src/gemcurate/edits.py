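"""Typed model modifications, application, and global/conditional vetting.

Every proposed correction to a model — a suppression, an added
reaction, a GPR rewrite, a biomass edit, a medium amendment — is a
``Modification`` carrying a kind, a kind-specific payload, and a
provenance tag for the human literature-vetting loop.  A modification
is *global* when, re-screened against the full phenotype table, it
flips no previously correct prediction to incorrect; otherwise it is
*conditional* (medium-specific), and verdicts are tracked per medium
since an edit may be conditional in one medium and global in another.
``batch_curate`` walks a classified mismatch list in a fixed order,
invokes the restoration or suppression engine per class, auto-accepts
only global modifications, and re-baselines after each acceptance.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

from .gpr import parse_gpr, substitute_false
from .model import GLOBAL_BOUND, MediumSpec, MetabolicModel, Metabolite, Reaction, apply_medium

__all__ = [
    "Modification",
    "VettingReport",
    "CurationLedger",
    "MODIFICATION_KINDS",
    "apply_modification",
    "apply_with_inverse",
    "vet_modification",
    "batch_curate",
]

MODIFICATION_KINDS = (
    "reversibility_relaxation",
    "reaction_addition",
    "transport_addition",
    "exchange_addition",
    "reaction_suppression",
    "gene_suppression",
    "gpr_change",
    "biomass_substitute",
    "biomass_proxy_pool",
    "medium_component",
    "snapshot_restore",  # internal: inverse of any structural edit
)

PROVENANCE_LEVELS = ("supported", "uncorroborated", "rejected")


@dataclass(frozen=True)
class Modification:
    kind: str
    payload: Mapping
    provenance: str = "uncorroborated"
    note: str = ""

    def __post_init__(self):
        if self.kind not in MODIFICATION_KINDS:
            raise ValueError(f"unknown modification kind {self.kind!r}")
        if self.provenance not in PROVENANCE_LEVELS:
            raise ValueError(f"unknown provenance {self.provenance!r}")

    def describe(self) -> str:
        p = self.payload
        if self.kind == "reversibility_relaxation":
            return f"relax {p['reaction_id']}"
        if self.kind in ("reaction_addition", "transport_addition", "exchange_addition"):
            return f"add {p['reaction'].id}"
        if self.kind == "reaction_suppression":
            return f"suppress reaction {p['reaction_id']}"
        if self.kind == "gene_suppression":
            return f"suppress gene {p['gene_id']}"
        if self.kind == "gpr_change":
            return f"GPR of {p['reaction_id']} -> {p['gpr']}"
        if self.kind == "biomass_substitute":
            return f"biomass: {p['remove']} -> {p['add_reactant']}/{p['add_product']}"
        if self.kind == "biomass_proxy_pool":
            return f"biomass: {p['remove']} -> proxy {p['proxy']}"
        if self.kind == "medium_component":
            return f"medium += {p['compound']} @ {p['uptake_level']}"
        return self.kind


# ---------------------------------------------------------------------------
# application
# ---------------------------------------------------------------------------

def apply_modification(model: MetabolicModel, mod: Modification) -> MetabolicModel:
    """Return an edited copy of the model; the original is untouched.

    ``medium_component`` modifications do not change model structure
    here beyond opening/stubbing uptake (they conceptually belong to
    the medium; see ``amend_medium``).
    """
    new_model, _ = apply_with_inverse(model, mod)
    return new_model


def apply_with_inverse(
    model: MetabolicModel, mod: Modification
) -> tuple[MetabolicModel, Modification]:
    """Apply and also return the inverse modification (a snapshot of the
    touched reactions/metabolites) so the edit can be rolled back."""
    p = mod.payload
    kind = mod.kind

    if kind == "snapshot_restore":
        restored = MetabolicModel(
            id=model.id,
            metabolites=tuple(p["metabolites"]),
            reactions=tuple(p["reactions"]),
            genes=frozenset(p["genes"]),
            biomass_reaction_id=p["biomass_reaction_id"],
            atpm_reaction_id=p["atpm_reaction_id"],
            background_deletions=model.background_deletions,
            compartments=model.compartments,
        )
        return restored, _snapshot(model)

    inverse = _snapshot(model)

    if kind == "reversibility_relaxation":
        r = model.reaction(p["reaction_id"])
        return model.with_reactions(updated=[r.with_bounds(-GLOBAL_BOUND, r.upper_bound)]), inverse

    if kind in ("reaction_addition", "transport_addition", "exchange_addition"):
        return (
            model.with_reactions(
                added=[p["reaction"]], added_metabolites=tuple(p.get("metabolites", ()))
            ),
            inverse,
        )

    if kind == "reaction_suppression":
        r = model.reaction(p["reaction_id"])
        return model.with_reactions(updated=[r.with_bounds(0.0, 0.0)]), inverse

    if kind == "gene_suppression":
        gene = p["gene_id"]
        if gene not in model.genes:
            raise ValueError(f"gene {gene!r} not in model")
        updated = []
        for r in model.reactions:
            if gene not in r.gpr.genes():
                continue
            simplified = substitute_false(r.gpr, (gene,))
            if simplified is None:
                updated.append(r.with_bounds(0.0, 0.0))
            else:
                updated.append(r.with_gpr(simplified))
        return model.with_reactions(updated=updated), inverse

    if kind == "gpr_change":
        r = model.reaction(p["reaction_id"])
        gpr = p["gpr"]
        if isinstance(gpr, str):
            gpr = parse_gpr(gpr)
        new_genes = gpr.genes() - model.genes
        return (
            model.with_reactions(updated=[r.with_gpr(gpr)], added_genes=new_genes),
            inverse,
        )

    if kind == "biomass_substitute":
        bio = model.biomass_reaction
        remove, reac, prod = p["remove"], p["add_reactant"], p["add_product"]
        stoich = dict(bio.stoichiometry)
        if remove not in stoich or stoich[remove] >= 0:
            raise ValueError(f"{remove!r} is not a biomass reactant")
        coeff = p.get("coefficient", -stoich.pop(remove))
        stoich[reac] = stoich.get(reac, 0.0) - coeff
        stoich[prod] = stoich.get(prod, 0.0) + coeff
        mets = [
            Metabolite(id=mid, compartment=_comp(mid))
            for mid in (reac, prod)
            if not model.has_metabolite(mid)
        ]
        return (
            model.with_reactions(
                updated=[replace(bio, stoichiometry=stoich)], added_metabolites=mets
            ),
            inverse,
        )

    if kind == "biomass_proxy_pool":
        bio = model.biomass_reaction
        remove = p["remove"]
        proxy = p["proxy"]
        proxy_id = proxy.id if isinstance(proxy, Metabolite) else proxy
        producers: Sequence[Reaction] = p["producers"]
        if not producers:
            raise ValueError("a proxy pool needs at least one producing reaction")
        stoich = dict(bio.stoichiometry)
        if remove not in stoich or stoich[remove] >= 0:
            raise ValueError(f"{remove!r} is not a biomass reactant")
        coeff = stoich.pop(remove)
        stoich[proxy_id] = stoich.get(proxy_id, 0.0) + coeff
        mets = []
        if not model.has_metabolite(proxy_id):
            mets.append(
                proxy if isinstance(proxy, Metabolite)
                else Metabolite(id=proxy_id, compartment=_comp(proxy_id))
            )
        return (
            model.with_reactions(
                updated=[replace(bio, stoichiometry=stoich)],
                added=list(producers),
                added_metabolites=mets,
            ),
            inverse,
        )

    if kind == "medium_component":
        from .phenotypes import open_supplement_uptake

        return (
            open_supplement_uptake(model, p["compound"], p["uptake_level"]),
            inverse,
        )

    raise ValueError(f"unhandled modification kind {kind!r}")


def _snapshot(model: MetabolicModel) -> Modification:
    return Modification(
        kind="snapshot_restore",
        payload={
            "metabolites": model.metabolites,
            "reactions": model.reactions,
            "genes": model.genes,
            "biomass_reaction_id": model.biomass_reaction_id,
            "atpm_reaction_id": model.atpm_reaction_id,
        },
    )


def _comp(met_id: str) -> str:
    return met_id.rsplit("_", 1)[1] if "_" in met_id else "c"


# ---------------------------------------------------------------------------
# vetting
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VettingReport:
    verdicts: Mapping[str, str]  # medium name -> "global" | "conditional"
    flipped: tuple  # (medium, genes, old label, new label)
    scope: str = "single+double"

    @property
    def verdict(self) -> str:
        return "global" if all(v == "global" for v in self.verdicts.values()) else "conditional"


def _classified(model, medium, calls, threshold_fraction):
    from .phenotypes import classify_records
    from .screens import essential_genes, find_sl_pairs

    constrained = apply_medium(model, medium)
    screen = essential_genes(constrained, medium.name, threshold_fraction)
    need_pairs = any(len(c.genes) == 2 for c in calls)
    sl = (
        find_sl_pairs(constrained, medium.name, threshold_fraction, single_screen=screen)
        if need_pairs
        else None
    )
    records, _ = classify_records(calls, screen, sl, model_genes=model.genes)
    return {r.genes: r for r in records}


def vet_modification(
    model: MetabolicModel,
    mod: Modification,
    calls: Sequence,
    media: Sequence[MediumSpec],
    threshold_fraction: float = 0.01,
    scope: str = "single+double",
    baseline: Mapping | None = None,
) -> VettingReport:
    """Per-medium global/conditional verdict for one modification.

    ``baseline`` may carry precomputed per-medium classifications
    ({medium name: {genes: MismatchRecord}}) to avoid rescreening.
    """
    verdicts: dict[str, str] = {}
    flipped: list[tuple] = []
    for medium in media:
        calls_m = [c for c in calls if not c.medium or c.medium == medium.name]
        if scope == "single":
            calls_m = [c for c in calls_m if len(c.genes) == 1]
        before = (
            baseline[medium.name]
            if baseline is not None and medium.name in baseline
            else _classified(model, medium, calls_m, threshold_fraction)
        )
        if mod.kind == "medium_component":
            edited_model, edited_medium = medium_component_application(
                model, medium, mod.payload["compound"], mod.payload["uptake_level"]
            )
        else:
            edited_model, edited_medium = apply_modification(model, mod), medium
        after = _classified(edited_model, edited_medium, calls_m, threshold_fraction)
        bad = []
        for genes, rec in before.items():
            if rec.is_consistent and genes in after and not after[genes].is_consistent:
                bad.append((medium.name, genes, rec.label, after[genes].label))
        verdicts[medium.name] = "global" if not bad else "conditional"
        flipped.extend(bad)
    return VettingReport(verdicts=verdicts, flipped=tuple(flipped), scope=scope)


def medium_component_application(
    model: MetabolicModel, medium: MediumSpec, compound: str, level: float
) -> tuple[MetabolicModel, MediumSpec]:
    """Realize a medium amendment: make sure the compound's exchange
    exists on the model (stubbing exchange/transport if needed) and add
    it to the medium's supplements so ``apply_medium`` keeps it open."""
    from .phenotypes import open_supplement_uptake

    edited = open_supplement_uptake(model, compound, level)
    base = compound.rsplit("_", 1)[0] if "_" in compound else compound
    ex_id = None
    for r in edited.reactions:
        if r.is_exchange and _stem(next(iter(r.stoichiometry))) == base:
            ex_id = r.id
            break
    if ex_id is None:  # fall back to the stub naming convention
        ex_id = f"EX_{base}_supp"
    supp = dict(medium.supplements)
    supp[ex_id] = level
    return edited, replace(medium, supplements=supp)


def _stem(met_id: str) -> str:
    return met_id.rsplit("_", 1)[0] if "_" in met_id else met_id


# ---------------------------------------------------------------------------
# batch curation
# ---------------------------------------------------------------------------

_CLASS_ORDER = ("NGG", "GNG", "GSL", "ESSL", "SLG", "SLES")


@dataclass
class CurationEntry:
    mismatch_genes: tuple[str, ...]
    mismatch_label: str
    modifications: tuple[Modification, ...]
    verdict: str  # global | conditional | unresolved
    accepted: bool
    note: str = ""


@dataclass
class CurationLedger:
    entries: list[CurationEntry] = field(default_factory=list)
    metrics_before: Mapping | None = None
    metrics_after: Mapping | None = None
    final_model: MetabolicModel | None = None


def batch_curate(
    model: MetabolicModel,
    calls: Sequence,
    media: Sequence[MediumSpec],
    db_reactions: Sequence[Reaction] = (),
    n_suppressions: int = 2,
    max_additions: int = 2,
    threshold_fraction: float = 0.01,
    suppression_level: str = "gene",
) -> CurationLedger:
    """Resolve a classified mismatch list, class by class.

    Mismatch classes are visited in a fixed order (falsely lethal
    singles first, then falsely viable singles, then the pair classes);
    within a class, mismatches are visited in lexicographic gene order.
    For each mismatch the matching engine is invoked — restoration for
    NGG/SLG, suppression for GNG/GSL/SLES — candidate fixes are vetted
    against the full phenotype table on every medium, and only global,
    non-rejected modifications are accepted.  The working model is
    re-baselined after each acceptance, so the process is sequential
    and order-dependent by design; replay is deterministic.
    """
    from .phenotypes import classify_records, compute_metrics
    from .restore import build_candidate_pool, restore_growth
    from .screens import essential_genes, find_sl_pairs
    from .suppress import min_gene_suppressions, min_reaction_suppressions

    ledger = CurationLedger()
    working = model

    def classify_all(m: MetabolicModel):
        per_medium = {}
        all_records = []
        for medium in media:
            calls_m = [c for c in calls if not c.medium or c.medium == medium.name]
            constrained = apply_medium(m, medium)
            screen = essential_genes(constrained, medium.name, threshold_fraction)
            sl = find_sl_pairs(
                constrained, medium.name, threshold_fraction, single_screen=screen
            ) if any(len(c.genes) == 2 for c in calls_m) else None
            records, _ = classify_records(calls_m, screen, sl, model_genes=m.genes)
            per_medium[medium.name] = {r.genes: r for r in records}
            all_records.extend(records)
        return per_medium, all_records

    baseline, records0 = classify_all(working)
    ledger.metrics_before = compute_metrics(records0)

    for cls in _CLASS_ORDER:
        targets = sorted(
            {
                (med, rec.genes)
                for med, recs in baseline.items()
                for rec in recs.values()
                if rec.label == cls
            }
        )
        for med_name, genes in targets:
            medium = next(m for m in media if m.name == med_name)
            constrained = apply_medium(working, medium)
            # the mismatch may have been fixed by an earlier acceptance
            rec = baseline.get(med_name, {}).get(genes)
            if rec is None or rec.label != cls:
                continue
            if cls in ("NGG", "SLG"):
                pool = build_candidate_pool(working, db_reactions=db_reactions)
                found = restore_growth(
                    constrained, genes, pool, max_additions, threshold_fraction
                )
                proposals = [tuple(sol.modifications()) for sol in found if sol.additions]
            else:  # GNG, GSL, ESSL, SLES -> suppression engines
                solver = (
                    min_gene_suppressions
                    if suppression_level == "gene"
                    else min_reaction_suppressions
                )
                found = solver(constrained, genes, n_suppressions, threshold_fraction)
                proposals = []
                from .gpr import FICTITIOUS_PREFIX

                def as_mod(s: str) -> Modification:
                    if suppression_level == "reaction":
                        return Modification(
                            kind="reaction_suppression", payload={"reaction_id": s}
                        )
                    if s.startswith(FICTITIOUS_PREFIX):
                        # a gene-free reaction reached through its stand-in gene
                        return Modification(
                            kind="reaction_suppression",
                            payload={"reaction_id": s[len(FICTITIOUS_PREFIX):]},
                        )
                    return Modification(kind="gene_suppression", payload={"gene_id": s})

                for sol in found:
                    if not sol.suppressed:
                        continue
                    proposals.append(tuple(as_mod(s) for s in sorted(sol.suppressed)))
            accepted = False
            chosen: tuple[Modification, ...] = ()
            verdict = "unresolved"
            for mods in proposals:
                candidate_model = working
                ok = True
                for m in mods:
                    if m.provenance == "rejected":
                        ok = False
                        break
                    report = vet_modification(
                        candidate_model, m, calls, media, threshold_fraction
                    )
                    if report.verdict != "global":
                        ok = False
                        verdict = "conditional"
                        chosen = mods
                        break
                    candidate_model = apply_modification(candidate_model, m)
                if ok:
                    working = candidate_model
                    accepted = True
                    verdict = "global"
                    chosen = mods
                    break
            if proposals:
                ledger.entries.append(
                    CurationEntry(
                        mismatch_genes=genes,
                        mismatch_label=cls,
                        modifications=chosen or proposals[0],
                        verdict=verdict,
                        accepted=accepted,
                    )
                )
            else:
                ledger.entries.append(
                    CurationEntry(
                        mismatch_genes=genes,
                        mismatch_label=cls,
                        modifications=(),
                        verdict="unresolved",
                        accepted=False,
                        note="no candidate fix found within budget",
                    )
                )
            if accepted:
                baseline, _ = classify_all(working)

    _, records1 = classify_all(working)
    ledger.metrics_after = compute_metrics(records1)
    ledger.final_model = working
    return ledger
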