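"""Deterministic synthetic toy models with planted ground truth.

``generate_fixture`` composes small metabolic networks from motifs on a
linear carbon backbone — a glucose exchange/transport head, an ATP
maintenance drain, and one branch per planted feature, each feeding a
dedicated biomass precursor:

* an essential gene: a single-gene reaction uniquely making a precursor;
* an isozyme SL pair: one precursor reaction gated by ``a or b``;
* a parallel-pathway SL pair: two single-gene routes to one precursor;
* a blocked dead-end chain rooted in a no-consumption metabolite;
* a falsely lethal mutant (NGG) rescued by a matching database reaction;
* a falsely viable mutant (GNG) fixed by suppressing its isozyme partner;
* a falsely viable pair (GSL) fixed by suppressing a gene-free bypass.

Matching experimental calls are emitted so classifying the generated
model against them yields exactly the planted mismatch classes, and the
planted truth is re-derived by the exhaustive screens before the
fixture is returned — a fixture that fails its own audit raises.

``motif_fixtures`` additionally provides hand-built miniatures of
published curation case studies (pyrimidine-salvage suppression, the
phosphoribosylpyrophosphate-synthetase GPR rewrite, tRNA charging in
the biomass equation, a medium-dependent conditional suppression),
used as regression networks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .gpr import GPRExpr, parse_gpr
from .model import (
    GLOBAL_BOUND,
    MediumSpec,
    MetabolicModel,
    Metabolite,
    Reaction,
)

__all__ = [
    "FixtureSpec",
    "Fixture",
    "FixtureGenerationError",
    "generate_fixture",
    "motif_fixtures",
]


class FixtureGenerationError(RuntimeError):
    """A generated fixture failed its own planted-truth audit."""


@dataclass(frozen=True)
class FixtureSpec:
    """Counts of planted features and the generation seed."""

    seed: int = 0
    n_essential: int = 1
    n_isozyme_sl: int = 1
    n_parallel_sl: int = 1
    n_blocked_chains: int = 1
    n_ngg: int = 1
    n_gng: int = 1
    n_gsl: int = 1
    n_decoys: int = 2
    backbone_length: int = 3
    glucose_uptake: float = 10.0
    atpm_flux: float = 1.0

    def total_features(self) -> int:
        return (
            self.n_essential + self.n_isozyme_sl + self.n_parallel_sl
            + self.n_blocked_chains + self.n_ngg + self.n_gng + self.n_gsl
        )


@dataclass
class Fixture:
    model: MetabolicModel
    medium: MediumSpec
    db_reactions: list[Reaction]
    calls: list  # ExperimentalCall
    ground_truth: dict
    spec: FixtureSpec | None = None


def _leaf(g):
    return GPRExpr.leaf(g)


def generate_fixture(spec: FixtureSpec, verify: bool = True) -> Fixture:
    """Build a toy model with the planted features of ``spec``.

    Deterministic for a given seed.  With ``verify`` (default) the
    exhaustive screens re-derive the planted truth and a mismatch
    raises ``FixtureGenerationError`` — fixtures cannot lie.
    """
    from .phenotypes import ExperimentalCall

    rng = np.random.default_rng(spec.seed)
    mets: list[Metabolite] = []
    rxns: list[Reaction] = []
    calls: list = []
    db: list[Reaction] = []
    truth: dict = {
        "essential_genes": set(),
        "sl_pairs": set(),
        "blocked_reactions": set(),
        "no_consumption": set(),
        "mismatches": {},  # label -> list of (genes, resolution dict)
    }

    def met(mid: str, comp: str = "c") -> str:
        mets.append(Metabolite(id=mid, compartment=comp))
        return mid

    def rxn(rid: str, stoich: dict, gpr: GPRExpr | None = None,
            lb: float = 0.0, ub: float = GLOBAL_BOUND) -> str:
        rxns.append(
            Reaction(id=rid, stoichiometry=stoich,
                     lower_bound=lb, upper_bound=ub,
                     gpr=gpr or GPRExpr.empty())
        )
        return rid

    # backbone: glucose head, carbon chain, ATP maintenance
    met("glc_e", "e")
    backbone = [met("m0_c")]
    rxn("EX_glc", {"glc_e": -1.0}, lb=-GLOBAL_BOUND)
    rxn("GLCt", {"glc_e": -1.0, "m0_c": 1.0})
    n_nodes = max(2, spec.backbone_length)
    for i in range(1, n_nodes):
        backbone.append(met(f"m{i}_c"))
        rxn(f"B{i}", {f"m{i-1}_c": -1.0, f"m{i}_c": 1.0})
    met("atp_c")
    rxn("ATPS", {"m0_c": -1.0, "atp_c": 1.0})
    rxn("ATPM", {"atp_c": -1.0})

    precursors: list[str] = []

    def node() -> str:
        return backbone[int(rng.integers(0, len(backbone)))]

    def precursor(tag: str) -> str:
        p = met(f"p_{tag}_c")
        precursors.append(p)
        return p

    # --- planted motifs ------------------------------------------------
    for i in range(spec.n_essential):
        g = f"gE{i}"
        p = precursor(f"ess{i}")
        rxn(f"RE{i}", {node(): -1.0, p: 1.0}, _leaf(g))
        truth["essential_genes"].add(g)
        calls.append(ExperimentalCall(genes=(g,), medium="minimal", observed="NG"))

    for i in range(spec.n_isozyme_sl):
        a, b = f"gIa{i}", f"gIb{i}"
        p = precursor(f"iso{i}")
        rxn(f"RI{i}", {node(): -1.0, p: 1.0}, parse_gpr(f"{a} or {b}"))
        truth["sl_pairs"].add(frozenset((a, b)))
        calls.append(
            ExperimentalCall(genes=(a, b), medium="minimal", observed="NG", cause="SL")
        )

    for i in range(spec.n_parallel_sl):
        a, b = f"gPa{i}", f"gPb{i}"
        p = precursor(f"par{i}")
        rxn(f"RPa{i}", {node(): -1.0, p: 1.0}, _leaf(a))
        rxn(f"RPb{i}", {node(): -1.0, p: 1.0}, _leaf(b))
        truth["sl_pairs"].add(frozenset((a, b)))
        calls.append(
            ExperimentalCall(genes=(a, b), medium="minimal", observed="NG", cause="SL")
        )

    for i in range(spec.n_blocked_chains):
        g = f"gD{i}"
        d1 = met(f"d{i}a_c")
        d2 = met(f"d{i}b_c")
        r1 = rxn(f"RD{i}a", {node(): -1.0, d1: 1.0}, _leaf(g))
        r2 = rxn(f"RD{i}b", {d1: -1.0, d2: 1.0})
        truth["blocked_reactions"] |= {r1, r2}
        truth["no_consumption"] |= {d1, d2}
        calls.append(ExperimentalCall(genes=(g,), medium="minimal", observed="G"))

    for i in range(spec.n_ngg):
        g = f"gN{i}"
        p = precursor(f"ngg{i}")
        src = node()
        rxn(f"RN{i}", {src: -1.0, p: 1.0}, _leaf(g))
        alt_src = node()
        db.append(
            Reaction(id=f"DBR{i}", stoichiometry={alt_src: -1.0, p: 1.0},
                     lower_bound=0.0, upper_bound=GLOBAL_BOUND)
        )
        truth["essential_genes"].add(g)  # essential until the db fix lands
        truth["mismatches"].setdefault("NGG", []).append(
            ((g,), {"kind": "reaction_addition", "reaction_id": f"DBR{i}"})
        )
        calls.append(ExperimentalCall(genes=(g,), medium="minimal", observed="G"))

    for i in range(spec.n_gng):
        main, iso = f"gGm{i}", f"gGi{i}"
        p = precursor(f"gng{i}")
        rxn(f"RG{i}", {node(): -1.0, p: 1.0}, parse_gpr(f"{main} or {iso}"))
        truth["sl_pairs"].add(frozenset((main, iso)))
        truth["mismatches"].setdefault("GNG", []).append(
            ((main,), {"kind": "gene_suppression", "gene_id": iso})
        )
        calls.append(ExperimentalCall(genes=(main,), medium="minimal", observed="NG"))

    for i in range(spec.n_gsl):
        a, b = f"gSa{i}", f"gSb{i}"
        p = precursor(f"gsl{i}")
        rxn(f"RSa{i}", {node(): -1.0, p: 1.0}, _leaf(a))
        rxn(f"RSb{i}", {node(): -1.0, p: 1.0}, _leaf(b))
        bypass = rxn(f"RSc{i}", {node(): -1.0, p: 1.0})
        truth["mismatches"].setdefault("GSL", []).append(
            ((a, b), {"kind": "reaction_suppression", "reaction_id": bypass})
        )
        calls.append(
            ExperimentalCall(genes=(a, b), medium="minimal", observed="NG", cause="SL")
        )

    # decoys: redundant backbone bridges with their own genes; they can
    # never create new lethals because the backbone stays intact
    for i in range(spec.n_decoys):
        if len(backbone) < 2:
            break
        j = int(rng.integers(0, len(backbone) - 1))
        k = int(rng.integers(j + 1, len(backbone)))
        g = f"gX{i}"
        rxn(f"RX{i}", {backbone[j]: -1.0, backbone[k]: 1.0}, _leaf(g))
        calls.append(ExperimentalCall(genes=(g,), medium="minimal", observed="G"))
    # a decoy database entry that only duplicates an existing backbone step
    if len(backbone) >= 2:
        db.append(
            Reaction(id="DBX0", stoichiometry={backbone[0]: -1.0, backbone[-1]: 1.0},
                     lower_bound=0.0, upper_bound=GLOBAL_BOUND)
        )

    if not precursors:
        precursors.append(met("p_base_c"))
        rxn("RBASE", {backbone[-1]: -1.0, "p_base_c": 1.0})
    rxn("BIOMASS", {p: -1.0 for p in precursors})

    genes = frozenset().union(*(r.gpr.genes() for r in rxns)) if rxns else frozenset()
    model = MetabolicModel(
        id=f"fixture_seed{spec.seed}",
        metabolites=tuple(mets),
        reactions=tuple(rxns),
        genes=genes,
        biomass_reaction_id="BIOMASS",
        atpm_reaction_id="ATPM",
        compartments=("c", "e"),
    )
    model.validate()
    medium = MediumSpec(
        name="minimal",
        uptake_limits={"EX_glc": spec.glucose_uptake},
        atpm_flux=spec.atpm_flux,
    )
    fixture = Fixture(
        model=model, medium=medium, db_reactions=db,
        calls=calls, ground_truth=truth, spec=spec,
    )
    if verify:
        _audit(fixture)
    return fixture


def _audit(fx: Fixture) -> None:
    """Re-derive planted truth with the exhaustive screens."""
    from .model import apply_medium
    from .screens import essential_genes, find_sl_pairs
    from .gaps import find_gap_metabolites

    m = apply_medium(fx.model, fx.medium)
    screen = essential_genes(m)
    if screen.essential_genes != frozenset(fx.ground_truth["essential_genes"]):
        raise FixtureGenerationError(
            "planted essentials not recovered: expected "
            f"{sorted(fx.ground_truth['essential_genes'])}, got "
            f"{sorted(screen.essential_genes)}"
        )
    sl = find_sl_pairs(m, single_screen=screen)
    if sl.pairs != frozenset(fx.ground_truth["sl_pairs"]):
        raise FixtureGenerationError(
            "planted SL pairs not recovered: expected "
            f"{sorted(map(sorted, fx.ground_truth['sl_pairs']))}, got "
            f"{sorted(map(sorted, sl.pairs))}"
        )
    if fx.ground_truth["no_consumption"]:
        report = find_gap_metabolites(fx.model)
        missing = frozenset(fx.ground_truth["no_consumption"]) - report.no_consumption
        if missing:
            raise FixtureGenerationError(
                f"planted dead-end metabolites not flagged: {sorted(missing)}"
            )
    return None


# ---------------------------------------------------------------------------
# hand-built literature motifs
# ---------------------------------------------------------------------------

def _toy(mets, rxns, media_extra=None, atpm=True, model_id="motif"):
    metabolites = [Metabolite(id=m, compartment=m.rsplit("_", 1)[1]) for m in mets]
    reactions = list(rxns)
    genes = frozenset().union(*(r.gpr.genes() for r in reactions))
    model = MetabolicModel(
        id=model_id,
        metabolites=tuple(metabolites),
        reactions=tuple(reactions),
        genes=genes,
        biomass_reaction_id="BIOMASS",
        atpm_reaction_id="ATPM" if atpm else None,
        compartments=tuple(sorted({m.compartment for m in metabolites})),
    )
    model.validate()
    return model


def _r(rid, stoich, gpr="", lb=0.0, ub=GLOBAL_BOUND):
    return Reaction(id=rid, stoichiometry=stoich, lower_bound=lb,
                    upper_bound=ub, gpr=parse_gpr(gpr))


def ump_salvage_fixture() -> Fixture:
    """Two gene-gated de-novo routes to a biomass precursor plus a
    gene-free salvage bypass; the gene pair is falsely viable (GSL) and
    suppressing the bypass reaction is the unique single-reaction fix."""
    from .phenotypes import ExperimentalCall

    mets = ["glc_e", "m0_c", "atp_c", "ump_c"]
    rxns = [
        _r("EX_glc", {"glc_e": -1.0}, lb=-GLOBAL_BOUND),
        _r("GLCt", {"glc_e": -1.0, "m0_c": 1.0}),
        _r("ATPS", {"m0_c": -1.0, "atp_c": 1.0}),
        _r("ATPM", {"atp_c": -1.0}),
        _r("DENOVO1", {"m0_c": -1.0, "ump_c": 1.0}, "gFUR"),
        _r("DENOVO2", {"m0_c": -1.0, "ump_c": 1.0}, "gURA"),
        _r("SALVAGE", {"m0_c": -1.0, "ump_c": 1.0}),
        _r("BIOMASS", {"ump_c": -1.0}),
    ]
    model = _toy(mets, rxns, model_id="ump_salvage")
    medium = MediumSpec(name="minimal", uptake_limits={"EX_glc": 10.0})
    calls = [
        ExperimentalCall(genes=("gFUR", "gURA"), medium="minimal",
                         observed="NG", cause="SL")
    ]
    truth = {"unique_reaction_suppression": "SALVAGE",
             "target_pair": ("gFUR", "gURA")}
    return Fixture(model, medium, [], calls, truth)


REVISED_PRPPS_GPR = "(PRS1 and PRS3) or ((PRS2 or PRS4) and PRS5)"
ORIGINAL_PRPPS_GPR = "PRS1 or PRS2 or PRS3 or PRS4 or PRS5"
#: deletion combinations that must be lethal under the revised rule
PRPPS_LETHAL_COMBOS = (
    ("PRS1", "PRS5"),
    ("PRS3", "PRS5"),
    ("PRS1", "PRS2", "PRS4"),
    ("PRS3", "PRS2", "PRS4"),
)


def prpps_gpr_fixture() -> Fixture:
    """Five isozyme genes on one essential reaction; the GPR rewrite to
    a complex/isozyme mixture makes four listed combinations lethal."""
    from .phenotypes import ExperimentalCall

    mets = ["glc_e", "m0_c", "atp_c", "prpp_c"]
    rxns = [
        _r("EX_glc", {"glc_e": -1.0}, lb=-GLOBAL_BOUND),
        _r("GLCt", {"glc_e": -1.0, "m0_c": 1.0}),
        _r("ATPS", {"m0_c": -1.0, "atp_c": 1.0}),
        _r("ATPM", {"atp_c": -1.0}),
        _r("PRPPS", {"m0_c": -1.0, "prpp_c": 1.0}, ORIGINAL_PRPPS_GPR),
        _r("BIOMASS", {"prpp_c": -1.0}),
    ]
    model = _toy(mets, rxns, model_id="prpps_gpr")
    medium = MediumSpec(name="minimal", uptake_limits={"EX_glc": 10.0})
    calls = [
        ExperimentalCall(genes=combo[:2], medium="minimal", observed="NG", cause="SL")
        for combo in PRPPS_LETHAL_COMBOS[:2]
    ]
    truth = {
        "reaction": "PRPPS",
        "revised_gpr": REVISED_PRPPS_GPR,
        "lethal_combos": PRPPS_LETHAL_COMBOS,
    }
    return Fixture(model, medium, [], calls, truth)


def trna_charging_fixture() -> Fixture:
    """A tRNA-charging reaction blocked by its dead-end charged-tRNA
    product; swapping the amino acid for the charged/uncharged tRNA
    pair in the biomass reaction unblocks it and makes it essential."""
    from .phenotypes import ExperimentalCall

    mets = ["glc_e", "m0_c", "atp_c", "trp_c", "trnatrp_c", "trptrna_c"]
    rxns = [
        _r("EX_glc", {"glc_e": -1.0}, lb=-GLOBAL_BOUND),
        _r("GLCt", {"glc_e": -1.0, "m0_c": 1.0}),
        _r("ATPS", {"m0_c": -1.0, "atp_c": 1.0}),
        _r("ATPM", {"atp_c": -1.0}),
        _r("TRPSYN", {"m0_c": -1.0, "trp_c": 1.0}),
        _r("TRPTRS", {"trp_c": -1.0, "trnatrp_c": -1.0, "trptrna_c": 1.0}, "gWRS"),
        _r("BIOMASS", {"trp_c": -1.0}),
    ]
    model = _toy(mets, rxns, model_id="trna_charging")
    medium = MediumSpec(name="minimal", uptake_limits={"EX_glc": 10.0})
    calls = [ExperimentalCall(genes=("gWRS",), medium="minimal", observed="NG")]
    truth = {
        "blocked_reaction": "TRPTRS",
        "biomass_substitute": {
            "remove": "trp_c", "add_reactant": "trptrna_c", "add_product": "trnatrp_c",
        },
        "gene": "gWRS",
    }
    return Fixture(model, medium, [], calls, truth)


def conditional_suppression_fixture() -> tuple[Fixture, MediumSpec]:
    """A suppression that is conditional in one medium, global in another.

    The pair (gMa, gMb) is falsely viable through a bypass gated by gC;
    suppressing gC fixes the pair, but gC also backs up gZ's route to a
    second precursor.  On the poor medium that flips gZ's correct
    viable prediction (conditional); on the rich medium the precursor
    is fed from the environment, so no correct call flips (global).
    Returns (fixture on the poor medium, the rich medium).
    """
    from .phenotypes import ExperimentalCall

    mets = ["glc_e", "pz_e", "m0_c", "atp_c", "pm_c", "pz_c"]
    rxns = [
        _r("EX_glc", {"glc_e": -1.0}, lb=-GLOBAL_BOUND),
        _r("EX_pz", {"pz_e": -1.0}, lb=-GLOBAL_BOUND),
        _r("GLCt", {"glc_e": -1.0, "m0_c": 1.0}),
        _r("PZt", {"pz_e": -1.0, "pz_c": 1.0}),
        _r("ATPS", {"m0_c": -1.0, "atp_c": 1.0}),
        _r("ATPM", {"atp_c": -1.0}),
        _r("RM", {"m0_c": -1.0, "pm_c": 1.0}, "gMa or gMb"),
        _r("RMBYPASS", {"m0_c": -1.0, "pm_c": 1.0}, "gC"),
        _r("RZ", {"m0_c": -1.0, "pz_c": 1.0}, "gZ or gC"),
        _r("BIOMASS", {"pm_c": -1.0, "pz_c": -1.0}),
    ]
    model = _toy(mets, rxns, model_id="conditional_suppression")
    poor = MediumSpec(name="minimal", uptake_limits={"EX_glc": 10.0})
    rich = MediumSpec(name="rich", uptake_limits={"EX_glc": 10.0, "EX_pz": 10.0})
    calls = [
        ExperimentalCall(genes=("gMa", "gMb"), medium="", observed="NG", cause="SL"),
        ExperimentalCall(genes=("gZ",), medium="", observed="G"),
    ]
    truth = {"suppression": "gC", "conditional_in": "minimal", "global_in": "rich"}
    return Fixture(model, poor, [], calls, truth), rich


def isozyme_triple_fixture() -> Fixture:
    """Three OR-isozymes on an essential reaction; with two deleted,
    suppressing the third is the unique single-gene fix."""
    from .phenotypes import ExperimentalCall

    mets = ["glc_e", "m0_c", "atp_c", "asn_c"]
    rxns = [
        _r("EX_glc", {"glc_e": -1.0}, lb=-GLOBAL_BOUND),
        _r("GLCt", {"glc_e": -1.0, "m0_c": 1.0}),
        _r("ATPS", {"m0_c": -1.0, "atp_c": 1.0}),
        _r("ATPM", {"atp_c": -1.0}),
        _r("ASNS", {"m0_c": -1.0, "asn_c": 1.0}, "gASN1 or gASN2 or gASN3"),
        _r("BIOMASS", {"asn_c": -1.0}),
    ]
    model = _toy(mets, rxns, model_id="isozyme_triple")
    medium = MediumSpec(name="minimal", uptake_limits={"EX_glc": 10.0})
    calls = [
        ExperimentalCall(genes=("gASN1", "gASN2"), medium="minimal",
                         observed="NG", cause="SL")
    ]
    truth = {"unique_gene_suppression": "gASN3", "target_pair": ("gASN1", "gASN2")}
    return Fixture(model, medium, [], calls, truth)


def compartment_duplicate_fixture() -> Fixture:
    """A cytosolic reaction duplicated in an organelle; the organelle
    copy sustains a falsely viable gene pair, so its suppression is
    among the fixes."""
    from .phenotypes import ExperimentalCall

    mets = ["glc_e", "m0_c", "m0_r", "atp_c", "p6_c", "p6_r"]
    rxns = [
        _r("EX_glc", {"glc_e": -1.0}, lb=-GLOBAL_BOUND),
        _r("GLCt", {"glc_e": -1.0, "m0_c": 1.0}),
        _r("ATPS", {"m0_c": -1.0, "atp_c": 1.0}),
        _r("ATPM", {"atp_c": -1.0}),
        _r("M0tr", {"m0_c": -1.0, "m0_r": 1.0}, lb=-GLOBAL_BOUND),
        _r("G6PDH_c", {"m0_c": -1.0, "p6_c": 1.0}, "gZWF"),
        _r("G6PDH_r", {"m0_r": -1.0, "p6_r": 1.0}),
        _r("P6tr", {"p6_r": -1.0, "p6_c": 1.0}, lb=-GLOBAL_BOUND),
        _r("ALT", {"m0_c": -1.0, "p6_c": 1.0}, "gRPE"),
        _r("BIOMASS", {"p6_c": -1.0}),
    ]
    model = _toy(mets, rxns, model_id="compartment_duplicate")
    medium = MediumSpec(name="minimal", uptake_limits={"EX_glc": 10.0})
    calls = [
        ExperimentalCall(genes=("gZWF", "gRPE"), medium="minimal",
                         observed="NG", cause="SL")
    ]
    truth = {"organelle_reaction": "G6PDH_r", "target_pair": ("gZWF", "gRPE")}
    return Fixture(model, medium, [], calls, truth)


def auxotrophy_rescue_fixture() -> Fixture:
    """An SL pair rescued in vivo by feeding the missing intermediate;
    the model lacks an import route, so an exchange + transport pair
    must be added before the rescue reproduces in silico."""
    from .phenotypes import ExperimentalCall

    mets = ["glc_e", "m0_c", "atp_c", "mev_c", "p_c"]
    rxns = [
        _r("EX_glc", {"glc_e": -1.0}, lb=-GLOBAL_BOUND),
        _r("GLCt", {"glc_e": -1.0, "m0_c": 1.0}),
        _r("ATPS", {"m0_c": -1.0, "atp_c": 1.0}),
        _r("ATPM", {"atp_c": -1.0}),
        _r("HMG1R", {"m0_c": -1.0, "mev_c": 1.0}, "gHMG1"),
        _r("HMG2R", {"m0_c": -1.0, "mev_c": 1.0}, "gHMG2"),
        _r("MEVUSE", {"mev_c": -1.0, "p_c": 1.0}),
        _r("BIOMASS", {"p_c": -1.0}),
    ]
    model = _toy(mets, rxns, model_id="auxotrophy_rescue")
    medium = MediumSpec(name="minimal", uptake_limits={"EX_glc": 10.0})
    calls = [
        ExperimentalCall(genes=("gHMG1", "gHMG2"), medium="minimal",
                         observed="NG", cause="SL", rescue_supplement="mev")
    ]
    truth = {"supplement": "mev", "target_pair": ("gHMG1", "gHMG2")}
    return Fixture(model, medium, [], calls, truth)


def motif_fixtures() -> dict[str, Fixture]:
    """The named hand-built regression networks."""
    conditional, _rich = conditional_suppression_fixture()
    return {
        "ump_salvage": ump_salvage_fixture(),
        "prpps_gpr": prpps_gpr_fixture(),
        "trna_charging": trna_charging_fixture(),
        "conditional_suppression": conditional,
        "isozyme_triple": isozyme_triple_fixture(),
        "compartment_duplicate": compartment_duplicate_fixture(),
        "auxotrophy_rescue": auxotrophy_rescue_fixture(),
    }
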