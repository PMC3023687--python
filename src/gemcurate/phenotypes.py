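"""Model-vs-experiment comparison: mismatch taxonomy and accuracy metrics.

Single-gene calls combine the in-silico and in-vivo growth verdicts
into GG / NGG / GNG / NGNG (prediction first).  Double-gene calls use
the three-way alphabet G (viable), ES (one gene essential), SL (only
the pair lethal), giving the nine classes GG ... SLSL; diagonal labels
are consistencies.  Accuracy metrics:

    specificity = #NGNG / (#NGNG + #GNG)
    sensitivity (TVR) = #GG / (#GG + #NGG)
    FVR = #GNG / (#GNG + #NGNG) = 100% - specificity
    pair specificity = #SLSL / (#SLSL + #ESSL + #GSL)
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Sequence

import pandas as pd

from .fba import VIABILITY_FRACTION, is_viable
from .model import GLOBAL_BOUND, MetabolicModel, Metabolite, Reaction
from .screens import ScreenResult, SLPairSet

__all__ = [
    "ExperimentalCall",
    "MismatchRecord",
    "AccuracyMetrics",
    "classify_single",
    "classify_double",
    "classify_records",
    "compute_metrics",
    "auxotrophy_check",
    "read_phenotype_table",
    "write_mismatch_table",
]


@dataclass(frozen=True)
class ExperimentalCall:
    """One experimental growth observation (single gene or gene pair)."""

    genes: tuple[str, ...]
    medium: str
    observed: str  # "G" | "NG"
    cause: str | None = None  # "ES" | "SL" when observed == NG
    rescue_supplement: str | None = None

    def __post_init__(self):
        if self.observed not in ("G", "NG"):
            raise ValueError(f"observed must be G or NG, got {self.observed!r}")
        if len(self.genes) not in (1, 2):
            raise ValueError("a call covers one gene or a gene pair")
        if self.observed == "NG" and len(self.genes) == 1:
            object.__setattr__(self, "cause", "ES")

    @property
    def in_vivo_label(self) -> str:
        if self.observed == "G":
            return "G"
        return self.cause or ("ES" if len(self.genes) == 1 else "SL")


@dataclass(frozen=True)
class MismatchRecord:
    genes: tuple[str, ...]
    in_silico: str
    in_vivo: str
    label: str
    medium: str = ""

    @property
    def is_consistent(self) -> bool:
        return self.in_silico == self.in_vivo


_SINGLE = {"G", "NG"}
_DOUBLE = {"G", "ES", "SL"}


def classify_single(in_silico: str, in_vivo: str) -> str:
    """GG / NGG / GNG / NGNG, prediction written first."""
    if in_silico not in _SINGLE or in_vivo not in _SINGLE:
        raise ValueError(f"single-gene calls must be G or NG, got {in_silico!r}/{in_vivo!r}")
    return in_silico + in_vivo


def classify_double(in_silico: str, in_vivo: str) -> str:
    """Concatenated three-way labels for gene pairs (GG ... SLSL)."""
    if in_silico not in _DOUBLE or in_vivo not in _DOUBLE:
        raise ValueError(f"pair calls must be G, ES or SL, got {in_silico!r}/{in_vivo!r}")
    return in_silico + in_vivo


def in_silico_pair_call(
    pair: Iterable[str], screen: ScreenResult, sl_pairs: SLPairSet
) -> str:
    """ES if either gene is essential, SL if the pair is synthetic
    lethal, else G."""
    genes = frozenset(pair)
    if genes & screen.essential_genes:
        return "ES"
    if genes in sl_pairs.pairs:
        return "SL"
    return "G"


def classify_records(
    calls: Sequence[ExperimentalCall],
    screen: ScreenResult,
    sl_pairs: SLPairSet | None = None,
    model_genes: frozenset[str] | None = None,
) -> tuple[list[MismatchRecord], list[ExperimentalCall]]:
    """Classify experimental calls against screen results.

    Calls naming genes absent from the model cannot be compared and are
    returned separately (they do not enter metric denominators).
    """
    records: list[MismatchRecord] = []
    skipped: list[ExperimentalCall] = []
    for call in calls:
        if model_genes is not None and any(g not in model_genes for g in call.genes):
            skipped.append(call)
            continue
        if len(call.genes) == 1:
            g = call.genes[0]
            silico = "NG" if g in screen.essential_genes else "G"
            label = classify_single(silico, call.observed)
        else:
            if sl_pairs is None:
                raise ValueError("pair calls require an SL pair set")
            silico = in_silico_pair_call(call.genes, screen, sl_pairs)
            label = classify_double(silico, call.in_vivo_label)
        records.append(
            MismatchRecord(
                genes=call.genes,
                in_silico=silico,
                in_vivo=call.in_vivo_label if len(call.genes) == 2 else call.observed,
                label=label,
                medium=call.medium,
            )
        )
    return records, skipped


@dataclass(frozen=True)
class AccuracyMetrics:
    specificity: float | None
    sensitivity: float | None
    fvr: float | None
    double_specificity: float | None
    counts: dict = field(default_factory=dict)


def _percent(num: int, den: int) -> float | None:
    if den == 0:
        return None
    pct = Decimal(100 * num) / Decimal(den)
    return float(pct.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def compute_metrics(records: Sequence[MismatchRecord]) -> AccuracyMetrics:
    """Percentages (two decimals, half-up) from classified records."""
    counts: dict[str, int] = {}
    for r in records:
        counts[r.label] = counts.get(r.label, 0) + 1
    n = counts.get
    return AccuracyMetrics(
        specificity=_percent(n("NGNG", 0), n("NGNG", 0) + n("GNG", 0)),
        sensitivity=_percent(n("GG", 0), n("GG", 0) + n("NGG", 0)),
        fvr=_percent(n("GNG", 0), n("GNG", 0) + n("NGNG", 0)),
        double_specificity=_percent(
            n("SLSL", 0), n("SLSL", 0) + n("ESSL", 0) + n("GSL", 0)
        ),
        counts=counts,
    )


# ---------------------------------------------------------------------------
# auxotrophy rescue
# ---------------------------------------------------------------------------

def auxotrophy_check(
    model: MetabolicModel,
    genes: Iterable[str],
    supplement_metabolite: str,
    rescued_in_vivo: bool = True,
    uptake_level: float = 0.5,
    threshold_fraction: float = VIABILITY_FRACTION,
    add_missing_routes: bool = False,
) -> str:
    """Check supplementation-rescue consistency for an NG mutant.

    Opens uptake of the supplement through the model's existing import
    machinery and re-runs the viability call.  Returns
    ``"consistent"``, ``"inconsistent"``, or ``"compound missing"``
    when the metabolite is absent from the model entirely (a
    restoration task, not an error).  A compound that exists only
    inside the cell cannot be imported as-is; by default that counts
    as a failed in-silico rescue (the restoration engines can then
    propose the missing exchange/transport pair), while
    ``add_missing_routes`` stubs those routes first — the
    post-restoration semantics.
    """
    candidates = [
        m for m in model.metabolites
        if m.id == supplement_metabolite
        or m.id.rsplit("_", 1)[0] == supplement_metabolite
    ]
    if not candidates:
        return "compound missing"
    importable = any(m.compartment == "e" for m in candidates)
    if not importable and not add_missing_routes:
        rescued_in_silico = False
    else:
        supplemented = open_supplement_uptake(model, supplement_metabolite, uptake_level)
        call = is_viable(supplemented, frozenset(genes), threshold_fraction)
        rescued_in_silico = call.viable
    return "consistent" if rescued_in_silico == rescued_in_vivo else "inconsistent"


def open_supplement_uptake(
    model: MetabolicModel, metabolite: str, uptake_level: float
) -> MetabolicModel:
    """Return a model copy where the compound can be taken up.

    Uses the existing exchange if present; otherwise stubs an exchange
    (and a transport into the cytosol when the compound only exists
    internally).
    """
    stems = {m.id.rsplit("_", 1)[0] if "_" in m.id else m.id for m in model.metabolites}
    if metabolite in stems:
        base = metabolite  # already a bare compound stem
    elif "_" in metabolite:
        base = metabolite.rsplit("_", 1)[0]  # a species id with suffix
    else:
        base = metabolite
    ext_id, int_id = None, None
    for m in model.metabolites:
        stem = m.id.rsplit("_", 1)[0] if "_" in m.id else m.id
        if stem == base or m.id == metabolite:
            if m.compartment == "e":
                ext_id = m.id
            else:
                int_id = int_id or m.id
    for r in model.reactions:
        if r.is_exchange and next(iter(r.stoichiometry)) == ext_id:
            return model.with_reactions(
                updated=[r.with_bounds(-uptake_level, max(r.upper_bound, 0.0))]
            )
    added_mets: list[Metabolite] = []
    added_rxns: list[Reaction] = []
    if ext_id is None:
        if int_id is None:
            raise ValueError(f"metabolite {metabolite!r} not present in model")
        ext_id = f"{base}_e"
        added_mets.append(Metabolite(id=ext_id, name=base, compartment="e"))
        added_rxns.append(
            Reaction(
                id=f"{base.upper()}t_supp",
                stoichiometry={ext_id: -1.0, int_id: 1.0},
                lower_bound=-GLOBAL_BOUND,
                upper_bound=GLOBAL_BOUND,
            )
        )
    added_rxns.append(
        Reaction(
            id=f"EX_{base}_supp",
            stoichiometry={ext_id: -1.0},
            lower_bound=-uptake_level,
            upper_bound=GLOBAL_BOUND,
        )
    )
    return model.with_reactions(added=added_rxns, added_metabolites=added_mets)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_TABLE_COLUMNS = ["gene1", "gene2", "medium", "phenotype", "cause", "supplement"]


def read_phenotype_table(path) -> list[ExperimentalCall]:
    """Read a TSV of experimental calls (gene1, optional gene2, medium,
    phenotype G/NG, cause ES/SL, optional supplement)."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    calls = []
    for _, row in df.iterrows():
        genes = tuple(g for g in (row.get("gene1", ""), row.get("gene2", "")) if g)
        calls.append(
            ExperimentalCall(
                genes=genes,
                medium=row.get("medium", ""),
                observed=row["phenotype"],
                cause=row.get("cause") or None,
                rescue_supplement=row.get("supplement") or None,
            )
        )
    return calls


def write_phenotype_table(calls: Sequence[ExperimentalCall], path) -> None:
    rows = []
    for c in calls:
        rows.append(
            {
                "gene1": c.genes[0],
                "gene2": c.genes[1] if len(c.genes) == 2 else "",
                "medium": c.medium,
                "phenotype": c.observed,
                "cause": c.cause or "",
                "supplement": c.rescue_supplement or "",
            }
        )
    pd.DataFrame(rows, columns=_TABLE_COLUMNS).to_csv(path, sep="\t", index=False)


def write_mismatch_table(records: Sequence[MismatchRecord], path) -> None:
    rows = [
        {
            "genes": ";".join(r.genes),
            "in_silico": r.in_silico,
            "in_vivo": r.in_vivo,
            "class": r.label,
            "medium": r.medium,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=["genes", "in_silico", "in_vivo", "class", "medium"]).to_csv(
        path, sep="\t", index=False
    )
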