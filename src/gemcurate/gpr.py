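"""Gene-protein-reaction (GPR) boolean logic.

A GPR rule states which combinations of genes suffice to catalyze a
reaction: AND joins subunits of a protein complex, OR joins isozymes.
Besides parsing and evaluation, this module converts rules to CNF and
emits the summed-indicator flux-bound rows that let gene knockouts act
directly on reaction bounds without auxiliary reaction binaries: for a
CNF clause C of reaction j,

    (sum_{k in C} w_k) * LB_j  <=  v_j  <=  (sum_{k in C} w_k) * UB_j

with w_k in {0,1} the gene-activity indicator, plus the plain
``LB_j <= v_j <= UB_j`` row whenever a clause contains more than one
gene (the summed coefficient can exceed 1, which the plain row caps).
If every clause retains at least one active gene the feasible interval
for v_j is exactly [LB_j, UB_j]; if any clause is fully knocked out it
collapses to [0, 0].
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator

__all__ = [
    "GPRExpr",
    "GPRParseError",
    "CNFCapacityError",
    "BoundConstraintRow",
    "parse_gpr",
    "evaluate_gpr",
    "to_cnf",
    "emit_bound_constraints",
    "implied_flux_interval",
    "FICTITIOUS_PREFIX",
]

#: prefix for the fictitious gene assigned to reactions without a GPR,
#: so that suppression machinery treats every reaction uniformly.
FICTITIOUS_PREFIX = "__rxn__"


class GPRParseError(ValueError):
    """Raised when a GPR string cannot be parsed; carries the position."""

    def __init__(self, message: str, position: int | None = None):
        super().__init__(message if position is None else f"{message} (at position {position})")
        self.position = position


class CNFCapacityError(ValueError):
    """CNF conversion exceeded the configured clause or gene cap.

    Callers should fall back to a reaction-level indicator for the
    affected reaction instead of gene-level rows.
    """


@dataclass(frozen=True)
class GPRExpr:
    """Immutable boolean tree over gene identifiers.

    ``op`` is one of ``"gene"``, ``"and"``, ``"or"``, or ``"empty"``.
    An empty expression means the reaction is unconditionally active.
    """

    op: str
    gene: str | None = None
    children: tuple["GPRExpr", ...] = field(default_factory=tuple)

    # -- constructors -------------------------------------------------
    @staticmethod
    def empty() -> "GPRExpr":
        return GPRExpr("empty")

    @staticmethod
    def leaf(gene: str) -> "GPRExpr":
        if not gene:
            raise ValueError("gene identifier must be non-empty")
        return GPRExpr("gene", gene=gene)

    @staticmethod
    def and_(children: Iterable["GPRExpr"]) -> "GPRExpr":
        return _nary("and", children)

    @staticmethod
    def or_(children: Iterable["GPRExpr"]) -> "GPRExpr":
        return _nary("or", children)

    # -- basic queries ------------------------------------------------
    @property
    def is_empty(self) -> bool:
        return self.op == "empty"

    def genes(self) -> frozenset[str]:
        if self.op == "gene":
            return frozenset((self.gene,))
        out: set[str] = set()
        for c in self.children:
            out |= c.genes()
        return frozenset(out)

    def evaluate(self, deleted: Iterable[str] = ()) -> bool:
        return evaluate_gpr(self, deleted)

    def to_string(self) -> str:
        if self.op == "empty":
            return ""
        if self.op == "gene":
            return self.gene  # type: ignore[return-value]
        joiner = " and " if self.op == "and" else " or "
        parts = []
        for c in self.children:
            s = c.to_string()
            if c.op in ("and", "or") and c.op != self.op:
                s = f"({s})"
            elif c.op == self.op:
                s = f"({s})"
            parts.append(s)
        return joiner.join(parts)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.to_string()


def _nary(op: str, children: Iterable[GPRExpr]) -> GPRExpr:
    flat: list[GPRExpr] = []
    for c in children:
        if c.is_empty:
            continue
        if c.op == op:
            flat.extend(c.children)
        else:
            flat.append(c)
    if not flat:
        raise ValueError(f"{op.upper()} node requires at least one non-empty child")
    if len(flat) == 1:
        return flat[0]
    return GPRExpr(op, children=tuple(flat))


# ---------------------------------------------------------------------------
# parsing
# ---------------------------------------------------------------------------

_TOKEN_RE = re.compile(r"\s*(\(|\)|[^\s()]+)")


def _tokenize(text: str) -> Iterator[tuple[str, int]]:
    pos = 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if m is None:
            break
        yield m.group(1), m.start(1)
        pos = m.end()


def parse_gpr(text: str) -> GPRExpr:
    """Parse a GPR string such as ``"(PRS1 and PRS3) or (PRS2 or PRS4) and PRS5"``.

    AND/OR keywords are case-insensitive; AND binds tighter than OR,
    matching the SBML fbc association convention.  Returns the empty
    (always-active) expression for blank input.
    """
    tokens = list(_tokenize(text))
    if not tokens:
        return GPRExpr.empty()
    parser = _Parser(tokens, text)
    expr = parser.parse_or()
    if parser.peek() is not None:
        tok, pos = parser.tokens[parser.i]
        raise GPRParseError(f"unexpected token {tok!r}", pos)
    return expr


class _Parser:
    def __init__(self, tokens: list[tuple[str, int]], text: str):
        self.tokens = tokens
        self.text = text
        self.i = 0

    def peek(self) -> str | None:
        if self.i < len(self.tokens):
            return self.tokens[self.i][0]
        return None

    def next(self) -> tuple[str, int]:
        tok = self.tokens[self.i]
        self.i += 1
        return tok

    def parse_or(self) -> GPRExpr:
        terms = [self.parse_and()]
        while self.peek() is not None and self.peek().lower() == "or":
            self.next()
            terms.append(self.parse_and())
        return GPRExpr.or_(terms) if len(terms) > 1 else terms[0]

    def parse_and(self) -> GPRExpr:
        terms = [self.parse_atom()]
        while self.peek() is not None and self.peek().lower() == "and":
            self.next()
            terms.append(self.parse_atom())
        return GPRExpr.and_(terms) if len(terms) > 1 else terms[0]

    def parse_atom(self) -> GPRExpr:
        if self.peek() is None:
            raise GPRParseError("unexpected end of expression", len(self.text))
        tok, pos = self.next()
        if tok == "(":
            inner = self.parse_or()
            if self.peek() != ")":
                raise GPRParseError("unbalanced parentheses", pos)
            self.next()
            return inner
        if tok == ")" or tok.lower() in ("and", "or"):
            raise GPRParseError(f"unexpected token {tok!r}", pos)
        return GPRExpr.leaf(tok)


# ---------------------------------------------------------------------------
# evaluation and CNF
# ---------------------------------------------------------------------------

def evaluate_gpr(expr: GPRExpr, deleted: Iterable[str] = ()) -> bool:
    """Boolean semantics with the listed genes set to false (deleted)."""
    dels = deleted if isinstance(deleted, (set, frozenset)) else frozenset(deleted)
    return _eval(expr, dels)


def _eval(expr: GPRExpr, deleted) -> bool:
    if expr.op == "empty":
        return True
    if expr.op == "gene":
        return expr.gene not in deleted
    if expr.op == "and":
        return all(_eval(c, deleted) for c in expr.children)
    return any(_eval(c, deleted) for c in expr.children)


def to_cnf(
    expr: GPRExpr,
    max_genes: int = 16,
    max_clauses: int = 256,
) -> list[frozenset[str]]:
    """Convert to a conjunction of disjunctions over gene ids.

    Each returned clause is a gene set; the reaction is active iff every
    clause contains at least one non-deleted gene.  Clauses are
    deduplicated and subsumed clauses (supersets of another clause) are
    dropped.  ``(k1 and k2) or (k1 and k3)`` becomes ``{k1}, {k2,k3}``.
    """
    if expr.is_empty:
        return []
    genes = expr.genes()
    if len(genes) > max_genes:
        raise CNFCapacityError(
            f"GPR touches {len(genes)} genes (cap {max_genes}); "
            "use a reaction-level indicator instead"
        )
    clauses = _cnf(expr, max_clauses)
    return _minimize_clauses(clauses)


def _cnf(expr: GPRExpr, cap: int) -> list[frozenset[str]]:
    if expr.op == "gene":
        return [frozenset((expr.gene,))]
    if expr.op == "and":
        out: list[frozenset[str]] = []
        for c in expr.children:
            out.extend(_cnf(c, cap))
            if len(out) > cap:
                raise CNFCapacityError(f"CNF clause count exceeded cap {cap}")
        return out
    # OR: cross-product of children's clause lists
    child_cnfs = [_cnf(c, cap) for c in expr.children]
    n = 1
    for cc in child_cnfs:
        n *= len(cc)
        if n > cap:
            raise CNFCapacityError(f"CNF clause count exceeded cap {cap}")
    return [frozenset().union(*combo) for combo in itertools.product(*child_cnfs)]


def _minimize_clauses(clauses: list[frozenset[str]]) -> list[frozenset[str]]:
    uniq = sorted(set(clauses), key=lambda c: (len(c), sorted(c)))
    kept: list[frozenset[str]] = []
    for c in uniq:
        if not any(k <= c for k in kept):
            kept.append(c)
    return kept


# ---------------------------------------------------------------------------
# flux-bound constraint rows
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BoundConstraintRow:
    """One summed-indicator bound row for a reaction.

    ``genes`` lists the w_k that sum in the row; ``plain`` marks the
    unscaled LB <= v <= UB row that accompanies multi-gene clauses.
    """

    reaction_id: str
    genes: frozenset[str]
    plain: bool = False


def emit_bound_constraints(
    expr: GPRExpr,
    reaction_id: str = "rxn",
    max_genes: int = 16,
    max_clauses: int = 256,
) -> list[BoundConstraintRow]:
    """Emit the gene-indicator bound rows for one reaction.

    One row per CNF clause; a plain (unscaled) row is appended whenever
    any clause has more than one gene, since a summed coefficient > 1
    would otherwise loosen the bound beyond [LB, UB].
    """
    clauses = to_cnf(expr, max_genes=max_genes, max_clauses=max_clauses)
    rows = [BoundConstraintRow(reaction_id, clause) for clause in clauses]
    if any(len(c) > 1 for c in clauses):
        rows.append(BoundConstraintRow(reaction_id, frozenset(), plain=True))
    return rows


def implied_flux_interval(
    rows: list[BoundConstraintRow],
    lb: float,
    ub: float,
    deleted: Iterable[str] = (),
) -> tuple[float, float]:
    """Flux interval implied by the bound rows under a deletion pattern.

    Intersects every row's interval analytically; used as the algebraic
    counterpart of putting the rows into an LP.  Returns (lo, hi); an
    empty intersection is reported with lo > hi.
    """
    dels = frozenset(deleted)
    lo, hi = -float("inf"), float("inf")
    for row in rows:
        if row.plain:
            s = 1.0
        else:
            s = float(sum(1 for g in row.genes if g not in dels))
        lo = max(lo, s * lb)
        hi = min(hi, s * ub)
    if not rows:  # empty GPR: only the plain bounds apply
        lo, hi = lb, ub
    else:
        lo = max(lo, lb) if any(r.plain for r in rows) else lo
        hi = min(hi, ub) if any(r.plain for r in rows) else hi
    return lo, hi


def substitute_false(expr: GPRExpr, genes: Iterable[str]) -> GPRExpr | None:
    """Set the given genes constitutively false and simplify.

    Returns the simplified expression, or ``None`` when the whole rule
    collapses to false (the reaction can never be active).  Used to
    bake a gene suppression into a model as a structural edit.
    """
    off = frozenset(genes)
    if expr.op == "empty":
        return expr
    if expr.op == "gene":
        return None if expr.gene in off else expr
    parts = [substitute_false(c, off) for c in expr.children]
    if expr.op == "and":
        if any(p is None for p in parts):
            return None
        return GPRExpr.and_(parts)  # type: ignore[arg-type]
    live = [p for p in parts if p is not None]
    if not live:
        return None
    return GPRExpr.or_(live)


def fictitious_gene(reaction_id: str) -> str:
    """Name of the always-active stand-in gene for a bare reaction."""
    return FICTITIOUS_PREFIX + reaction_id
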