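"""GPR parsing, evaluation, CNF conversion, and bound-row encoding."""

import itertools

import numpy as np
import pytest

from gemcurate.gpr import (
    BoundConstraintRow,
    CNFCapacityError,
    GPRExpr,
    GPRParseError,
    emit_bound_constraints,
    evaluate_gpr,
    fictitious_gene,
    implied_flux_interval,
    parse_gpr,
    substitute_false,
    to_cnf,
)

GENES = ["g0", "g1", "g2", "g3", "g4", "g5", "g6", "g7"]


def random_expr(rng, genes, depth=0):
    if depth >= 3 or rng.random() < 0.35:
        return GPRExpr.leaf(genes[rng.integers(0, len(genes))])
    op = GPRExpr.and_ if rng.random() < 0.5 else GPRExpr.or_
    n = int(rng.integers(2, 4))
    return op([random_expr(rng, genes, depth + 1) for _ in range(n)])


def truth_table_eval(expr, deleted):
    """Direct recursive oracle, independent of evaluate_gpr's internals."""
    if expr.op == "empty":
        return True
    if expr.op == "gene":
        return expr.gene not in deleted
    results = [truth_table_eval(c, deleted) for c in expr.children]
    return all(results) if expr.op == "and" else any(results)


class TestParse:
    def test_isozyme_complex_mixture(self):
        expr = parse_gpr("(PRS1 AND PRS3) OR ((PRS2 OR PRS4) AND PRS5)")
        assert expr.op == "or"
        left, right = expr.children
        assert left.op == "and" and left.genes() == {"PRS1", "PRS3"}
        assert right.op == "and" and right.genes() == {"PRS2", "PRS4", "PRS5"}

    def test_empty_string_is_always_active(self):
        expr = parse_gpr("")
        assert expr.is_empty
        assert evaluate_gpr(expr, {"anything"})

    def test_keywords_case_insensitive_and_flattened(self):
        expr = parse_gpr("a And b AND c")
        assert expr.op == "and" and len(expr.children) == 3

    @pytest.mark.parametrize("bad", ["(a or b", "a b", "a or or b", ")a(", "a and"])
    def test_parse_errors(self, bad):
        with pytest.raises(GPRParseError):
            parse_gpr(bad)

    def test_random_expressions_agree_with_truth_table(self):
        rng = np.random.default_rng(42)
        genes = GENES[:6]
        for _ in range(50):
            expr = random_expr(rng, genes)
            reparsed = parse_gpr(expr.to_string())
            for bits in itertools.product([0, 1], repeat=len(genes)):
                dels = {g for g, b in zip(genes, bits) if not b}
                want = truth_table_eval(expr, dels)
                assert evaluate_gpr(expr, dels) == want
                assert evaluate_gpr(reparsed, dels) == want


class TestEvaluate:
    def test_isozyme_survives_single_deletion(self):
        assert evaluate_gpr(parse_gpr("g1 or g2"), {"g1"})

    def test_revised_gpr_lethal_and_viable_combinations(self):
        expr = parse_gpr("(PRS1 and PRS3) or ((PRS2 or PRS4) and PRS5)")
        assert not evaluate_gpr(expr, {"PRS1", "PRS5"})
        assert not evaluate_gpr(expr, {"PRS3", "PRS5"})
        assert evaluate_gpr(expr, {"PRS2", "PRS4"})  # complex branch survives


class TestCNF:
    def test_shared_factor_pattern(self):
        clauses = to_cnf(parse_gpr("(k1 and k2) or (k1 and k3)"))
        assert sorted(map(sorted, clauses)) == [["k1"], ["k2", "k3"]]

    def test_single_gene(self):
        assert to_cnf(parse_gpr("g")) == [frozenset(("g",))]

    def test_equivalence_on_random_expressions(self):
        rng = np.random.default_rng(7)
        genes = GENES[:5]
        for _ in range(40):
            expr = random_expr(rng, genes)
            clauses = to_cnf(expr)
            for bits in itertools.product([0, 1], repeat=len(genes)):
                dels = {g for g, b in zip(genes, bits) if not b}
                via_cnf = all(any(g not in dels for g in c) for c in clauses)
                assert via_cnf == truth_table_eval(expr, dels)

    def test_capacity_cap(self):
        many = " and ".join(f"(a{i} or b{i})" for i in range(10))
        with pytest.raises(CNFCapacityError):
            to_cnf(parse_gpr(many), max_clauses=5)
        with pytest.raises(CNFCapacityError):
            to_cnf(parse_gpr(many), max_genes=4)


class TestBoundRows:
    def test_single_gene_deleted_forces_zero(self):
        rows = emit_bound_constraints(parse_gpr("k"))
        assert implied_flux_interval(rows, -1000, 1000, {"k"}) == (0.0, 0.0)

    def test_or_pair_capped_by_plain_row(self):
        rows = emit_bound_constraints(parse_gpr("k1 or k2"))
        assert any(r.plain for r in rows)
        assert implied_flux_interval(rows, -1000, 1000, set()) == (-1000.0, 1000.0)

    def test_all_active_gives_exact_bounds(self):
        for text in ("k", "k1 and k2", "k1 or k2", "(a and b) or (a and c)"):
            rows = emit_bound_constraints(parse_gpr(text))
            assert implied_flux_interval(rows, -7.5, 42.0, set()) == (-7.5, 42.0)

    def test_interval_matches_boolean_activity_exhaustively(self):
        rng = np.random.default_rng(5)
        for _ in range(30):
            n = int(rng.integers(1, 7))
            genes = GENES[:n]
            expr = random_expr(rng, genes)
            rows = emit_bound_constraints(expr)
            for lb, ub in ((-1000.0, 1000.0), (0.0, 1000.0)):
                for bits in itertools.product([0, 1], repeat=n):
                    dels = {g for g, b in zip(genes, bits) if not b}
                    lo, hi = implied_flux_interval(rows, lb, ub, dels)
                    if truth_table_eval(expr, dels):
                        assert (lo, hi) == (lb, ub)
                    else:
                        assert (lo, hi) == (0.0, 0.0)


class TestSubstitution:
    def test_or_leaf_removal(self):
        out = substitute_false(parse_gpr("a or b"), ("a",))
        assert out is not None and out.genes() == {"b"}

    def test_and_collapse(self):
        assert substitute_false(parse_gpr("a and b"), ("a",)) is None

    def test_empty_untouched(self):
        assert substitute_false(GPRExpr.empty(), ("a",)).is_empty

    def test_matches_truth_table(self):
        rng = np.random.default_rng(3)
        genes = GENES[:5]
        for _ in range(30):
            expr = random_expr(rng, genes)
            off = {g for g in genes if rng.random() < 0.4}
            reduced = substitute_false(expr, off)
            for bits in itertools.product([0, 1], repeat=len(genes)):
                dels = {g for g, b in zip(genes, bits) if not b} | off
                want = truth_table_eval(expr, dels)
                got = reduced is not None and truth_table_eval(reduced, dels)
                assert got == want


try:
    from hypothesis import given, settings, strategies as st

    def expr_strategy(genes=tuple(GENES[:5]), depth=2):
        leaf = st.sampled_from(genes).map(GPRExpr.leaf)
        if depth == 0:
            return leaf
        sub = expr_strategy(genes, depth - 1)
        branch = st.lists(sub, min_size=2, max_size=3).map(
            lambda cs: GPRExpr.and_(cs)
        ) | st.lists(sub, min_size=2, max_size=3).map(lambda cs: GPRExpr.or_(cs))
        return leaf | branch

    @given(expr=expr_strategy(), deleted=st.sets(st.sampled_from(GENES[:5])))
    @settings(max_examples=150, deadline=None, derandomize=True)
    def test_parse_cnf_and_rows_agree_with_semantics(expr, deleted):
        """Round-tripping through the string form, the CNF clauses and
        the bound-row interval all preserve deletion semantics."""
        want = truth_table_eval(expr, deleted)
        assert evaluate_gpr(parse_gpr(expr.to_string()), deleted) == want
        clauses = to_cnf(expr)
        assert all(any(g not in deleted for g in c) for c in clauses) == want
        lo, hi = implied_flux_interval(
            emit_bound_constraints(expr), -1000.0, 1000.0, deleted
        )
        assert ((lo, hi) == (-1000.0, 1000.0)) == want
        assert want or (lo, hi) == (0.0, 0.0)
except ImportError:  # pragma: no cover - hypothesis is an optional extra
    pass


def test_fictitious_gene_names_are_distinct_from_real_ids():
    assert fictitious_gene("PYNP2r") != "PYNP2r"
    assert fictitious_gene("A") != fictitious_gene("B")


def test_bound_row_is_hashable_value_object():
    r1 = BoundConstraintRow("rxn", frozenset(("a",)))
    r2 = BoundConstraintRow("rxn", frozenset(("a",)))
    assert r1 == r2 and hash(r1) == hash(r2)
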