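"""Minimal suppression search: bilevel MILP vs exhaustive enumeration."""

import pytest

from gemcurate import (
    apply_medium,
    enumerate_alternatives,
    exhaustive_suppressions,
    min_gene_suppressions,
    min_reaction_suppressions,
)
from gemcurate.fixtures import FixtureSpec, _r, _toy, generate_fixture
from gemcurate.model import GLOBAL_BOUND, MediumSpec
from gemcurate.suppress import BilevelSuppressor, SuppressionProblem


class TestMotifRegressions:
    def test_salvage_bypass_is_unique_reaction_suppression(self, motifs):
        fx = motifs["ump_salvage"]
        m = apply_medium(fx.model, fx.medium)
        sols = min_reaction_suppressions(m, fx.ground_truth["target_pair"], n=2)
        assert [sorted(s.suppressed) for s in sols] == [
            [fx.ground_truth["unique_reaction_suppression"]]
        ]

    def test_third_isozyme_is_unique_gene_suppression(self, motifs):
        fx = motifs["isozyme_triple"]
        m = apply_medium(fx.model, fx.medium)
        sols = min_gene_suppressions(m, fx.ground_truth["target_pair"], n=2)
        assert [sorted(s.suppressed) for s in sols] == [
            [fx.ground_truth["unique_gene_suppression"]]
        ]

    def test_organelle_duplicate_found_among_suppressions(self, motifs):
        fx = motifs["compartment_duplicate"]
        m = apply_medium(fx.model, fx.medium)
        sols = min_reaction_suppressions(m, fx.ground_truth["target_pair"], n=2)
        union = set().union(*(s.suppressed for s in sols))
        assert fx.ground_truth["organelle_reaction"] in union

    def test_already_lethal_mutant_needs_no_suppression(self, basic_model):
        sols = min_gene_suppressions(basic_model, ("gE0",), n=2)
        assert len(sols) == 1 and sols[0].cardinality == 0


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", [51, 52, 53])
    @pytest.mark.parametrize("level", ["gene", "reaction"])
    def test_bilevel_matches_exhaustive(self, seed, level):
        fx = generate_fixture(FixtureSpec(seed=seed), verify=False)
        m = apply_medium(fx.model, fx.medium)
        targets = []
        if fx.ground_truth["mismatches"].get("GNG"):
            targets.append(fx.ground_truth["mismatches"]["GNG"][0][0])
        if fx.ground_truth["mismatches"].get("GSL"):
            targets.append(fx.ground_truth["mismatches"]["GSL"][0][0])
        solver = min_gene_suppressions if level == "gene" else min_reaction_suppressions
        for genes in targets:
            milp = solver(m, genes, n=2, max_alternates=50)
            brute = exhaustive_suppressions(m, genes, level, n=2)
            assert {s.suppressed for s in milp} == {s.suppressed for s in brute}

    def test_planted_resolutions_recovered(self):
        fx = generate_fixture(FixtureSpec(seed=55), verify=False)
        m = apply_medium(fx.model, fx.medium)
        (gng_genes, gng_fix), = fx.ground_truth["mismatches"]["GNG"]
        sols = min_gene_suppressions(m, gng_genes, n=1)
        assert frozenset((gng_fix["gene_id"],)) in {s.suppressed for s in sols}
        (gsl_genes, gsl_fix), = fx.ground_truth["mismatches"]["GSL"]
        sols = min_reaction_suppressions(m, gsl_genes, n=1)
        assert frozenset((gsl_fix["reaction_id"],)) in {s.suppressed for s in sols}


class TestBilevelConsistency:
    def test_strong_duality_against_direct_fba(self, motifs):
        """The dualized MILP's inner optimum must equal plain FBA with
        the suppressions applied."""
        for name in ("ump_salvage", "isozyme_triple", "compartment_duplicate"):
            fx = motifs[name]
            m = apply_medium(fx.model, fx.medium)
            pair = fx.ground_truth["target_pair"]
            for solver in (min_gene_suppressions, min_reaction_suppressions):
                for sol in solver(m, pair, n=2, max_alternates=10):
                    assert sol.biomass == pytest.approx(sol.verified_biomass, abs=1e-6)

    def test_levels_agree_on_unique_single_gene_gprs(self):
        """With a bijective gene<->reaction map the two solvers must
        return matching suppression sets."""
        rxns = [
            _r("EX_glc", {"glc_e": -1.0}, lb=-GLOBAL_BOUND),
            _r("GLCt", {"glc_e": -1.0, "m0_c": 1.0}, "gT"),
            _r("RA", {"m0_c": -1.0, "p_c": 1.0}, "gA"),
            _r("RB", {"m0_c": -1.0, "p_c": 1.0}, "gB"),
            _r("RC", {"m0_c": -1.0, "p_c": 1.0}, "gC"),
            _r("BIOMASS", {"p_c": -1.0}),
        ]
        model = _toy(["glc_e", "m0_c", "p_c"], rxns, atpm=False)
        m = apply_medium(model, MediumSpec(uptake_limits={"EX_glc": 10.0}, atpm_flux=0.0))
        by_gene = min_gene_suppressions(m, ("gA",), n=2, max_alternates=10)
        by_rxn = min_reaction_suppressions(m, ("gA",), n=2, max_alternates=10)
        gene_sets = {frozenset(s.suppressed) for s in by_gene}
        rxn_sets = {
            frozenset("g" + r[1] for r in s.suppressed) for s in by_rxn
        }  # RB -> gB etc.
        assert gene_sets == {frozenset(("gB", "gC"))}
        assert rxn_sets == gene_sets

    def test_achieved_biomass_nonincreasing_in_n(self, motifs):
        fx = motifs["compartment_duplicate"]
        m = apply_medium(fx.model, fx.medium)
        pair = fx.ground_truth["target_pair"]
        prev = float("inf")
        for n in (1, 2):
            problem = SuppressionProblem(m, frozenset(pair), "reaction", n)
            bl = BilevelSuppressor(problem)
            res = bl.solve_once(n)
            assert res is not None
            assert res[0] <= prev + 1e-9
            prev = res[0]

    def test_genes_outside_gprs_never_suppressed(self):
        fx = generate_fixture(FixtureSpec(seed=60), verify=False)
        m = apply_medium(fx.model, fx.medium)
        for genes, _fix in fx.ground_truth["mismatches"].get("GNG", []):
            for sol in min_gene_suppressions(m, genes, n=2, max_alternates=20):
                gpr_genes = set().union(*(r.gpr.genes() for r in m.reactions))
                real = {g for g in sol.suppressed if not g.startswith("__")}
                assert real <= gpr_genes


class TestAlternatives:
    def test_symmetric_isozymes_both_enumerated(self):
        rxns = [
            _r("EX_glc", {"glc_e": -1.0}, lb=-GLOBAL_BOUND),
            _r("GLCt", {"glc_e": -1.0, "m0_c": 1.0}),
            _r("R1", {"m0_c": -1.0, "p_c": 1.0}, "gA"),
            _r("R2", {"m0_c": -1.0, "p_c": 1.0}, "gB or gC"),
            _r("BIOMASS", {"p_c": -1.0}),
        ]
        model = _toy(["glc_e", "m0_c", "p_c"], rxns, atpm=False)
        m = apply_medium(model, MediumSpec(uptake_limits={"EX_glc": 10.0}, atpm_flux=0.0))
        problem = SuppressionProblem(m, frozenset(("gA",)), "gene", 2)
        sols = enumerate_alternatives(problem, k=10)
        assert {frozenset(s.suppressed) for s in sols} == {frozenset(("gB", "gC"))}
        only_one = enumerate_alternatives(problem, k=1)
        assert len(only_one) == 1

    def test_k_caps_enumeration(self, motifs):
        fx = motifs["compartment_duplicate"]
        m = apply_medium(fx.model, fx.medium)
        problem = SuppressionProblem(
            m, frozenset(fx.ground_truth["target_pair"]), "reaction", 1
        )
        assert len(enumerate_alternatives(problem, k=2)) == 2
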