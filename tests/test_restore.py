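"""Growth restoration: candidate pools, the addition MILP, medium fixes."""

import pytest

from gemcurate import apply_medium, build_candidate_pool, resolve_medium, restore_growth
from gemcurate.fba import FBAProblem
from gemcurate.fixtures import FixtureSpec, _r, _toy, generate_fixture
from gemcurate.model import GLOBAL_BOUND, MediumSpec
from gemcurate.restore import apply_candidates, parse_reaction_database, parse_reaction_equation

from conftest import brute_force_restorations


class TestDatabaseParsing:
    def test_equation_with_coefficients_and_reversibility(self):
        r = parse_reaction_equation("R1", "2 a_c + b_c <=> c_c")
        assert r.stoichiometry == {"a_c": -2.0, "b_c": -1.0, "c_c": 1.0}
        assert r.lower_bound == -GLOBAL_BOUND
        r2 = parse_reaction_equation("R2", "a_c => b_c")
        assert r2.lower_bound == 0.0

    def test_malformed_line_reports_line_number(self, tmp_path):
        path = tmp_path / "db.tsv"
        path.write_text("R1\ta_c => b_c\nbroken-line\n")
        with pytest.raises(ValueError, match="2"):
            parse_reaction_database(path)

    def test_file_round_trip_through_cli_format(self, tmp_path):
        path = tmp_path / "db.tsv"
        path.write_text("# comment\nR1\ta_c + 2 b_c => c_c\nR2\tx_c <=> y_c\n")
        rxns = parse_reaction_database(path)
        assert [r.id for r in rxns] == ["R1", "R2"]


class TestCandidatePool:
    def test_irreversible_reactions_become_relaxation_candidates(self, basic_fixture):
        pool = build_candidate_pool(basic_fixture.model)
        relax = {c.target_reaction for c in pool if c.kind == "reversibility_relaxation"}
        # every irreversible non-exchange, non-biomass/ATPM reaction is eligible
        for r in basic_fixture.model.reactions:
            if (r.lower_bound == 0.0 and not r.is_exchange
                    and r.id not in ("BIOMASS", "ATPM")):
                assert r.id in relax

    def test_db_reaction_for_planted_lesion_included(self, basic_fixture):
        pool = build_candidate_pool(
            basic_fixture.model, db_reactions=basic_fixture.db_reactions
        )
        assert any(c.id == "db:DBR0" for c in pool)

    def test_disabling_mechanisms_empties_them(self, basic_fixture):
        pool = build_candidate_pool(
            basic_fixture.model,
            enable_relaxations=False,
            enable_transports=False,
            enable_exchanges=False,
        )
        kinds = {c.kind for c in pool}
        assert "reversibility_relaxation" not in kinds
        assert "transport_addition" not in kinds
        assert "exchange_addition" not in kinds

    def test_candidates_disjoint_from_model_ids(self, basic_fixture):
        pool = build_candidate_pool(
            basic_fixture.model, db_reactions=basic_fixture.db_reactions
        )
        existing = {r.id for r in basic_fixture.model.reactions}
        for c in pool:
            if c.reaction is not None:
                assert c.reaction.id not in existing


class TestRestoreGrowth:
    def test_planted_lesion_fixed_by_single_db_addition(self, basic_fixture, basic_model):
        (genes, fix), = basic_fixture.ground_truth["mismatches"]["NGG"]
        pool = build_candidate_pool(
            basic_fixture.model, db_reactions=basic_fixture.db_reactions
        )
        sols = restore_growth(basic_model, genes, pool, max_additions=2)
        supports = {frozenset(c.id for c in s.additions) for s in sols}
        assert frozenset((f"db:{fix['reaction_id']}",)) in supports
        assert all(s.cardinality == 1 for s in sols)

    def test_viable_mutant_returns_cardinality_zero(self, basic_fixture, basic_model):
        pool = build_candidate_pool(basic_fixture.model)
        sols = restore_growth(basic_model, ("gIa0",), pool)
        assert len(sols) == 1 and sols[0].cardinality == 0

    def test_unfixable_mutant_returns_empty(self, basic_fixture, basic_model):
        from gemcurate.restore import CandidatePool

        sols = restore_growth(basic_model, ("gE0",), CandidatePool(()), max_additions=1)
        assert sols == []

    def test_relaxation_only_rescue(self):
        rxns = [
            _r("EX_glc", {"glc_e": -1.0}, lb=-GLOBAL_BOUND),
            _r("GLCt", {"glc_e": -1.0, "m0_c": 1.0}),
            _r("MAIN", {"m0_c": -1.0, "p_c": 1.0}, "gMain"),
            _r("DRAIN", {"p_c": -1.0, "m0_c": 1.0}),  # reversed it makes p
            _r("BIOMASS", {"p_c": -1.0}),
        ]
        model = _toy(["glc_e", "m0_c", "p_c"], rxns, atpm=False)
        m = apply_medium(model, MediumSpec(uptake_limits={"EX_glc": 10.0}, atpm_flux=0.0))
        pool = build_candidate_pool(model, enable_transports=False, enable_exchanges=False)
        sols = restore_growth(m, ("gMain",), pool, max_additions=1)
        assert {c.id for s in sols for c in s.additions} == {"relax:DRAIN"}

    @pytest.mark.parametrize("seed", [71, 72, 73])
    def test_matches_subset_enumeration_oracle(self, seed):
        fx = generate_fixture(FixtureSpec(seed=seed), verify=False)
        m = apply_medium(fx.model, fx.medium)
        pool = build_candidate_pool(
            fx.model, db_reactions=fx.db_reactions,
            enable_transports=False, enable_exchanges=False,
        )
        assert len(pool) <= 20
        (genes, _fix), = fx.ground_truth["mismatches"]["NGG"]
        sols = restore_growth(m, genes, pool, max_additions=2, max_alternates=50)
        milp_supports = {frozenset(c.id for c in s.additions) for s in sols}
        oracle = brute_force_restorations(m, genes, pool, max_additions=2)
        assert milp_supports == oracle

    def test_every_solution_reverified_by_fba(self, basic_fixture, basic_model):
        (genes, _), = basic_fixture.ground_truth["mismatches"]["NGG"]
        pool = build_candidate_pool(
            basic_fixture.model, db_reactions=basic_fixture.db_reactions
        )
        for sol in restore_growth(basic_model, genes, pool, max_additions=2):
            edited = apply_candidates(basic_model, sol.additions)
            state = FBAProblem(edited).solve(frozenset(genes))
            assert state.objective == pytest.approx(sol.verified_biomass, abs=1e-6)
            assert state.objective >= 0.01 * FBAProblem(basic_model).solve().objective - 1e-6

    def test_restoration_keeps_wild_type_healthy(self, basic_fixture, basic_model):
        (genes, _), = basic_fixture.ground_truth["mismatches"]["NGG"]
        pool = build_candidate_pool(
            basic_fixture.model, db_reactions=basic_fixture.db_reactions
        )
        wt = FBAProblem(basic_model).solve().objective
        for sol in restore_growth(basic_model, genes, pool, max_additions=2):
            edited = apply_candidates(basic_model, sol.additions)
            assert FBAProblem(edited).solve().objective >= wt - 1e-9


class TestResolveMedium:
    def test_vitamin_style_uptake_fix(self):
        """A biosynthesis lesion fixed by feeding the product from the
        medium rather than editing the network."""
        rxns = [
            _r("EX_glc", {"glc_e": -1.0}, lb=-GLOBAL_BOUND),
            _r("EX_ribo", {"ribo_e": -1.0}, lb=0.0),
            _r("GLCt", {"glc_e": -1.0, "m0_c": 1.0}),
            _r("RIBOt", {"ribo_e": -1.0, "ribo_c": 1.0}),
            _r("RIBOSYN", {"m0_c": -1.0, "ribo_c": 1.0}, "gRIB"),
            _r("BIOMASS", {"ribo_c": -1.0}),
        ]
        model = _toy(["glc_e", "ribo_e", "m0_c", "ribo_c"], rxns, atpm=False)
        m = apply_medium(model, MediumSpec(uptake_limits={"EX_glc": 10.0}, atpm_flux=0.0))
        mods = resolve_medium(m, ("gRIB",), "ribo")
        assert [mod.kind for mod in mods] == ["medium_component"]

    def test_internal_only_compound_needs_exchange_and_transport(self, motifs):
        fx = motifs["auxotrophy_rescue"]
        m = apply_medium(fx.model, fx.medium)
        mods = resolve_medium(m, fx.ground_truth["target_pair"], "mev")
        kinds = sorted(mod.kind for mod in mods)
        assert kinds == ["exchange_addition", "medium_component", "transport_addition"]

    def test_compound_with_no_route_to_biomass_returns_empty(self, basic_model):
        # the dead-end metabolite cannot rescue the essential-gene mutant
        assert resolve_medium(basic_model, ("gE0",), "d0b") == []
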