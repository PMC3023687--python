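"""Model containers, SBML round-tripping, validation, media."""

import itertools

import pytest

from gemcurate import apply_medium, generate_fixture, read_model, write_model
from gemcurate.fba import max_biomass
from gemcurate.fixtures import FixtureSpec
from gemcurate.gpr import parse_gpr
from gemcurate.model import (
    GLOBAL_BOUND,
    MediumSpec,
    MetabolicModel,
    Metabolite,
    ModelValidationError,
    Reaction,
    SBMLFormatError,
)


def tiny_model(**overrides):
    kwargs = dict(
        id="tiny",
        metabolites=(
            Metabolite(id="a_c", compartment="c"),
            Metabolite(id="b_c", compartment="c"),
        ),
        reactions=(
            Reaction(id="R1", stoichiometry={"a_c": -1.0, "b_c": 1.0},
                     lower_bound=0.0, gpr=parse_gpr("g1")),
            Reaction(id="EX_a", stoichiometry={"a_c": -1.0}, lower_bound=-10.0),
            Reaction(id="BIO", stoichiometry={"b_c": -1.0}, lower_bound=0.0),
        ),
        genes=frozenset(("g1",)),
        biomass_reaction_id="BIO",
        compartments=("c",),
    )
    kwargs.update(overrides)
    return MetabolicModel(**kwargs)


class TestValidation:
    def test_valid_model_passes(self):
        assert tiny_model().validate() == []

    def test_lb_above_ub_rejected(self):
        bad = tiny_model(reactions=(
            Reaction(id="R1", stoichiometry={"a_c": -1.0}, lower_bound=5.0, upper_bound=1.0),
        ), biomass_reaction_id=None, genes=frozenset())
        with pytest.raises(ModelValidationError, match="LB"):
            bad.validate()

    def test_dangling_metabolite_rejected(self):
        bad = tiny_model(reactions=(
            Reaction(id="R1", stoichiometry={"ghost_c": -1.0, "a_c": 1.0}),
        ), biomass_reaction_id=None, genes=frozenset())
        with pytest.raises(ModelValidationError, match="ghost_c"):
            bad.validate()

    def test_undeclared_gpr_gene_rejected(self):
        bad = tiny_model(genes=frozenset())
        with pytest.raises(ModelValidationError, match="undeclared"):
            bad.validate()

    def test_empty_model_warns_but_passes(self):
        empty = MetabolicModel(id="void", metabolites=(), reactions=(), genes=frozenset())
        assert "no reactions" in empty.validate()[0]

    def test_duplicate_reaction_addition_rejected(self):
        m = tiny_model()
        with pytest.raises(ModelValidationError, match="duplicate"):
            m.with_reactions(added=[Reaction(id="R1", stoichiometry={"a_c": -1.0})])


class TestSBMLRoundTrip:
    def test_structural_and_gpr_equality(self, tmp_path):
        fx = generate_fixture(FixtureSpec(seed=5))
        path = tmp_path / "model.xml"
        write_model(fx.model, path)
        back = read_model(path)
        assert back.genes == fx.model.genes
        assert back.biomass_reaction_id == fx.model.biomass_reaction_id
        assert back.atpm_reaction_id == fx.model.atpm_reaction_id
        assert {r.id for r in back.reactions} == {r.id for r in fx.model.reactions}
        for r in fx.model.reactions:
            r2 = back.reaction(r.id)
            assert (r.lower_bound, r.upper_bound) == (r2.lower_bound, r2.upper_bound)
            assert dict(r.stoichiometry) == dict(r2.stoichiometry)
            genes = sorted(r.gpr.genes())
            assert len(genes) <= 8
            for bits in itertools.product([0, 1], repeat=len(genes)):
                dels = {g for g, b in zip(genes, bits) if not b}
                assert r.gpr.evaluate(dels) == r2.gpr.evaluate(dels)

    def test_empty_gpr_round_trips_as_empty(self, tmp_path):
        m = tiny_model()
        path = tmp_path / "m.xml"
        write_model(m, path)
        assert read_model(path).reaction("EX_a").gpr.is_empty

    def test_relaxed_bound_round_trips(self, tmp_path):
        m = tiny_model()
        relaxed = m.with_reactions(
            updated=[m.reaction("R1").with_bounds(-GLOBAL_BOUND, GLOBAL_BOUND)]
        )
        path = tmp_path / "m.xml"
        write_model(relaxed, path)
        assert read_model(path).reaction("R1").lower_bound == -GLOBAL_BOUND

    def test_empty_gene_id_is_serialization_error(self, tmp_path):
        m = tiny_model(genes=frozenset(("g1", "")))
        with pytest.raises(SBMLFormatError):
            write_model(m, tmp_path / "m.xml")

    def test_parse_failure_names_problem(self, tmp_path):
        bad = tmp_path / "bad.xml"
        bad.write_text("<sbml>this is not valid</sbml>")
        with pytest.raises(SBMLFormatError):
            read_model(bad)


class TestMedium:
    def test_uptake_limits_applied_and_atpm_fixed(self, basic_fixture):
        m = apply_medium(basic_fixture.model, basic_fixture.medium)
        ex = m.reaction("EX_glc")
        assert ex.lower_bound == -basic_fixture.medium.uptake_limits["EX_glc"]
        atpm = m.reaction("ATPM")
        assert atpm.lower_bound == atpm.upper_bound == basic_fixture.medium.atpm_flux

    def test_unlisted_exchanges_closed_and_unknown_rejected(self, basic_fixture):
        medium = MediumSpec(name="empty", uptake_limits={}, atpm_flux=0.0)
        closed = apply_medium(basic_fixture.model, medium)
        for r in closed.exchanges():
            assert r.lower_bound == 0.0
        assert max_biomass(closed).objective == pytest.approx(0.0, abs=1e-9)
        with pytest.raises(ModelValidationError, match="EX_missing"):
            apply_medium(
                basic_fixture.model,
                MediumSpec(name="bad", uptake_limits={"EX_missing": 1.0}),
            )

    def test_idempotent_and_rich_overrides_poor(self, basic_fixture):
        poor = basic_fixture.medium
        rich = MediumSpec(
            name="rich",
            uptake_limits={**poor.uptake_limits, "EX_glc": 20.0},
            atpm_flux=poor.atpm_flux,
        )
        via_poor = apply_medium(apply_medium(basic_fixture.model, poor), rich)
        direct = apply_medium(basic_fixture.model, rich)
        assert via_poor.reactions == direct.reactions
        twice = apply_medium(direct, rich)
        assert twice.reactions == direct.reactions

    def test_background_deletions_recorded(self, basic_fixture):
        medium = MediumSpec(
            name="strain",
            uptake_limits=basic_fixture.medium.uptake_limits,
            background_deletions=frozenset(("gX0",)),
        )
        m = apply_medium(basic_fixture.model, medium)
        assert m.background_deletions == frozenset(("gX0",))

    def test_config_file_round_trip(self, tmp_path, basic_fixture):
        medium = MediumSpec(
            name="minimal",
            uptake_limits={"EX_glc": 10.0, "EX_o2": 2.0},
            atpm_flux=1.0,
            background_deletions=frozenset(("his3", "leu2", "met15", "ura3")),
            supplements={"EX_met": 0.5},
        )
        path = tmp_path / "medium.cfg"
        medium.to_file(path)
        back = MediumSpec.from_file(path)
        assert back == medium

    def test_negative_uptake_rejected(self):
        with pytest.raises(ValueError):
            MediumSpec(uptake_limits={"EX_glc": -1.0})
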