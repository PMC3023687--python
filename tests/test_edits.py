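"""Model modifications, global/conditional vetting, batch curation."""

import pytest

from gemcurate import apply_medium, apply_modification, essential_genes, is_viable, vet_modification
from gemcurate.edits import Modification, apply_with_inverse, batch_curate
from gemcurate.fixtures import (
    FixtureSpec,
    PRPPS_LETHAL_COMBOS,
    REVISED_PRPPS_GPR,
    generate_fixture,
)
from gemcurate.gaps import find_blocked_reactions


class TestApplyModification:
    def test_gpr_rewrite_makes_listed_combinations_lethal(self, motifs):
        fx = motifs["prpps_gpr"]
        mod = Modification(
            kind="gpr_change",
            payload={"reaction_id": "PRPPS", "gpr": REVISED_PRPPS_GPR},
        )
        edited = apply_modification(fx.model, mod)
        m = apply_medium(edited, fx.medium)
        before = apply_medium(fx.model, fx.medium)
        for combo in PRPPS_LETHAL_COMBOS:
            assert is_viable(before, combo).viable
            assert not is_viable(m, combo).viable

    def test_biomass_substitute_unblocks_and_essentializes(self, motifs):
        fx = motifs["trna_charging"]
        m0 = apply_medium(fx.model, fx.medium)
        assert fx.ground_truth["blocked_reaction"] in find_blocked_reactions(m0)
        assert fx.ground_truth["gene"] not in essential_genes(m0).essential_genes
        mod = Modification(
            kind="biomass_substitute", payload=fx.ground_truth["biomass_substitute"]
        )
        m1 = apply_medium(apply_modification(fx.model, mod), fx.medium)
        assert fx.ground_truth["blocked_reaction"] not in find_blocked_reactions(m1)
        assert fx.ground_truth["gene"] in essential_genes(m1).essential_genes

    def test_proxy_pool_accepts_any_single_producer(self, motifs):
        from gemcurate.model import Metabolite, Reaction

        fx = motifs["trna_charging"]
        producers = [
            Reaction(id=f"PLP{i}", stoichiometry={src: -1.0, "plp_c": 1.0})
            for i, src in enumerate(["trp_c", "m0_c"])
        ]
        mod = Modification(
            kind="biomass_proxy_pool",
            payload={"remove": "trp_c", "proxy": Metabolite(id="plp_c"),
                     "producers": producers},
        )
        edited = apply_modification(fx.model, mod)
        m = apply_medium(edited, fx.medium)
        # knocking out either producer alone leaves the other route
        assert is_viable(m, (), _problem=None).viable
        from gemcurate.fba import FBAProblem

        for rid in ("PLP0", "PLP1"):
            state = FBAProblem(m).solve(disabled_reactions=[rid])
            assert state.objective > 0

    def test_gpr_change_with_unknown_reaction_errors(self, motifs):
        fx = motifs["prpps_gpr"]
        mod = Modification(kind="gpr_change", payload={"reaction_id": "NOPE", "gpr": "a"})
        with pytest.raises(KeyError):
            apply_modification(fx.model, mod)

    def test_biomass_edit_on_non_reactant_errors(self, motifs):
        fx = motifs["prpps_gpr"]
        mod = Modification(
            kind="biomass_substitute",
            payload={"remove": "glc_e", "add_reactant": "x", "add_product": "y"},
        )
        with pytest.raises(ValueError, match="reactant"):
            apply_modification(fx.model, mod)

    def test_unknown_kind_rejected_at_construction(self):
        with pytest.raises(ValueError):
            Modification(kind="teleport", payload={})

    @pytest.mark.parametrize(
        "kind,payload_key",
        [("gene_suppression", "gene_id"), ("reaction_suppression", "reaction_id")],
    )
    def test_apply_then_inverse_restores_model(self, motifs, kind, payload_key):
        fx = motifs["conditional_suppression"]
        payload = {"gene_id": "gC"} if kind == "gene_suppression" else {"reaction_id": "RM"}
        mod = Modification(kind=kind, payload=payload)
        edited, inverse = apply_with_inverse(fx.model, mod)
        assert edited.reactions != fx.model.reactions
        restored, _ = apply_with_inverse(edited, inverse)
        assert restored.reactions == fx.model.reactions
        assert restored.genes == fx.model.genes


class TestVetting:
    def test_suppression_conditional_in_poor_global_in_rich(self, motifs):
        from gemcurate.fixtures import conditional_suppression_fixture

        fx, rich = conditional_suppression_fixture()
        mod = Modification(kind="gene_suppression", payload={"gene_id": "gC"})
        report = vet_modification(fx.model, mod, fx.calls, [fx.medium, rich])
        assert report.verdicts == {"minimal": "conditional", "rich": "global"}
        assert report.verdict == "conditional"
        assert any(flip[0] == "minimal" for flip in report.flipped)

    def test_identity_modification_is_global(self, motifs):
        fx = motifs["conditional_suppression"]
        noop = Modification(
            kind="gpr_change",
            payload={"reaction_id": "RM", "gpr": "gMa or gMb"},
        )
        report = vet_modification(fx.model, noop, fx.calls, [fx.medium])
        assert report.verdict == "global" and not report.flipped

    def test_fixing_suppression_without_collateral_is_global(self, basic_fixture):
        (genes, fix), = basic_fixture.ground_truth["mismatches"]["GNG"]
        mod = Modification(kind="gene_suppression", payload={"gene_id": fix["gene_id"]})
        report = vet_modification(
            basic_fixture.model, mod, basic_fixture.calls, [basic_fixture.medium]
        )
        assert report.verdict == "global"


class TestBatchCuration:
    def test_planted_mismatches_resolved_in_order(self, basic_fixture):
        ledger = batch_curate(
            basic_fixture.model,
            basic_fixture.calls,
            [basic_fixture.medium],
            db_reactions=basic_fixture.db_reactions,
        )
        by_class = {e.mismatch_label: e for e in ledger.entries}
        assert by_class["NGG"].accepted
        assert by_class["GNG"].accepted
        assert by_class["GSL"].accepted
        labels = [e.mismatch_label for e in ledger.entries]
        assert labels == sorted(
            labels, key=["NGG", "GNG", "GSL", "ESSL", "SLG", "SLES"].index
        )

    def test_metrics_never_degrade_under_global_only_acceptance(self):
        for seed in (81, 82):
            fx = generate_fixture(FixtureSpec(seed=seed), verify=False)
            ledger = batch_curate(
                fx.model, fx.calls, [fx.medium], db_reactions=fx.db_reactions
            )
            before, after = ledger.metrics_before, ledger.metrics_after
            if before.specificity is not None and after.specificity is not None:
                assert after.specificity >= before.specificity
            if (before.double_specificity is not None
                    and after.double_specificity is not None):
                assert after.double_specificity >= before.double_specificity

    def test_empty_mismatch_list_changes_nothing(self, motifs):
        fx = motifs["prpps_gpr"]
        consistent_calls = []  # nothing to compare -> nothing to fix
        ledger = batch_curate(fx.model, consistent_calls, [fx.medium])
        assert ledger.entries == []
        assert ledger.final_model.reactions == fx.model.reactions

    def test_conditional_only_fix_recorded_not_accepted(self, motifs):
        from gemcurate.fixtures import conditional_suppression_fixture

        fx, _rich = conditional_suppression_fixture()
        # only the poor medium: the lone fix (suppress gC) is conditional
        ledger = batch_curate(fx.model, fx.calls, [fx.medium])
        gsl = [e for e in ledger.entries if e.mismatch_label == "GSL"]
        assert gsl and not gsl[0].accepted
        assert gsl[0].verdict in ("conditional", "unresolved")
        assert ledger.final_model.reactions == fx.model.reactions

    def test_replay_is_deterministic(self, basic_fixture):
        runs = [
            batch_curate(
                basic_fixture.model,
                basic_fixture.calls,
                [basic_fixture.medium],
                db_reactions=basic_fixture.db_reactions,
            )
            for _ in range(2)
        ]
        snap = [
            [(e.mismatch_label, e.mismatch_genes, e.verdict, e.accepted)
             for e in run.entries]
            for run in runs
        ]
        assert snap[0] == snap[1]
        assert runs[0].final_model.reactions == runs[1].final_model.reactions
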