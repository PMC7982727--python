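"""Decision-tree evaluation: answers, policies, traces, screening."""

import pytest

from pddikit import fixtures as fx
from pddikit.errors import MissingDataError, MissingValueSetError, UnitError
from pddikit.engine import (
    Comparator,
    MedicationRecord,
    ObservationRecord,
    PatientContext,
    Question,
    QuestionKind,
    answer_question,
    applies,
    evaluate,
    reachable_outcomes,
)
from pddikit.model import ActionCategory, ValueSetRef, merge_classifications


def ctx_with(*med_codes, routes=None, conditions=(), inr=None):
    routes = routes or {}
    meds = tuple(
        MedicationRecord(concept=fx.rx(c), route=routes.get(c, "oral"))
        for c in med_codes
    )
    obs = ()
    if inr is not None:
        obs = (ObservationRecord(concept=fx.INR, value=inr, unit="ratio"),)
    return PatientContext(
        medications=meds,
        conditions=tuple(fx.cond(c) for c in conditions),
        observations=obs,
    )


INR_QUESTION = Question(
    id="q-inr", kind=QuestionKind.OBSERVATION_COMPARE, observation=fx.INR,
    comparator=Comparator.GT, threshold=3.0, unit="ratio",
)


class TestAnswerQuestion:
    def test_medication_membership(self, registry):
        q = Question(id="q", kind=QuestionKind.MED_IN_VALUESET,
                     value_set=ValueSetRef("ppis"))
        assert answer_question(q, ctx_with("imatinib", "omeprazole"), registry) == "yes"
        assert answer_question(q, ctx_with("imatinib"), registry) == "no"

    def test_condition_membership_absence_is_no(self, registry):
        q = Question(id="q", kind=QuestionKind.CONDITION_IN_VALUESET,
                     value_set=ValueSetRef("ulcer-ugib-history"))
        assert answer_question(q, ctx_with("warfarin",
                                           conditions=("peptic-ulcer",)),
                               registry) == "yes"
        assert answer_question(q, ctx_with("warfarin"), registry) == "no"

    def test_route_question_discriminates_oral_from_topical(self, registry):
        q = Question(id="q", kind=QuestionKind.MED_ROUTE_IS,
                     value_set=ValueSetRef("diclofenac"), route="topical")
        oral = ctx_with("warfarin", "diclofenac")
        topical = ctx_with("warfarin", "diclofenac",
                           routes={"diclofenac": "topical"})
        assert answer_question(q, oral, registry) == "no"
        assert answer_question(q, topical, registry) == "yes"

    def test_missing_observation_is_unknown(self, registry):
        assert answer_question(INR_QUESTION, ctx_with("warfarin"), registry) == "unknown"

    @pytest.mark.parametrize("inr,expected", [(3.5, "yes"), (2.0, "no"), (3.0, "no")])
    def test_observation_comparison(self, registry, inr, expected):
        assert answer_question(INR_QUESTION, ctx_with("warfarin", inr=inr),
                               registry) == expected

    def test_unit_mismatch_is_an_error(self, registry):
        ctx = PatientContext(observations=(
            ObservationRecord(concept=fx.INR, value=3.5, unit="s"),
        ))
        with pytest.raises(UnitError):
            answer_question(INR_QUESTION, ctx, registry)

    def test_unresolvable_value_set_is_an_error(self, registry):
        q = Question(id="q", kind=QuestionKind.MED_IN_VALUESET,
                     value_set=ValueSetRef("no-such-set"))
        with pytest.raises(MissingValueSetError):
            answer_question(q, ctx_with("warfarin"), registry)


class TestTkiPpiTree:
    """The worked TKI–PPI branching: management depends on which TKI."""

    PARTITION = {
        "imatinib": ActionCategory.NO_SPECIAL_PRECAUTIONS,
        "ponatinib": ActionCategory.NO_SPECIAL_PRECAUTIONS,
        "nilotinib": ActionCategory.ASSESS_RISK_AND_TAKE_ACTION,
        "bosutinib": ActionCategory.USE_ONLY_IF_BENEFIT_OUTWEIGHS_RISK,
        "dasatinib": ActionCategory.USE_ONLY_IF_BENEFIT_OUTWEIGHS_RISK,
    }

    @pytest.mark.parametrize("tki,expected", PARTITION.items())
    def test_per_tki_outcome(self, tki_ppi, registry, tki, expected):
        outcome, trace = evaluate(
            tki_ppi.decision_tree, ctx_with(tki, "omeprazole"), registry
        )
        assert outcome.action_category is expected
        assert len(trace.steps) >= 2

    def test_partition_covers_exactly_three_actions(self, tki_ppi, registry):
        cats = {
            evaluate(tki_ppi.decision_tree, ctx_with(t, "omeprazole"), registry)[0]
            .action_category
            for t in self.PARTITION
        }
        assert cats == set(ActionCategory)

    def test_no_ppi_means_no_special_precautions(self, tki_ppi, registry):
        outcome, _ = evaluate(tki_ppi.decision_tree, ctx_with("dasatinib"), registry)
        assert outcome.action_category is ActionCategory.NO_SPECIAL_PRECAUTIONS


class TestPolicies:
    def test_strict_raises_on_missing_inr(self, warfarin_nsaid, registry):
        ctx = ctx_with("warfarin", "naproxen")
        with pytest.raises(MissingDataError, match="q-inr-high"):
            evaluate(warfarin_nsaid.decision_tree, ctx, registry, "strict")

    def test_conservative_records_unknown_and_returns_outcome(
        self, warfarin_nsaid, registry
    ):
        ctx = ctx_with("warfarin", "naproxen")
        outcome, trace = evaluate(
            warfarin_nsaid.decision_tree, ctx, registry, "conservative"
        )
        assert outcome.action_category is ActionCategory.ASSESS_RISK_AND_TAKE_ACTION
        assert any(s.answer == "unknown" for s in trace.steps)

    def test_abstain_returns_reachable_set(self, warfarin_nsaid, registry):
        ctx = ctx_with("warfarin", "naproxen")
        outcomes, _ = evaluate(
            warfarin_nsaid.decision_tree, ctx, registry, "abstain"
        )
        assert isinstance(outcomes, frozenset)
        assert 1 <= len(outcomes) <= 2
        assert outcomes == reachable_outcomes(
            warfarin_nsaid.decision_tree, ctx, registry
        )

    def test_no_unknowns_all_policies_agree(self, warfarin_nsaid, registry):
        ctx = ctx_with("warfarin", "naproxen", inr=2.0)
        strict, _ = evaluate(warfarin_nsaid.decision_tree, ctx, registry, "strict")
        conservative, _ = evaluate(
            warfarin_nsaid.decision_tree, ctx, registry, "conservative"
        )
        abstain, _ = evaluate(warfarin_nsaid.decision_tree, ctx, registry, "abstain")
        assert strict == conservative
        assert abstain == frozenset({strict})

    def test_conservative_matches_bruteforce_oracle_on_random_contexts(
        self, registry
    ):
        """Conservative classification == merge over all completions of the
        unknown answers, across both fixture trees and seeded contexts with
        the INR observation stripped (forcing unknowns)."""
        import dataclasses

        trees = [
            fx.warfarin_nsaid_artifact().decision_tree,
            fx.tki_ppi_artifact().decision_tree,
        ]
        contexts = fx.generate_contexts(seed=123, n=100, registry=registry)
        checked = 0
        for ctx in contexts:
            stripped = dataclasses.replace(ctx, observations=())
            for tree in trees:
                outcome, _ = evaluate(tree, stripped, registry, "conservative")
                reachable = reachable_outcomes(tree, stripped, registry)
                expected = merge_classifications(
                    [o.classification for o in reachable]
                )
                assert outcome.classification is expected
                assert outcome in reachable
                checked += 1
        assert checked == 200

    def test_determinism(self, warfarin_nsaid, registry):
        ctx = ctx_with("warfarin", "diclofenac", conditions=("peptic-ulcer",))
        runs = [
            evaluate(warfarin_nsaid.decision_tree, ctx, registry, "conservative")
            for _ in range(3)
        ]
        assert runs[0] == runs[1] == runs[2]

    def test_unknown_policy_name_rejected(self, warfarin_nsaid, registry):
        with pytest.raises(ValueError):
            evaluate(warfarin_nsaid.decision_tree, ctx_with("warfarin"),
                     registry, "lenient")


class TestApplies:
    def test_both_slots_matched(self, warfarin_nsaid, registry):
        assert applies(warfarin_nsaid, ctx_with("warfarin", "naproxen"), registry)

    def test_single_slot_not_enough(self, warfarin_nsaid, tki_ppi, registry):
        assert not applies(warfarin_nsaid, ctx_with("warfarin"), registry)
        assert not applies(tki_ppi, ctx_with("omeprazole"), registry)

    def test_tki_ppi_pair_applies(self, tki_ppi, registry):
        assert applies(tki_ppi, ctx_with("nilotinib", "lansoprazole"), registry)


class TestTraces:
    def test_trace_names_visited_questions_in_order(self, tki_ppi, registry):
        _, trace = evaluate(
            tki_ppi.decision_tree, ctx_with("nilotinib", "omeprazole"), registry
        )
        assert [s.question_id for s in trace.steps] == [
            "q-ppi", "q-tki-ph-insensitive", "q-tki-nilotinib"
        ]
        assert "omeprazole" in trace.steps[0].basis

    def test_trace_renders_one_line_per_step(self, tki_ppi, registry):
        _, trace = evaluate(
            tki_ppi.decision_tree, ctx_with("imatinib", "omeprazole"), registry
        )
        rendered = trace.render()
        assert len(rendered.splitlines()) == len(trace.steps)


class TestTreeStructure:
    def test_fixture_trees_enumerate_leaves_and_questions(
        self, warfarin_nsaid, tki_ppi
    ):
        assert len(warfarin_nsaid.decision_tree.leaves()) == 5
        assert len(warfarin_nsaid.decision_tree.questions()) == 4
        assert len(tki_ppi.decision_tree.leaves()) == 5
        assert len(tki_ppi.decision_tree.questions()) == 4

    def test_duplicate_medication_records_rejected(self):
        med = MedicationRecord(concept=fx.rx("warfarin"), route="oral")
        with pytest.raises(ValueError):
            PatientContext(medications=(med, med))
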