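"""Conformance validation: required-element errors, best-practice warnings."""

import dataclasses

import pytest

from pddikit.model import (
    ClinicalConsequence,
    DrugInvolved,
    Frequency,
    FrequencyKind,
    Mechanism,
    OperationalClassification,
    RecommendedAction,
    SeriousnessAssessment,
)
from pddikit.validator import (
    check_best_practices,
    check_required,
    list_rules,
    validate,
)

#: (field, replacement emptying that slot, expected rule id)
REQUIRED_FAULTS = [
    ("drugs", (), "E-REQ-DRUGS"),
    ("consequences", (), "E-REQ-CONSEQUENCE"),
    ("seriousness", None, "E-REQ-SERIOUSNESS"),  # nested; handled specially
    ("classifications", (), "E-REQ-OCS"),
    ("mechanism", None, "E-REQ-MECHANISM"),
    ("contextual_factors", (), "E-REQ-CONTEXT"),
    ("evidence", (), "E-REQ-EVIDENCE"),
]


def _drop_slot(artifact, field, replacement):
    if field == "seriousness":
        stripped = tuple(
            dataclasses.replace(c, seriousness=None) for c in artifact.consequences
        )
        return dataclasses.replace(artifact, consequences=stripped)
    return dataclasses.replace(artifact, **{field: replacement})


class TestRequiredRules:
    def test_conformant_fixture_has_no_issues(self, warfarin_nsaid):
        assert check_required(warfarin_nsaid) == []

    @pytest.mark.parametrize("field,replacement,rule_id",
                             REQUIRED_FAULTS,
                             ids=[f[2] for f in REQUIRED_FAULTS])
    def test_single_fault_isolation(self, warfarin_nsaid, field, replacement, rule_id):
        """Deleting exactly one required slot yields exactly one error,
        carrying the matching rule id."""
        broken = _drop_slot(warfarin_nsaid, field, replacement)
        issues = check_required(broken)
        assert len(issues) == 1
        assert issues[0].rule_id == rule_id
        assert issues[0].severity == "error"

    def test_emptied_actions_produce_no_error(self, warfarin_nsaid, registry):
        """Recommended action is recommended, not required."""
        no_actions = dataclasses.replace(warfarin_nsaid, actions=())
        assert check_required(no_actions) == []

    def test_absent_frequencies_produce_no_error(self, warfarin_nsaid):
        bare = dataclasses.replace(
            warfarin_nsaid, frequency_exposure=None, frequency_harm=None
        )
        assert check_required(bare) == []


class TestBestPracticeRules:
    def test_both_worked_fixtures_are_warning_free(self, warfarin_nsaid, tki_ppi,
                                                   registry):
        assert check_best_practices(warfarin_nsaid, registry) == []
        assert check_best_practices(tki_ppi, registry) == []

    def test_unknown_frequency_satisfies_bp8(self, tki_ppi, registry):
        """Explicitly 'unknown' frequencies are information, not a gap."""
        assert tki_ppi.frequency_exposure.kind is FrequencyKind.UNKNOWN
        issues = check_best_practices(tki_ppi, registry)
        assert not [i for i in issues if i.rule_id == "BP-8"]

    def test_absent_frequency_draws_bp8(self, warfarin_nsaid, registry):
        bare = dataclasses.replace(warfarin_nsaid, frequency_exposure=None)
        issues = check_best_practices(bare, registry)
        assert [i.rule_id for i in issues] == ["BP-8"]

    def test_action_without_evidence_draws_bp5(self, warfarin_nsaid, registry):
        acts = tuple(
            dataclasses.replace(a, evidence_refs=()) for a in warfarin_nsaid.actions
        )
        issues = check_best_practices(
            dataclasses.replace(warfarin_nsaid, actions=acts), registry
        )
        assert [i.rule_id for i in issues] == ["BP-5"]

    def test_free_text_drug_draws_bp1(self, warfarin_nsaid, registry):
        drugs = (warfarin_nsaid.drugs[0], DrugInvolved(text="some NSAID"))
        issues = check_best_practices(
            dataclasses.replace(warfarin_nsaid, drugs=drugs), registry
        )
        assert [i.rule_id for i in issues] == ["BP-1"]

    def test_uncoded_consequence_draws_bp2(self, warfarin_nsaid, registry):
        cons = tuple(
            dataclasses.replace(c, concepts=()) for c in warfarin_nsaid.consequences
        )
        issues = check_best_practices(
            dataclasses.replace(warfarin_nsaid, consequences=cons), registry
        )
        assert [i.rule_id for i in issues] == ["BP-2"]

    def test_unjustified_seriousness_draws_bp3(self, warfarin_nsaid, registry):
        cons = tuple(
            dataclasses.replace(c, seriousness=SeriousnessAssessment())
            for c in warfarin_nsaid.consequences
        )
        issues = check_best_practices(
            dataclasses.replace(warfarin_nsaid, consequences=cons), registry
        )
        assert [i.rule_id for i in issues] == ["BP-3"]

    def test_adopter_only_categories_draw_bp4(self, warfarin_nsaid, registry):
        cls = (OperationalClassification(category="house-system-red",
                                         statement="house rule"),)
        issues = check_best_practices(
            dataclasses.replace(warfarin_nsaid, classifications=cls), registry
        )
        assert [i.rule_id for i in issues] == ["BP-4"]

    def test_blank_known_mechanism_draws_bp6(self, warfarin_nsaid, registry):
        broken = dataclasses.replace(
            warfarin_nsaid, mechanism=Mechanism(known=True, description="  ")
        )
        issues = check_best_practices(broken, registry)
        assert [i.rule_id for i in issues] == ["BP-6"]

    def test_not_elucidated_marker_satisfies_bp6(self, warfarin_nsaid, registry):
        marked = dataclasses.replace(
            warfarin_nsaid, mechanism=Mechanism(known=False)
        )
        assert check_best_practices(marked, registry) == []

    def test_uncoded_unflagged_factor_draws_bp7(self, warfarin_nsaid, registry):
        factors = tuple(
            dataclasses.replace(f, concepts=(), free_text_last_resort=False)
            for f in warfarin_nsaid.contextual_factors
        )
        issues = check_best_practices(
            dataclasses.replace(warfarin_nsaid, contextual_factors=factors), registry
        )
        assert {i.rule_id for i in issues} == {"BP-7"}
        assert len(issues) == len(factors)


class TestValidateReport:
    def test_fixture_report_valid_with_zero_errors(self, warfarin_nsaid, registry):
        report = validate(warfarin_nsaid, registry)
        assert report.valid
        assert report.errors == ()

    def test_combined_faults_compose(self, warfarin_nsaid, registry):
        broken = dataclasses.replace(
            warfarin_nsaid,
            consequences=(),
            frequency_exposure=None,
            frequency_harm=None,
        )
        report = validate(broken, registry)
        assert not report.valid
        assert [i.rule_id for i in report.errors] == ["E-REQ-CONSEQUENCE"]
        assert len(report.warnings) >= 1
        assert {i.rule_id for i in report.warnings} == {"BP-8"}

    def test_warnings_never_invalidate(self, warfarin_nsaid, registry):
        acts = tuple(
            dataclasses.replace(a, evidence_refs=()) for a in warfarin_nsaid.actions
        )
        report = validate(dataclasses.replace(warfarin_nsaid, actions=acts), registry)
        assert report.valid and len(report.warnings) == 1

    def test_validation_is_pure(self, warfarin_nsaid, registry):
        broken = dataclasses.replace(warfarin_nsaid, evidence=())
        assert validate(broken, registry) == validate(broken, registry)

    def test_issue_order_follows_model_slots(self, warfarin_nsaid, registry):
        broken = dataclasses.replace(
            warfarin_nsaid, drugs=(), evidence=(), consequences=()
        )
        rule_ids = [i.rule_id for i in validate(broken, registry).issues
                    if i.severity == "error"]
        assert rule_ids == ["E-REQ-DRUGS", "E-REQ-CONSEQUENCE", "E-REQ-EVIDENCE"]


class TestRuleTable:
    def test_seven_required_and_eight_best_practice_rules(self):
        rules = list_rules()
        req = [r for r in rules if r.id.startswith("E-REQ-")]
        bp = [r for r in rules if r.id.startswith("BP-")]
        assert len(req) == 7
        assert len(bp) == 8
        assert len(rules) == 15

    def test_rule_ids_unique_with_citations(self):
        rules = list_rules()
        assert len({r.id for r in rules}) == len(rules)
        assert all(r.citation for r in rules)
        assert all(r.severity == "error" for r in rules if r.id.startswith("E-REQ-"))
        assert all(r.severity == "warning" for r in rules if r.id.startswith("BP-"))
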