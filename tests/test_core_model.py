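"""Core domain logic: concepts, seriousness, frequencies, the ORCA order."""

import itertools

import pytest
from hypothesis import given
from hypothesis import strategies as st

from pddikit.errors import (
    CardinalityError,
    DanglingReferenceError,
    FrequencyRangeError,
    VocabularyError,
)
from pddikit.model import (
    CodedConcept,
    DrugInvolved,
    DrugRole,
    EvidenceItem,
    FrequencyKind,
    OperationalClassification,
    OrcaCategory,
    RecommendedAction,
    SeriousnessReason,
    ValueSetRef,
    format_frequency,
    information_items,
    is_serious,
    merge_classifications,
    new_artifact,
    parse_frequency,
    restrictiveness_rank,
)


class TestCodedConcept:
    def test_identity_is_system_and_code_display_ignored(self):
        a = CodedConcept("DEMO-RX", "warfarin", "Warfarin")
        b = CodedConcept("DEMO-RX", "warfarin", "warfarin sodium")
        c = CodedConcept("OTHER", "warfarin", "Warfarin")
        assert a == b and hash(a) == hash(b)
        assert a != c

    @pytest.mark.parametrize("system,code", [("", "x"), ("x", "")])
    def test_empty_system_or_code_rejected(self, system, code):
        with pytest.raises(ValueError):
            CodedConcept(system, code)


class TestSeriousness:
    @pytest.mark.parametrize(
        "reasons,expected",
        [
            ({SeriousnessReason.DEATH}, True),
            (set(), False),
            ({SeriousnessReason.DISABILITY}, True),
            ({"death", "disability"}, True),
        ],
    )
    def test_serious_iff_reasons_nonempty(self, reasons, expected):
        assert is_serious(reasons) is expected

    def test_unknown_reason_token_rejected(self):
        with pytest.raises(VocabularyError):
            is_serious({"mild-rash"})

    @given(
        st.sets(st.sampled_from(list(SeriousnessReason))),
        st.sets(st.sampled_from(list(SeriousnessReason))),
    )
    def test_monotone_in_reason_sets(self, smaller, extra):
        """Adding reasons can never turn a serious consequence non-serious."""
        larger = smaller | extra
        if is_serious(smaller):
            assert is_serious(larger)


class TestParseFrequency:
    @pytest.mark.parametrize(
        "text,kind,value",
        [
            ("24.3%", FrequencyKind.PROPORTION, 0.243),
            ("0%", FrequencyKind.PROPORTION, 0.0),
            ("100%", FrequencyKind.PROPORTION, 1.0),
            ("Concomitant NSAIDs occur with 24.3% of warfarin courses of therapy.",
             FrequencyKind.PROPORTION, 0.243),
        ],
    )
    def test_percentage_dialect(self, text, kind, value):
        f = parse_frequency(text)
        assert f.kind is kind
        assert f.value == pytest.approx(value)

    @pytest.mark.parametrize("text", ["2.9–3.3", "2.9-3.3", "relative risk 2.9–3.3 higher"])
    def test_relative_risk_dialect(self, text):
        f = parse_frequency(text)
        assert f.kind is FrequencyKind.RELATIVE_RISK
        assert (f.low, f.high) == (2.9, 3.3)

    @pytest.mark.parametrize("text", ["Unknown", "unknown", " UNKNOWN "])
    def test_unknown_dialect(self, text):
        f = parse_frequency(text)
        assert f.kind is FrequencyKind.UNKNOWN
        assert f.value is None and f.low is None and f.high is None
        assert f.parsed

    def test_unparseable_text_preserved_with_flag(self):
        f = parse_frequency("rare, mostly anecdotal")
        assert f.kind is FrequencyKind.UNKNOWN
        assert f.description == "rare, mostly anecdotal"
        assert not f.parsed

    def test_percentage_out_of_range(self):
        with pytest.raises(FrequencyRangeError):
            parse_frequency("140%")

    def test_empty_text_rejected(self):
        with pytest.raises(ValueError):
            parse_frequency("  ")

    @given(st.floats(min_value=0, max_value=100).map(lambda x: round(x, 3)))
    def test_percent_format_round_trip(self, pct):
        """Parsing 'X%' and formatting back preserves X to 3 decimals."""
        out = format_frequency(parse_frequency(f"{pct}%"))
        assert out.endswith("%")
        assert float(out[:-1]) == pytest.approx(pct, abs=5e-4)

    def test_relative_risk_bounds_validated(self):
        with pytest.raises(FrequencyRangeError):
            parse_frequency("3.3–2.9")  # low > high


class TestOrcaOrder:
    def test_total_order_values(self):
        ranks = {c: restrictiveness_rank(c) for c in OrcaCategory}
        assert ranks[OrcaCategory.IGNORE] == 0
        assert ranks[OrcaCategory.NO_SPECIAL_PRECAUTIONS] == 1
        assert ranks[OrcaCategory.MINIMIZE_RISK] == 2
        assert ranks[OrcaCategory.USUALLY_AVOID] == 3
        assert ranks[OrcaCategory.AVOID] == 4
        assert len(set(ranks.values())) == 5

    def test_avoid_outranks_ignore(self):
        assert restrictiveness_rank(OrcaCategory.AVOID) > restrictiveness_rank(
            OrcaCategory.IGNORE
        )

    def test_unknown_category_rejected(self):
        with pytest.raises(VocabularyError):
            restrictiveness_rank("SEVERE")


class TestMergeClassifications:
    def test_empty_list_rejected(self):
        with pytest.raises(CardinalityError):
            merge_classifications([])

    def test_idempotent(self):
        assert merge_classifications([OrcaCategory.MINIMIZE_RISK]) is OrcaCategory.MINIMIZE_RISK

    def test_permutation_invariant_triple(self):
        trio = [OrcaCategory.IGNORE, OrcaCategory.USUALLY_AVOID, OrcaCategory.MINIMIZE_RISK]
        for perm in itertools.permutations(trio):
            assert merge_classifications(list(perm)) is OrcaCategory.USUALLY_AVOID

    def test_equals_pairwise_fold_over_all_subsets(self):
        """Brute-force oracle: for every non-empty subset of the five
        categories (31 cases) the merge equals a fold of pairwise max."""
        cats = list(OrcaCategory)
        for r in range(1, 6):
            for subset in itertools.combinations(cats, r):
                expected = subset[0]
                for c in subset[1:]:
                    expected = max(expected, c, key=restrictiveness_rank)
                assert merge_classifications(list(subset)) is expected


class TestArtifactConstruction:
    def test_fewer_than_two_drugs_is_cardinality_error(self):
        drug = DrugInvolved(role=DrugRole.OBJECT,
                            concept=CodedConcept("DEMO-RX", "warfarin"))
        with pytest.raises(CardinalityError):
            new_artifact(id="x", drugs=(drug,))

    def test_dangling_evidence_ref_rejected(self):
        drugs = (
            DrugInvolved(concept=CodedConcept("DEMO-RX", "a")),
            DrugInvolved(concept=CodedConcept("DEMO-RX", "b")),
        )
        with pytest.raises(DanglingReferenceError):
            new_artifact(
                id="x",
                drugs=drugs,
                classifications=(
                    OperationalClassification(
                        category=OrcaCategory.AVOID, evidence_refs=("nope",)
                    ),
                ),
                evidence=(EvidenceItem(id="ev-1"),),
            )

    def test_duplicate_evidence_ids_rejected(self):
        drugs = (
            DrugInvolved(concept=CodedConcept("DEMO-RX", "a")),
            DrugInvolved(concept=CodedConcept("DEMO-RX", "b")),
        )
        with pytest.raises(DanglingReferenceError):
            new_artifact(id="x", drugs=drugs,
                         evidence=(EvidenceItem(id="ev-1"), EvidenceItem(id="ev-1")))

    def test_drug_slot_requires_exactly_one_representation(self):
        with pytest.raises(ValueError):
            DrugInvolved(concept=CodedConcept("DEMO-RX", "a"),
                         value_set=ValueSetRef("nsaids"))
        with pytest.raises(ValueError):
            DrugInvolved()

    def test_substrategy_only_under_minimize_risk(self):
        with pytest.raises(ValueError):
            OperationalClassification(category=OrcaCategory.AVOID,
                                      sub_strategy="monitor")

    def test_action_text_required(self):
        with pytest.raises(ValueError):
            RecommendedAction(action_text="   ")


class TestSchemaRegistry:
    def test_ten_items_seven_required(self):
        items = information_items()
        assert len(items) == 10
        assert sum(i.required for i in items) == 7
        assert len({i.key for i in items}) == 10

    def test_frequencies_and_action_are_recommended_not_required(self):
        by_key = {i.key: i for i in information_items()}
        assert not by_key["actions"].required
        assert not by_key["frequency_exposure"].required
        assert not by_key["frequency_harm"].required
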