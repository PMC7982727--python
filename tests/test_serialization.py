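"""Interchange round-trips, byte stability, and the narrative renderer."""

import dataclasses
import json

import pytest

from pddikit import fixtures as fx
from pddikit.errors import DocumentParseError, RenderError
from pddikit.model import RecommendedAction
from pddikit.serialization import (
    FIXED_KEYS,
    from_document,
    render_narrative,
    to_document,
)
from pddikit.value_sets import ValueSetRegistry


class TestRoundTrip:
    def test_worked_fixtures_round_trip(self, warfarin_nsaid, tki_ppi, registry):
        for artifact in (warfarin_nsaid, tki_ppi):
            assert from_document(to_document(artifact, registry)) == artifact

    def test_all_exemplars_round_trip(self, exemplars, registry):
        for entry in exemplars:
            doc = to_document(entry.artifact, registry)
            assert from_document(doc) == entry.artifact

    def test_randomized_artifacts_round_trip(self, registry):
        for artifact in fx.generate_artifacts(seed=99, n=50):
            assert from_document(to_document(artifact, registry)) == artifact

    def test_serialization_is_byte_stable(self, warfarin_nsaid, registry):
        a = to_document(warfarin_nsaid, registry)
        b = to_document(from_document(a), registry)
        assert a == b

    def test_inline_valuesets_make_document_self_contained(self, tki_ppi, registry):
        doc = to_document(tki_ppi, registry, inline_valuesets=True)
        fresh = ValueSetRegistry()
        artifact = from_document(doc, fresh)
        assert artifact == tki_ppi
        assert "tkis" in fresh and "ppis" in fresh
        assert [c.code for c in fresh.expand("tkis")] == [
            "imatinib", "ponatinib", "nilotinib", "bosutinib", "dasatinib"
        ]


class TestDocumentShape:
    def test_all_twelve_fixed_keys_present_on_minimal_artifact(self, registry):
        minimal = fx.generate_artifacts(seed=1, n=1)[0]
        data = json.loads(to_document(minimal, registry))
        for key in FIXED_KEYS:
            assert key in data
        assert len(FIXED_KEYS) == 12

    def test_key_order_is_fixed(self, warfarin_nsaid, registry):
        data = json.loads(to_document(warfarin_nsaid, registry))
        assert tuple(data)[: len(FIXED_KEYS)] == FIXED_KEYS

    def test_unknown_frequency_serialized_never_omitted(self, tki_ppi, registry):
        data = json.loads(to_document(tki_ppi, registry))
        assert data["frequencyOfExposure"] == {"kind": "unknown"}
        assert data["frequencyOfHarm"] == {"kind": "unknown"}

    def test_missing_required_key_is_parse_error_naming_it(self, warfarin_nsaid,
                                                           registry):
        data = json.loads(to_document(warfarin_nsaid, registry))
        del data["drugsInvolved"]
        with pytest.raises(DocumentParseError, match="drugsInvolved"):
            from_document(json.dumps(data))

    def test_malformed_frequency_is_parse_error(self, warfarin_nsaid, registry):
        data = json.loads(to_document(warfarin_nsaid, registry))
        data["frequencyOfExposure"] = {"value": 0.2}  # no kind
        with pytest.raises(DocumentParseError, match="frequency"):
            from_document(json.dumps(data))

    def test_invalid_json_is_parse_error(self):
        with pytest.raises(DocumentParseError):
            from_document("{not json")

    def test_extension_keys_preserved_on_reemit(self, warfarin_nsaid, registry):
        data = json.loads(to_document(warfarin_nsaid, registry))
        data["x-local"] = {"note": "adopter extension"}
        artifact = from_document(json.dumps(data))
        assert ("x-local", {"note": "adopter extension"}) in artifact.extensions
        reemitted = json.loads(to_document(artifact, registry))
        assert reemitted["x-local"] == {"note": "adopter extension"}


class TestNarrative:
    def test_warfarin_narrative_carries_seriousness_rationale(self, warfarin_nsaid):
        text = render_narrative(warfarin_nsaid)
        assert ("may result in death, life-threatening hospitalization, "
                "and disability") in text

    def test_unknown_frequencies_print_unknown_verbatim(self, tki_ppi):
        text = render_narrative(tki_ppi)
        exposure = text.split("## Frequency of exposure")[1].splitlines()[1]
        harm = text.split("## Frequency of harm")[1].splitlines()[1]
        assert exposure == "Unknown"
        assert harm == "Unknown"

    def test_every_information_item_has_a_section(self, warfarin_nsaid):
        text = render_narrative(warfarin_nsaid)
        for heading in (
            "## Drugs involved",
            "## Clinical consequences and seriousness",
            "## Operational classification",
            "## Recommended actions",
            "## Mechanism of interaction",
            "## Contextual information / modifying factors",
            "## Frequency of exposure",
            "## Frequency of harm",
            "## Evidence",
        ):
            assert text.count(heading) == 1

    def test_no_actions_renders_none_stated(self, warfarin_nsaid):
        bare = dataclasses.replace(warfarin_nsaid, actions=())
        section = render_narrative(bare).split("## Recommended actions")[1]
        assert section.splitlines()[1] == "None stated"

    def test_evidence_refs_become_numbered_citations(self, warfarin_nsaid):
        text = render_narrative(warfarin_nsaid)
        # the classification cites the UGIB relative-risk study, item 1
        assert "[1]" in text

    def test_dangling_evidence_ref_is_render_error(self, warfarin_nsaid):
        broken = dataclasses.replace(
            warfarin_nsaid,
            actions=(RecommendedAction(action_text="x", evidence_refs=("ghost",)),),
        )
        with pytest.raises(RenderError, match="ghost"):
            render_narrative(broken)
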