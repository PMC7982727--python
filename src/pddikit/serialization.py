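"""Interchange format and clinician-facing narrative for PDDI artifacts.

The interchange format is a self-contained JSON dialect with FHIR-flavoured
camel-case keys emitted in a fixed order, so that serialization is
byte-stable and documents diff cleanly:

    id, title, version, drugsInvolved, clinicalConsequences,
    operationalClassifications, recommendedActions, mechanism,
    contextualFactors, evidence, frequencyOfExposure, frequencyOfHarm,
    [decisionTree], [valueSets], <extensions...>

Unknown frequencies serialize as ``{"kind": "unknown"}`` — never omitted —
because "unknown" is information.  Unknown top-level keys are preserved in
an extensions bag and re-emitted, so adopter extensions survive a
round-trip.  ``from_document(to_document(a))`` structurally equals ``a``
for every valid artifact.
"""

from __future__ import annotations

import json
from typing import Optional, Union

from .errors import DocumentParseError, RenderError
from .model import (
    ActionCategory,
    ClinicalConsequence,
    CodedConcept,
    ContextualFactor,
    ContextualFactorKind,
    DrugInvolved,
    DrugLevel,
    DrugRole,
    EvidenceItem,
    EvidenceStance,
    EvidenceType,
    Frequency,
    FrequencyKind,
    Mechanism,
    MinimizeRiskStrategy,
    OperationalClassification,
    OrcaCategory,
    PDDIArtifact,
    RecommendedAction,
    SeriousnessAssessment,
    SeriousnessReason,
    ValueSetRef,
    format_frequency,
)
from .engine import (
    Comparator,
    DecisionTree,
    InternalNode,
    Leaf,
    Node,
    Outcome,
    Question,
    QuestionKind,
)
from .value_sets import ValueSet, ValueSetRegistry

__all__ = ["to_document", "from_document", "render_narrative", "FIXED_KEYS"]

FIXED_KEYS = (
    "id",
    "title",
    "version",
    "drugsInvolved",
    "clinicalConsequences",
    "operationalClassifications",
    "recommendedActions",
    "mechanism",
    "contextualFactors",
    "evidence",
    "frequencyOfExposure",
    "frequencyOfHarm",
)
_OPTIONAL_KEYS = ("decisionTree", "valueSets")


# ---------------------------------------------------------------------------
# Encoding helpers
# ---------------------------------------------------------------------------


def _concept(c: CodedConcept) -> dict:
    return {"system": c.system, "code": c.code, "display": c.display}


def _concept_or_ref(x: Union[CodedConcept, ValueSetRef]) -> dict:
    if isinstance(x, ValueSetRef):
        return {"valueSet": x.id}
    return _concept(x)


def _drug(d: DrugInvolved) -> dict:
    out: dict = {"role": d.role.value, "level": d.level.value}
    if d.concept is not None:
        out["concept"] = _concept(d.concept)
    elif d.value_set is not None:
        out["valueSet"] = d.value_set.id
    else:
        out["text"] = d.text
    return out


def _seriousness(s: Optional[SeriousnessAssessment]) -> Optional[dict]:
    if s is None:
        return None
    return {
        "serious": s.serious,
        "reasons": [r.value for r in s.reasons],
        "rationale": s.rationale,
    }


def _consequence(c: ClinicalConsequence) -> dict:
    return {
        "description": c.description,
        "concepts": [_concept_or_ref(x) for x in c.concepts],
        "seriousness": _seriousness(c.seriousness),
    }


def _classification(c: OperationalClassification) -> dict:
    out: dict = {
        "category": c.category.value if isinstance(c.category, OrcaCategory) else c.category,
        "statement": c.statement,
    }
    if c.sub_strategy is not None:
        out["subStrategy"] = c.sub_strategy.value
    if c.condition:
        out["condition"] = c.condition
    out["evidenceRefs"] = list(c.evidence_refs)
    return out


def _action(a: RecommendedAction) -> dict:
    cat = a.action_category
    return {
        "actionText": a.action_text,
        "actionCategory": cat.value if isinstance(cat, ActionCategory) else cat,
        "evidenceRefs": list(a.evidence_refs),
    }


def _mechanism(m: Optional[Mechanism]) -> Optional[dict]:
    if m is None:
        return None
    return {
        "known": m.known,
        "description": m.description,
        "concepts": [_concept(c) for c in m.concepts],
    }


def _factor(f: ContextualFactor) -> dict:
    out: dict = {
        "kind": f.kind.value,
        "description": f.description,
        "concepts": [_concept_or_ref(x) for x in f.concepts],
        "effectNote": f.effect_note,
    }
    if f.free_text_last_resort:
        out["freeTextLastResort"] = True
    return out


def _frequency(f: Optional[Frequency]) -> Optional[dict]:
    if f is None:
        return None
    out: dict = {"kind": f.kind.value}
    if f.kind is FrequencyKind.PROPORTION:
        out["value"] = f.value
    elif f.kind is FrequencyKind.RELATIVE_RISK:
        out["low"] = f.low
        out["high"] = f.high
    if f.description:
        out["description"] = f.description
    if f.evidence_refs:
        out["evidenceRefs"] = list(f.evidence_refs)
    if not f.parsed:
        out["parsed"] = False
    return out


def _evidence(e: EvidenceItem) -> dict:
    return {
        "id": e.id,
        "stance": e.stance.value,
        "type": e.type.value,
        "citation": e.citation,
        "summary": e.summary,
    }


def _question(q: Question) -> dict:
    out: dict = {"id": q.id, "kind": q.kind.value, "text": q.text}
    if q.value_set is not None:
        out["valueSet"] = q.value_set.id
    if q.route is not None:
        out["route"] = q.route
    if q.observation is not None:
        out["observation"] = _concept(q.observation)
        out["comparator"] = q.comparator.value
        out["threshold"] = q.threshold
        out["unit"] = q.unit
    return out


def _node(n: Node) -> dict:
    if isinstance(n, Leaf):
        o = n.outcome
        return {
            "outcome": {
                "actionCategory": o.action_category.value,
                "classification": o.classification.value,
                "actionText": o.action_text,
                "evidenceRefs": list(o.evidence_refs),
            }
        }
    return {"question": _question(n.question), "yes": _node(n.yes), "no": _node(n.no)}


def _collect_vs_refs(artifact: PDDIArtifact) -> list[str]:
    refs: list[str] = []

    def add(x) -> None:
        if isinstance(x, ValueSetRef) and x.id not in refs:
            refs.append(x.id)

    for d in artifact.drugs:
        add(d.value_set)
    for c in artifact.consequences:
        for x in c.concepts:
            add(x)
    for f in artifact.contextual_factors:
        for x in f.concepts:
            add(x)
    tree = artifact.decision_tree
    if isinstance(tree, DecisionTree):
        for q in tree.questions():
            add(q.value_set)
    return refs


# ---------------------------------------------------------------------------
# Public API
# ---------------------------------------------------------------------------


def to_document(
    artifact: PDDIArtifact,
    registry: Optional[ValueSetRegistry] = None,
    *,
    inline_valuesets: bool = False,
) -> str:
    """Serialize an artifact to the interchange format (UTF-8 JSON text).

    Keys are emitted in the fixed dialect order; serializing the same
    artifact twice yields byte-identical output.  With
    ``inline_valuesets=True`` every value set the artifact references is
    resolved in ``registry`` and embedded under ``valueSets``, making the
    document self-contained.
    """
    doc: dict = {
        "id": artifact.id,
        "title": artifact.title,
        "version": artifact.version,
        "drugsInvolved": [_drug(d) for d in artifact.drugs],
        "clinicalConsequences": [_consequence(c) for c in artifact.consequences],
        "operationalClassifications": [
            _classification(c) for c in artifact.classifications
        ],
        "recommendedActions": [_action(a) for a in artifact.actions],
        "mechanism": _mechanism(artifact.mechanism),
        "contextualFactors": [_factor(f) for f in artifact.contextual_factors],
        "evidence": [_evidence(e) for e in artifact.evidence],
        "frequencyOfExposure": _frequency(artifact.frequency_exposure),
        "frequencyOfHarm": _frequency(artifact.frequency_harm),
    }
    if isinstance(artifact.decision_tree, DecisionTree):
        doc["decisionTree"] = _node(artifact.decision_tree.root)
    if inline_valuesets:
        if registry is None:
            raise ValueError("inline_valuesets=True requires a registry")
        doc["valueSets"] = [
            {
                "id": vs.id,
                "name": vs.name,
                "purpose": vs.purpose,
                "members": [_concept(m) for m in vs.members],
            }
            for vs in (registry.get(r) for r in _collect_vs_refs(artifact))
        ]
    for key, value in artifact.extensions:
        doc[key] = value
    return json.dumps(doc, indent=2, ensure_ascii=False) + "\n"


# -- decoding ---------------------------------------------------------------


def _req(obj: dict, key: str) -> object:
    if key not in obj:
        raise DocumentParseError(f"document is missing required key {key!r}")
    return obj[key]


def _parse_concept(d: dict) -> CodedConcept:
    return CodedConcept(d["system"], d["code"], d.get("display", ""))


def _parse_concept_or_ref(d: dict) -> Union[CodedConcept, ValueSetRef]:
    if "valueSet" in d:
        return ValueSetRef(d["valueSet"])
    return _parse_concept(d)


def _parse_frequency_obj(d: Optional[dict], key: str) -> Optional[Frequency]:
    if d is None:
        return None
    if not isinstance(d, dict) or "kind" not in d:
        raise DocumentParseError(f"malformed frequency object under {key!r}: {d!r}")
    try:
        return Frequency(
            kind=FrequencyKind(d["kind"]),
            value=d.get("value"),
            low=d.get("low"),
            high=d.get("high"),
            description=d.get("description", ""),
            evidence_refs=tuple(d.get("evidenceRefs", ())),
            parsed=d.get("parsed", True),
        )
    except (ValueError, KeyError) as exc:
        raise DocumentParseError(
            f"malformed frequency object under {key!r}: {exc}"
        ) from None


def _parse_question(d: dict) -> Question:
    return Question(
        id=d["id"],
        kind=QuestionKind(d["kind"]),
        text=d.get("text", ""),
        value_set=ValueSetRef(d["valueSet"]) if "valueSet" in d else None,
        route=d.get("route"),
        observation=_parse_concept(d["observation"]) if "observation" in d else None,
        comparator=Comparator(d["comparator"]) if "comparator" in d else None,
        threshold=d.get("threshold"),
        unit=d.get("unit"),
    )


def _parse_node(d: dict) -> Node:
    if "outcome" in d:
        o = d["outcome"]
        return Leaf(
            Outcome(
                action_category=ActionCategory(o["actionCategory"]),
                classification=OrcaCategory(o["classification"]),
                action_text=o.get("actionText", ""),
                evidence_refs=tuple(o.get("evidenceRefs", ())),
            )
        )
    if "question" not in d:
        raise DocumentParseError(f"malformed tree node: {sorted(d)}")
    return InternalNode(
        question=_parse_question(d["question"]),
        yes=_parse_node(d["yes"]),
        no=_parse_node(d["no"]),
    )


def from_document(
    doc: Union[str, bytes], registry: Optional[ValueSetRegistry] = None
) -> PDDIArtifact:
    """Parse an interchange document back into a :class:`PDDIArtifact`.

    Inline value sets (under ``valueSets``) are registered into
    ``registry`` when one is given (existing ids are overwritten — the
    document is authoritative for its own sets).  Unknown top-level keys
    land in the artifact's extensions bag and are re-emitted by
    :func:`to_document`.

    Raises
    ------
    DocumentParseError
        On missing required keys or malformed sub-objects.
    """
    try:
        data = json.loads(doc)
    except json.JSONDecodeError as exc:
        raise DocumentParseError(f"invalid JSON: {exc}") from None
    if not isinstance(data, dict):
        raise DocumentParseError("document root must be a JSON object")

    for key in FIXED_KEYS:
        _req(data, key)

    try:
        drugs = tuple(
            DrugInvolved(
                role=DrugRole(d.get("role", "unspecified")),
                concept=_parse_concept(d["concept"]) if "concept" in d else None,
                value_set=ValueSetRef(d["valueSet"]) if "valueSet" in d else None,
                text=d.get("text", ""),
                level=DrugLevel(d.get("level", "ingredient")),
            )
            for d in data["drugsInvolved"]
        )
        consequences = tuple(
            ClinicalConsequence(
                description=c.get("description", ""),
                concepts=tuple(_parse_concept_or_ref(x) for x in c.get("concepts", ())),
                seriousness=(
                    SeriousnessAssessment(
                        reasons=tuple(
                            SeriousnessReason(r)
                            for r in c["seriousness"].get("reasons", ())
                        ),
                        rationale=c["seriousness"].get("rationale", ""),
                    )
                    if c.get("seriousness") is not None
                    else None
                ),
            )
            for c in data["clinicalConsequences"]
        )
        classifications = tuple(
            OperationalClassification(
                category=(
                    OrcaCategory(c["category"])
                    if c["category"] in OrcaCategory._value2member_map_
                    else c["category"]
                ),
                statement=c.get("statement", ""),
                sub_strategy=(
                    MinimizeRiskStrategy(c["subStrategy"])
                    if "subStrategy" in c
                    else None
                ),
                condition=c.get("condition", ""),
                evidence_refs=tuple(c.get("evidenceRefs", ())),
            )
            for c in data["operationalClassifications"]
        )
        actions = tuple(
            RecommendedAction(
                action_text=a["actionText"],
                action_category=(
                    ActionCategory(a["actionCategory"])
                    if a.get("actionCategory") in ActionCategory._value2member_map_
                    else a.get("actionCategory", "")
                ),
                evidence_refs=tuple(a.get("evidenceRefs", ())),
            )
            for a in data["recommendedActions"]
        )
        mech_obj = data["mechanism"]
        mechanism = (
            Mechanism(
                known=bool(mech_obj["known"]),
                description=mech_obj.get("description", ""),
                concepts=tuple(
                    _parse_concept(c) for c in mech_obj.get("concepts", ())
                ),
            )
            if mech_obj is not None
            else None
        )
        factors = tuple(
            ContextualFactor(
                kind=ContextualFactorKind(f.get("kind", "other")),
                description=f.get("description", ""),
                concepts=tuple(_parse_concept_or_ref(x) for x in f.get("concepts", ())),
                effect_note=f.get("effectNote", ""),
                free_text_last_resort=bool(f.get("freeTextLastResort", False)),
            )
            for f in data["contextualFactors"]
        )
        evidence = tuple(
            EvidenceItem(
                id=e["id"],
                stance=EvidenceStance(e.get("stance", "supports")),
                type=EvidenceType(e.get("type", "other")),
                citation=e.get("citation", ""),
                summary=e.get("summary", ""),
            )
            for e in data["evidence"]
        )
    except DocumentParseError:
        raise
    except (KeyError, TypeError, ValueError) as exc:
        raise DocumentParseError(f"malformed artifact document: {exc!r}") from None

    tree = None
    if data.get("decisionTree") is not None:
        tree = DecisionTree(root=_parse_node(data["decisionTree"]))

    if registry is not None and data.get("valueSets"):
        for vs in data["valueSets"]:
            registry.register(
                ValueSet(
                    id=vs["id"],
                    name=vs.get("name", ""),
                    purpose=vs.get("purpose", ""),
                    members=tuple(_parse_concept(m) for m in vs.get("members", ())),
                ),
                overwrite=True,
            )

    known_keys = set(FIXED_KEYS) | set(_OPTIONAL_KEYS)
    extensions = tuple((k, v) for k, v in data.items() if k not in known_keys)

    return PDDIArtifact(
        id=data["id"],
        title=data["title"],
        version=data["version"],
        drugs=drugs,
        consequences=consequences,
        classifications=classifications,
        actions=actions,
        mechanism=mechanism,
        contextual_factors=factors,
        evidence=evidence,
        frequency_exposure=_parse_frequency_obj(
            data["frequencyOfExposure"], "frequencyOfExposure"
        ),
        frequency_harm=_parse_frequency_obj(data["frequencyOfHarm"], "frequencyOfHarm"),
        decision_tree=tree,
        extensions=extensions,
    )


# ---------------------------------------------------------------------------
# Narrative
# ---------------------------------------------------------------------------

_REASON_TEXT = {
    SeriousnessReason.DEATH: "death",
    SeriousnessReason.LIFE_THREATENING_HOSPITALIZATION: "life-threatening hospitalization",
    SeriousnessReason.CONGENITAL_ANOMALY: "congenital anomaly",
    SeriousnessReason.DISABILITY: "disability",
    SeriousnessReason.PERMANENT_IMPAIRMENT: "permanent impairment",
}


def _drug_label(d: DrugInvolved) -> str:
    if d.concept is not None:
        return d.concept.display or d.concept.code
    if d.value_set is not None:
        return f"value set `{d.value_set.id}`"
    return d.text


def render_narrative(artifact: PDDIArtifact) -> str:
    """Render a clinician-facing Markdown narrative of the artifact.

    Sections appear in model order and cover each of the ten information
    items exactly once; evidence references become numbered citations;
    unknown frequencies print the word "Unknown" verbatim.

    Raises
    ------
    RenderError
        If an evidence reference does not resolve to an evidence item.
    """
    ev_index = {e.id: i + 1 for i, e in enumerate(artifact.evidence)}

    def cite(refs: tuple[str, ...]) -> str:
        nums = []
        for r in refs:
            if r not in ev_index:
                raise RenderError(f"dangling evidence ref {r!r}")
            nums.append(str(ev_index[r]))
        return f" [{', '.join(nums)}]" if nums else ""

    lines: list[str] = []
    title = artifact.title or artifact.id
    lines.append(f"# {title}")
    lines.append("")
    lines.append("## Drugs involved")
    for d in artifact.drugs:
        lines.append(f"- {_drug_label(d)} ({d.role.value}, {d.level.value})")
    lines.append("")
    lines.append("## Clinical consequences and seriousness")
    if artifact.consequences:
        for c in artifact.consequences:
            lines.append(f"- {c.description}")
            s = c.seriousness
            if s is None:
                lines.append("  - Seriousness: not assessed")
            elif s.serious:
                reasons = ", ".join(_REASON_TEXT[r] for r in s.reasons)
                detail = s.rationale or f"may result in {reasons}"
                lines.append(f"  - Serious: yes ({detail})")
            else:
                detail = f" ({s.rationale})" if s.rationale else ""
                lines.append(f"  - Serious: no{detail}")
    else:
        lines.append("None stated")
    lines.append("")
    lines.append("## Operational classification")
    if artifact.classifications:
        for c in artifact.classifications:
            cat = c.category.value if isinstance(c.category, OrcaCategory) else c.category
            strat = f" / {c.sub_strategy.value}" if c.sub_strategy else ""
            cond = f" (when: {c.condition})" if c.condition else ""
            stmt = f" — {c.statement}" if c.statement else ""
            lines.append(f"- **{cat}**{strat}{cond}{stmt}{cite(c.evidence_refs)}")
    else:
        lines.append("None stated")
    lines.append("")
    lines.append("## Recommended actions")
    if artifact.actions:
        for a in artifact.actions:
            lines.append(f"- {a.action_text}{cite(a.evidence_refs)}")
    else:
        lines.append("None stated")
    lines.append("")
    lines.append("## Mechanism of interaction")
    lines.append(artifact.mechanism.description if artifact.mechanism else "None stated")
    lines.append("")
    lines.append("## Contextual information / modifying factors")
    if artifact.contextual_factors:
        for f in artifact.contextual_factors:
            note = f" — {f.effect_note}" if f.effect_note else ""
            lines.append(f"- {f.description} ({f.kind.value}){note}")
    else:
        lines.append("None stated")
    lines.append("")
    lines.append("## Frequency of exposure")
    lines.append(
        format_frequency(artifact.frequency_exposure)
        if artifact.frequency_exposure
        else "Not stated"
    )
    lines.append("")
    lines.append("## Frequency of harm")
    lines.append(
        format_frequency(artifact.frequency_harm)
        if artifact.frequency_harm
        else "Not stated"
    )
    lines.append("")
    lines.append("## Evidence")
    if artifact.evidence:
        for e in artifact.evidence:
            stance = "supports" if e.stance is EvidenceStance.SUPPORTS else "refutes"
            lines.append(
                f"{ev_index[e.id]}. {e.citation or e.id} ({e.type.value}, {stance})"
                + (f" — {e.summary}" if e.summary else "")
            )
    else:
        lines.append("None stated")
    lines.append("")
    return "\n".join(lines)
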