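"""Conformance checking of PDDI artifacts against the minimal information
model.

Two rule families:

* **Required-element rules** (``E-REQ-*``, severity *error*): the seven
  slots the model marks required must be populated — drugs, clinical
  consequences, a seriousness assessment on every consequence, at least one
  operational classification statement, a mechanism statement, contextual
  factors, and evidence.  Recommended action and the two frequency slots
  are recommended, never errors.

* **Best-practice rules** (``BP-1`` … ``BP-8``, severity *warning*): how
  artifact creators can best use the ten items — coded drugs, coded
  consequences, justified seriousness, a declared classification category,
  evidence-linked actions, an explicit mechanism (or an explicit statement
  that it is not elucidated), coded contextual factors, and frequencies
  stated as "unknown" rather than omitted.  These eight rules are this
  package's operationalization of the model's best-practice
  recommendations; the normative prose lives in the published community
  report, so the exact reading here is documented in docs/methods.md.

Validation is pure and issues are data: checks never raise on bad content,
they report it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .model import (
    NOT_ELUCIDATED,
    CodedConcept,
    Frequency,
    PDDIArtifact,
    ValueSetRef,
    information_items,
)
from .value_sets import ValueSetRegistry

__all__ = [
    "Severity",
    "ValidationIssue",
    "ValidationReport",
    "RuleDescriptor",
    "check_required",
    "check_best_practices",
    "validate",
    "list_rules",
]

Severity = str  # "error" | "warning" | "info"


@dataclass(frozen=True)
class ValidationIssue:
    rule_id: str
    severity: Severity
    path: str
    message: str


@dataclass(frozen=True)
class ValidationReport:
    """Ordered validation issues for one artifact.

    ``valid`` is true iff no issue has severity ``error``; warnings never
    affect it.
    """

    artifact_id: str
    issues: tuple[ValidationIssue, ...]

    @property
    def valid(self) -> bool:
        return not any(i.severity == "error" for i in self.issues)

    @property
    def errors(self) -> tuple[ValidationIssue, ...]:
        return tuple(i for i in self.issues if i.severity == "error")

    @property
    def warnings(self) -> tuple[ValidationIssue, ...]:
        return tuple(i for i in self.issues if i.severity == "warning")

    def to_dict(self) -> dict:
        return {
            "artifactId": self.artifact_id,
            "valid": self.valid,
            "issues": [
                {
                    "rule": i.rule_id,
                    "severity": i.severity,
                    "path": i.path,
                    "message": i.message,
                }
                for i in self.issues
            ],
        }


@dataclass(frozen=True)
class RuleDescriptor:
    id: str
    severity: Severity
    title: str
    citation: str


_REQUIRED_RULES: tuple[RuleDescriptor, ...] = (
    RuleDescriptor(
        "E-REQ-DRUGS", "error", "At least two drugs involved",
        "An interaction needs at least two participating drug products, "
        "classes, or active ingredients.",
    ),
    RuleDescriptor(
        "E-REQ-CONSEQUENCE", "error", "Clinical consequences stated",
        "Artifacts must indicate the known or anticipated clinical "
        "consequences of exposure; pharmacokinetic facts alone do not let a "
        "clinician assess patient risk.",
    ),
    RuleDescriptor(
        "E-REQ-SERIOUSNESS", "error", "Seriousness assessed per consequence",
        "Each consequence must state whether it is serious (may result in "
        "death, life-threatening hospitalization, congenital anomaly, "
        "disability, or permanent impairment).",
    ),
    RuleDescriptor(
        "E-REQ-OCS", "error", "Operational classification present",
        "Artifacts must report at least one operational classification "
        "statement — a management directive for a patient context.",
    ),
    RuleDescriptor(
        "E-REQ-MECHANISM", "error", "Mechanism statement present",
        "Artifacts must include a mechanism statement; when the mechanism is "
        "not known, that must be said explicitly.",
    ),
    RuleDescriptor(
        "E-REQ-CONTEXT", "error", "Contextual factors present",
        "Modifying factors (route, co-medication, history, demographics) are "
        "required for alerts that are both sensitive and specific.",
    ),
    RuleDescriptor(
        "E-REQ-EVIDENCE", "error", "Evidence present",
        "Artifacts must include evidence supporting or refuting the "
        "interaction in humans.",
    ),
)

_BP_RULES: tuple[RuleDescriptor, ...] = (
    RuleDescriptor(
        "BP-1", "warning", "Drugs coded, not bare text",
        "Reference drugs via coded concepts or value sets from widely "
        "adopted vocabularies (RxNorm, ATC); free text is a last resort.",
    ),
    RuleDescriptor(
        "BP-2", "warning", "Consequences coded",
        "Each clinical consequence should carry at least one coded concept "
        "or value-set reference (ICD-10, SNOMED-CT).",
    ),
    RuleDescriptor(
        "BP-3", "warning", "Seriousness justified",
        "Each seriousness assessment should cite at least one enumerated "
        "reason or give rationale text.",
    ),
    RuleDescriptor(
        "BP-4", "warning", "Declared classification category used",
        "At least one operational classification statement should use a "
        "category from a declared classification system (ORCA).",
    ),
    RuleDescriptor(
        "BP-5", "warning", "Actions linked to evidence",
        "Recommended actions should be linked, where possible, to "
        "justifying evidence.",
    ),
    RuleDescriptor(
        "BP-6", "warning", "Mechanism explicit or marked not-elucidated",
        "State the mechanism for clinicians, or mark it explicitly as not "
        "well elucidated; never leave it blank.",
    ),
    RuleDescriptor(
        "BP-7", "warning", "Contextual factors coded",
        "Each contextual factor should carry a coded concept or value-set "
        "reference, or be explicitly flagged free-text-last-resort.",
    ),
    RuleDescriptor(
        "BP-8", "warning", "Frequencies populated ('unknown' allowed)",
        "Both frequency slots should be populated; state 'unknown' to convey "
        "the limits of available information rather than omitting the slot.",
    ),
)


def list_rules() -> tuple[RuleDescriptor, ...]:
    """All registered rules: 7 required-element rules then 8 best-practice
    rules, in report order."""
    return _REQUIRED_RULES + _BP_RULES


#: Slot ordering used to stable-sort issues (model order of the ten items).
_SLOT_ORDER = {item.key: i for i, item in enumerate(information_items())}


def _slot_of(path: str) -> str:
    return path.split("[", 1)[0].split(".", 1)[0]


def check_required(artifact: PDDIArtifact) -> list[ValidationIssue]:
    """Evaluate the seven required-element rules.

    One issue per missing or empty required slot; recommended action and
    the two frequencies never produce errors here.
    """
    issues: list[ValidationIssue] = []

    def err(rule_id: str, path: str, message: str) -> None:
        issues.append(ValidationIssue(rule_id, "error", path, message))

    if len(artifact.drugs) < 2:
        err("E-REQ-DRUGS", "drugs",
            f"at least two drugs involved are required, found {len(artifact.drugs)}")
    if not artifact.consequences:
        err("E-REQ-CONSEQUENCE", "consequences",
            "no clinical consequences stated")
    for i, c in enumerate(artifact.consequences):
        if c.seriousness is None:
            err("E-REQ-SERIOUSNESS", f"consequences[{i}].seriousness",
                f"consequence {c.description!r} has no seriousness assessment")
    if not artifact.classifications:
        err("E-REQ-OCS", "classifications",
            "no operational classification statement")
    if artifact.mechanism is None:
        err("E-REQ-MECHANISM", "mechanism", "no mechanism statement")
    if not artifact.contextual_factors:
        err("E-REQ-CONTEXT", "contextual_factors",
            "no contextual information / modifying factors")
    if not artifact.evidence:
        err("E-REQ-EVIDENCE", "evidence", "no evidence items")
    return issues


def check_best_practices(
    artifact: PDDIArtifact, registry: Optional[ValueSetRegistry] = None
) -> list[ValidationIssue]:
    """Evaluate the eight best-practice rules; violations are warnings.

    ``registry`` is accepted so value-set references can be sanity-checked
    for resolvability (an unresolvable reference degrades BP-1/BP-2/BP-7 to
    a violation at that slot); pass None to skip resolution.
    """
    issues: list[ValidationIssue] = []

    def warn(rule_id: str, path: str, message: str) -> None:
        issues.append(ValidationIssue(rule_id, "warning", path, message))

    def coded(x: object) -> bool:
        if isinstance(x, ValueSetRef):
            return registry is None or x.id in registry
        return isinstance(x, CodedConcept)

    # BP-1: drugs via coded concepts / value sets, not bare text.
    for i, d in enumerate(artifact.drugs):
        ok = (d.concept is not None and coded(d.concept)) or (
            d.value_set is not None and coded(d.value_set)
        )
        if not ok:
            warn("BP-1", f"drugs[{i}]",
                 f"drug slot {i} is free text ({d.text!r}); prefer a coded "
                 "concept or value set")

    # BP-2: each consequence coded.
    for i, c in enumerate(artifact.consequences):
        if not any(coded(x) for x in c.concepts):
            warn("BP-2", f"consequences[{i}]",
                 f"consequence {c.description!r} has no coded concept or "
                 "value-set reference")

    # BP-3: seriousness cites a reason or rationale.
    for i, c in enumerate(artifact.consequences):
        s = c.seriousness
        if s is not None and not s.reasons and not s.rationale.strip():
            warn("BP-3", f"consequences[{i}].seriousness",
                 "seriousness assessment cites no enumerated reason and no "
                 "rationale text")

    # BP-4: at least one statement uses a declared category.
    if artifact.classifications and not any(
        c.orca_category is not None for c in artifact.classifications
    ):
        warn("BP-4", "classifications",
             "no operational classification statement uses a declared "
             "classification-system category")

    # BP-5: actions linked to evidence.
    for i, a in enumerate(artifact.actions):
        if not a.evidence_refs:
            warn("BP-5", f"actions[{i}]",
                 f"recommended action {a.action_text[:40]!r}... has no "
                 "evidence reference")

    # BP-6: mechanism explicit or marked not elucidated.
    m = artifact.mechanism
    if m is None:
        warn("BP-6", "mechanism",
             "mechanism absent; state it or mark it explicitly as "
             f"{NOT_ELUCIDATED!r}")
    elif m.known and not m.description.strip():
        warn("BP-6", "mechanism",
             "mechanism marked known but no description given")
    elif not m.known and not m.marked_not_elucidated:
        warn("BP-6", "mechanism",
             f"unknown mechanism should carry the marker text {NOT_ELUCIDATED!r}")

    # BP-7: contextual factors coded or flagged free text.
    for i, f in enumerate(artifact.contextual_factors):
        if not any(coded(x) for x in f.concepts) and not f.free_text_last_resort:
            warn("BP-7", f"contextual_factors[{i}]",
                 f"contextual factor {f.description[:40]!r} has no coded "
                 "concept and is not flagged free-text-last-resort")

    # BP-8: frequencies populated, 'unknown' rather than absent.
    for slot, freq in (
        ("frequency_exposure", artifact.frequency_exposure),
        ("frequency_harm", artifact.frequency_harm),
    ):
        if freq is None:
            warn("BP-8", slot,
                 f"{slot} absent; populate it, using kind='unknown' when no "
                 "data exist")
    return issues


def validate(
    artifact: PDDIArtifact, registry: Optional[ValueSetRegistry] = None
) -> ValidationReport:
    """Full conformance report: required-element errors plus best-practice
    warnings, stable-ordered by information-item slot then rule id."""
    issues = check_required(artifact) + check_best_practices(artifact, registry)
    issues.sort(key=lambda i: (_SLOT_ORDER.get(_slot_of(i.path), 99), i.rule_id, i.path))
    return ValidationReport(artifact_id=artifact.id, issues=tuple(issues))
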