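"""Binary decision trees evaluated against a patient context.

Each PDDI decision tree is a series of binary (yes/no) questions about the
patient's medications, conditions and observations, designed to constrain
the interpretation of the interaction and lead to one of three recommended
actions: *no special precautions*, *assess risk and take action if
necessary*, or *use only if benefits outweigh the risk*.

Unknown answers
---------------
Membership questions (is a medication / condition in this value set?) never
answer *unknown*: medication and problem lists are taken as complete, so
absence means *no*.  Only observation questions (e.g. "is the INR above
3?") can be unknown, when the observation was never recorded.  Three
policies govern what evaluation does then:

* ``strict`` — raise :class:`~pddikit.errors.MissingDataError` naming the
  question;
* ``conservative`` — explore both branches and return the outcome whose
  operational classification is most restrictive (ties broken toward the
  yes-branch), recording the unknown in the trace;
* ``abstain`` — return the set of all outcomes still reachable given the
  unknowns, leaving the risk judgement to the clinician.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterator, Optional, Union

from .errors import (
    ComplexityGuardError,
    MissingDataError,
    UnitError,
)
from .model import (
    ActionCategory,
    CodedConcept,
    OrcaCategory,
    PDDIArtifact,
    ValueSetRef,
    restrictiveness_rank,
)
from .value_sets import ValueSetRegistry

__all__ = [
    "MedicationRecord",
    "ObservationRecord",
    "PatientContext",
    "QuestionKind",
    "Comparator",
    "Question",
    "Outcome",
    "Leaf",
    "InternalNode",
    "DecisionTree",
    "Answer",
    "TraceStep",
    "Trace",
    "Policy",
    "answer_question",
    "evaluate",
    "applies",
    "reachable_outcomes",
    "UNKNOWN_CAP",
]


# ---------------------------------------------------------------------------
# Patient context
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MedicationRecord:
    """One active medication; ``route`` is an optional token such as
    ``oral`` or ``topical``."""

    concept: CodedConcept
    route: Optional[str] = None


@dataclass(frozen=True)
class ObservationRecord:
    """One recorded observation (e.g. an INR value)."""

    concept: CodedConcept
    value: float
    unit: str


@dataclass(frozen=True)
class PatientContext:
    """The slice of a patient record a tree is evaluated against."""

    medications: tuple[MedicationRecord, ...] = ()
    conditions: tuple[CodedConcept, ...] = ()
    observations: tuple[ObservationRecord, ...] = ()

    def __post_init__(self) -> None:
        seen: set[tuple[str, str, Optional[str]]] = set()
        for m in self.medications:
            key = (m.concept.system, m.concept.code, m.route)
            if key in seen:
                raise ValueError(f"duplicate medication record {key}")
            seen.add(key)

    @classmethod
    def from_dict(cls, data: dict) -> "PatientContext":
        """Build a context from the JSON interchange shape
        (``medications`` / ``conditions`` / ``observations`` arrays)."""
        meds = tuple(
            MedicationRecord(
                concept=CodedConcept(m["system"], m["code"], m.get("display", "")),
                route=m.get("route"),
            )
            for m in data.get("medications", ())
        )
        conds = tuple(
            CodedConcept(c["system"], c["code"], c.get("display", ""))
            for c in data.get("conditions", ())
        )
        obs = tuple(
            ObservationRecord(
                concept=CodedConcept(o["system"], o["code"], o.get("display", "")),
                value=float(o["value"]),
                unit=o["unit"],
            )
            for o in data.get("observations", ())
        )
        return cls(medications=meds, conditions=conds, observations=obs)

    def to_dict(self) -> dict:
        return {
            "medications": [
                {
                    "system": m.concept.system,
                    "code": m.concept.code,
                    "display": m.concept.display,
                    **({"route": m.route} if m.route else {}),
                }
                for m in self.medications
            ],
            "conditions": [
                {"system": c.system, "code": c.code, "display": c.display}
                for c in self.conditions
            ],
            "observations": [
                {
                    "system": o.concept.system,
                    "code": o.concept.code,
                    "display": o.concept.display,
                    "value": o.value,
                    "unit": o.unit,
                }
                for o in self.observations
            ],
        }


# ---------------------------------------------------------------------------
# Questions
# ---------------------------------------------------------------------------


class QuestionKind(str, enum.Enum):
    MED_IN_VALUESET = "MED_IN_VALUESET"
    CONDITION_IN_VALUESET = "CONDITION_IN_VALUESET"
    OBSERVATION_COMPARE = "OBSERVATION_COMPARE"
    MED_ROUTE_IS = "MED_ROUTE_IS"


class Comparator(str, enum.Enum):
    LT = "<"
    LE = "<="
    GT = ">"
    GE = ">="

    def apply(self, left: float, right: float) -> bool:
        if self is Comparator.LT:
            return left < right
        if self is Comparator.LE:
            return left <= right
        if self is Comparator.GT:
            return left > right
        return left >= right


@dataclass(frozen=True)
class Question:
    """One binary question of a decision tree.

    Parameterization depends on ``kind``:

    * ``MED_IN_VALUESET`` / ``CONDITION_IN_VALUESET`` — ``value_set``;
    * ``MED_ROUTE_IS`` — ``value_set`` plus ``route``;
    * ``OBSERVATION_COMPARE`` — ``observation`` concept, ``comparator``,
      ``threshold`` and ``unit``.
    """

    id: str
    kind: QuestionKind
    text: str = ""
    value_set: Optional[ValueSetRef] = None
    route: Optional[str] = None
    observation: Optional[CodedConcept] = None
    comparator: Optional[Comparator] = None
    threshold: Optional[float] = None
    unit: Optional[str] = None

    def __post_init__(self) -> None:
        kind = QuestionKind(self.kind)
        object.__setattr__(self, "kind", kind)
        if kind in (QuestionKind.MED_IN_VALUESET, QuestionKind.CONDITION_IN_VALUESET):
            if self.value_set is None:
                raise ValueError(f"{kind.value} question requires value_set")
        elif kind is QuestionKind.MED_ROUTE_IS:
            if self.value_set is None or not self.route:
                raise ValueError("MED_ROUTE_IS question requires value_set and route")
        else:  # OBSERVATION_COMPARE
            if (
                self.observation is None
                or self.comparator is None
                or self.threshold is None
                or not self.unit
            ):
                raise ValueError(
                    "OBSERVATION_COMPARE question requires observation, "
                    "comparator, threshold and unit"
                )
            object.__setattr__(self, "comparator", Comparator(self.comparator))


Answer = str  # "yes" | "no" | "unknown"


def answer_question(
    q: Question, ctx: PatientContext, registry: ValueSetRegistry
) -> Answer:
    """Answer one binary question from the patient context.

    Membership questions treat absence as *no* and never return unknown;
    only ``OBSERVATION_COMPARE`` returns ``"unknown"``, when no observation
    of that concept exists.  Observation units must match the question's
    unit exactly.

    Raises
    ------
    MissingValueSetError
        If the question's value-set reference does not resolve.
    UnitError
        If a matching observation is recorded in a different unit.
    """
    if q.kind is QuestionKind.MED_IN_VALUESET:
        vs = registry.get(q.value_set)
        return "yes" if any(m.concept in vs for m in ctx.medications) else "no"

    if q.kind is QuestionKind.CONDITION_IN_VALUESET:
        vs = registry.get(q.value_set)
        return "yes" if any(c in vs for c in ctx.conditions) else "no"

    if q.kind is QuestionKind.MED_ROUTE_IS:
        vs = registry.get(q.value_set)
        return (
            "yes"
            if any(m.concept in vs and m.route == q.route for m in ctx.medications)
            else "no"
        )

    # OBSERVATION_COMPARE
    matches = [o for o in ctx.observations if o.concept == q.observation]
    if not matches:
        return "unknown"
    obs = matches[-1]  # most recently listed wins
    if obs.unit != q.unit:
        raise UnitError(
            f"observation {obs.concept.code!r} recorded in {obs.unit!r} but "
            f"question {q.id!r} expects {q.unit!r}"
        )
    return "yes" if q.comparator.apply(obs.value, q.threshold) else "no"


def _basis(q: Question, ctx: PatientContext, registry: ValueSetRegistry,
           answer: Answer) -> str:
    """Human-readable justification recorded in the trace."""
    if answer == "unknown":
        return f"no observation of {q.observation.code!r} recorded"
    if q.kind is QuestionKind.MED_IN_VALUESET and answer == "yes":
        vs = registry.get(q.value_set)
        hit = next(m.concept for m in ctx.medications if m.concept in vs)
        return f"medication {hit.code!r} in value set {q.value_set.id!r}"
    if q.kind is QuestionKind.CONDITION_IN_VALUESET and answer == "yes":
        vs = registry.get(q.value_set)
        hit = next(c for c in ctx.conditions if c in vs)
        return f"condition {hit.code!r} in value set {q.value_set.id!r}"
    if q.kind is QuestionKind.MED_ROUTE_IS and answer == "yes":
        vs = registry.get(q.value_set)
        hit = next(
            m for m in ctx.medications if m.concept in vs and m.route == q.route
        )
        return f"medication {hit.concept.code!r} with route {q.route!r}"
    if q.kind is QuestionKind.OBSERVATION_COMPARE:
        obs = [o for o in ctx.observations if o.concept == q.observation][-1]
        return (
            f"observation {obs.concept.code!r} = {obs.value:g} {obs.unit} "
            f"{q.comparator.value} {q.threshold:g} is {answer}"
        )
    return "no match in context"


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Outcome:
    """A leaf of a decision tree: one of the three recommended actions plus
    its operational classification and free-text guidance."""

    action_category: ActionCategory
    classification: OrcaCategory
    action_text: str = ""
    evidence_refs: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "action_category", ActionCategory(self.action_category))
        object.__setattr__(self, "classification", OrcaCategory(self.classification))


@dataclass(frozen=True)
class Leaf:
    outcome: Outcome


@dataclass(frozen=True)
class InternalNode:
    question: Question
    yes: "Node"
    no: "Node"


Node = Union[Leaf, InternalNode]


@dataclass(frozen=True)
class DecisionTree:
    """A binary question tree; every internal node has exactly two children
    and every path ends in a leaf (guaranteed structurally)."""

    root: Node

    def leaves(self) -> list[Leaf]:
        out: list[Leaf] = []

        def walk(node: Node) -> None:
            if isinstance(node, Leaf):
                out.append(node)
            else:
                walk(node.yes)
                walk(node.no)

        walk(self.root)
        return out

    def questions(self) -> list[Question]:
        out: list[Question] = []

        def walk(node: Node) -> None:
            if isinstance(node, InternalNode):
                out.append(node.question)
                walk(node.yes)
                walk(node.no)

        walk(self.root)
        return out


@dataclass(frozen=True)
class TraceStep:
    question_id: str
    answer: Answer
    basis: str


@dataclass(frozen=True)
class Trace:
    steps: tuple[TraceStep, ...] = ()

    def render(self) -> str:
        lines = []
        for depth, s in enumerate(self.steps):
            lines.append(f"{'  ' * depth}{s.question_id}: {s.answer} ({s.basis})")
        return "\n".join(lines)


Policy = str  # "strict" | "conservative" | "abstain"

#: Cap on distinct unknown questions during exhaustive completion.
UNKNOWN_CAP = 20


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------


def evaluate(
    tree: DecisionTree,
    ctx: PatientContext,
    registry: ValueSetRegistry,
    policy: Policy = "strict",
) -> tuple[Union[Outcome, frozenset[Outcome]], Trace]:
    """Walk the tree root→leaf following the context's answers.

    Returns ``(outcome, trace)`` for the strict and conservative policies,
    and ``(frozenset of reachable outcomes, trace)`` for abstain.  See the
    module docstring for the unknown-answer semantics.

    Raises
    ------
    MissingDataError
        Under the strict policy, when a question cannot be answered.
    """
    if policy not in ("strict", "conservative", "abstain"):
        raise ValueError(f"unknown policy {policy!r}")

    steps: list[TraceStep] = []

    if policy == "abstain":
        outcomes = reachable_outcomes(tree, ctx, registry, _trace=steps)
        return frozenset(outcomes), Trace(tuple(steps))

    def walk(node: Node) -> Outcome:
        if isinstance(node, Leaf):
            return node.outcome
        ans = answer_question(node.question, ctx, registry)
        if ans == "unknown":
            if policy == "strict":
                raise MissingDataError(
                    f"cannot answer question {node.question.id!r} "
                    f"({node.question.text or node.question.kind.value}) from "
                    "the patient context"
                )
            steps.append(
                TraceStep(node.question.id, "unknown",
                          _basis(node.question, ctx, registry, "unknown"))
            )
            yes_out = walk(node.yes)
            no_out = walk(node.no)
            # Most restrictive wins; tie broken toward the yes branch.
            if restrictiveness_rank(no_out.classification) > restrictiveness_rank(
                yes_out.classification
            ):
                return no_out
            return yes_out
        steps.append(
            TraceStep(node.question.id, ans, _basis(node.question, ctx, registry, ans))
        )
        return walk(node.yes if ans == "yes" else node.no)

    outcome = walk(tree.root)
    return outcome, Trace(tuple(steps))


def reachable_outcomes(
    tree: DecisionTree,
    ctx: PatientContext,
    registry: ValueSetRegistry,
    _trace: Optional[list[TraceStep]] = None,
) -> frozenset[Outcome]:
    """All distinct leaf outcomes reachable under some completion of the
    unknown answers.

    With zero unknowns this is the singleton of the strict evaluation
    result.  Serves as the brute-force oracle for the conservative policy:
    the conservative outcome's classification equals the merge (most
    restrictive) of the classifications found here.

    Raises
    ------
    ComplexityGuardError
        If more than :data:`UNKNOWN_CAP` distinct questions are unknown.
    """
    unknown_seen: set[str] = set()
    out: set[Outcome] = set()

    def walk(node: Node) -> None:
        if isinstance(node, Leaf):
            out.add(node.outcome)
            return
        ans = answer_question(node.question, ctx, registry)
        if ans == "unknown":
            unknown_seen.add(node.question.id)
            if len(unknown_seen) > UNKNOWN_CAP:
                raise ComplexityGuardError(
                    f"more than {UNKNOWN_CAP} unknown questions; refusing "
                    "exhaustive completion"
                )
            if _trace is not None:
                _trace.append(
                    TraceStep(node.question.id, "unknown",
                              _basis(node.question, ctx, registry, "unknown"))
                )
            walk(node.yes)
            walk(node.no)
            return
        if _trace is not None:
            _trace.append(
                TraceStep(node.question.id, ans,
                          _basis(node.question, ctx, registry, ans))
            )
        walk(node.yes if ans == "yes" else node.no)

    walk(tree.root)
    return frozenset(out)


# ---------------------------------------------------------------------------
# Artifact-level screening
# ---------------------------------------------------------------------------


def _slot_matches(drug, med: MedicationRecord, registry: ValueSetRegistry) -> bool:
    if drug.concept is not None:
        return med.concept == drug.concept
    if drug.value_set is not None:
        return med.concept in registry.get(drug.value_set)
    return False  # free-text slots cannot be screened automatically


def applies(
    artifact: PDDIArtifact, ctx: PatientContext, registry: ValueSetRegistry
) -> bool:
    """Screening gate: does this artifact concern this patient at all?

    True iff the medication list matches at least two distinct drug slots
    of the artifact — i.e. the patient is co-exposed to both sides of the
    interaction.  Free-text drug slots never match.
    """
    matched = 0
    for drug in artifact.drugs:
        if any(_slot_matches(drug, m, registry) for m in ctx.medications):
            matched += 1
            if matched >= 2:
                return True
    return False
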