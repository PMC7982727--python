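"""Core domain types for PDDI knowledge artifacts.

A *potential drug-drug interaction* (PDDI) knowledge artifact is a curated,
structured description of one drug pair (or pair of drug classes) that may
cause harm when co-administered.  The minimal information model behind this
package fixes ten information items every artifact carries:

1.  drugs involved,
2.  clinical consequences,
3.  seriousness (nested inside each consequence),
4.  operational classification statement,
5.  recommended action,
6.  mechanism of interaction,
7.  contextual information / modifying factors,
8.  evidence about the suspected interaction,
9.  frequency of exposure to the combination, and
10. frequency of harm among the exposed.

Seven of those (1, 2, 3, 4, 6, 7, 8) are *required*; the remaining three are
recommended.  This module holds the in-memory types and the small pieces of
domain logic attached to them: the pharmacovigilance seriousness test, the
ORCA restrictiveness order, and frequency-statement parsing.  Conformance
checking lives in :mod:`pddikit.validator`; file formats live in
:mod:`pddikit.serialization`.

Deliberately absent: any notion of interaction *severity*.  The model uses
the pharmacovigilance notion of *seriousness* (an outcome is serious iff it
may cause death, life-threatening hospitalization, congenital anomaly,
disability, or permanent impairment) plus an operational classification,
which is more directly actionable at the point of care.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, Union

from .errors import (
    CardinalityError,
    DanglingReferenceError,
    FrequencyRangeError,
    VocabularyError,
)

__all__ = [
    "CodedConcept",
    "ValueSetRef",
    "DrugRole",
    "DrugLevel",
    "DrugInvolved",
    "SeriousnessReason",
    "SeriousnessAssessment",
    "ClinicalConsequence",
    "OrcaCategory",
    "MinimizeRiskStrategy",
    "OperationalClassification",
    "ActionCategory",
    "RecommendedAction",
    "Mechanism",
    "NOT_ELUCIDATED",
    "ContextualFactorKind",
    "ContextualFactor",
    "FrequencyKind",
    "Frequency",
    "EvidenceStance",
    "EvidenceType",
    "EvidenceItem",
    "PDDIArtifact",
    "InformationItem",
    "information_items",
    "new_artifact",
    "is_serious",
    "parse_frequency",
    "format_frequency",
    "restrictiveness_rank",
    "merge_classifications",
]


# ---------------------------------------------------------------------------
# Coded concepts and value-set references
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CodedConcept:
    """A concept identified by a (terminology system, code) pair.

    ``system`` names the source vocabulary (RxNorm, ATC, ICD-10, SNOMED-CT,
    or a local demo system); ``code`` is an opaque string within it.  The
    identity of a concept is the (system, code) pair — ``display`` is a
    human label and is ignored for equality and hashing.
    """

    system: str
    code: str
    display: str = ""

    def __post_init__(self) -> None:
        if not self.system or not self.code:
            raise ValueError("CodedConcept requires non-empty system and code")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CodedConcept):
            return NotImplemented
        return self.system == other.system and self.code == other.code

    def __hash__(self) -> int:
        return hash((self.system, self.code))

    @property
    def key(self) -> tuple[str, str]:
        return (self.system, self.code)


@dataclass(frozen=True)
class ValueSetRef:
    """A reference, by id, to a value set held in a registry."""

    id: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("ValueSetRef requires a non-empty id")


#: Either an inline concept or a reference into a value-set registry.
ConceptOrRef = Union[CodedConcept, ValueSetRef]


# ---------------------------------------------------------------------------
# Drugs involved
# ---------------------------------------------------------------------------


class DrugRole(str, enum.Enum):
    """Pharmacological role of a participant in the interaction.

    The *object* drug is the one whose effect is altered; the *precipitant*
    causes the alteration.  Many compendia do not assign roles, hence
    ``UNSPECIFIED``.
    """

    OBJECT = "object"
    PRECIPITANT = "precipitant"
    UNSPECIFIED = "unspecified"


class DrugLevel(str, enum.Enum):
    """Granularity of the drug slot: a clinical product, an active
    ingredient, or a whole drug class."""

    PRODUCT = "product"
    INGREDIENT = "ingredient"
    CLASS = "class"


@dataclass(frozen=True)
class DrugInvolved:
    """One participant slot of the interaction.

    Exactly one of ``concept`` (a single coded drug), ``value_set`` (a drug
    class given extensionally) or ``text`` (free text, last resort) is
    populated.  Free-text slots are legal but draw a best-practice warning
    from the validator.
    """

    role: DrugRole = DrugRole.UNSPECIFIED
    concept: Optional[CodedConcept] = None
    value_set: Optional[ValueSetRef] = None
    text: str = ""
    level: DrugLevel = DrugLevel.INGREDIENT

    def __post_init__(self) -> None:
        object.__setattr__(self, "role", DrugRole(self.role))
        object.__setattr__(self, "level", DrugLevel(self.level))
        populated = sum(
            1 for x in (self.concept, self.value_set, self.text or None) if x is not None
        )
        if populated != 1:
            raise ValueError(
                "DrugInvolved requires exactly one of concept, value_set or text"
            )


# ---------------------------------------------------------------------------
# Seriousness and clinical consequences
# ---------------------------------------------------------------------------


class SeriousnessReason(str, enum.Enum):
    """The pharmacovigilance criteria that make an outcome serious."""

    DEATH = "death"
    LIFE_THREATENING_HOSPITALIZATION = "life-threatening-hospitalization"
    CONGENITAL_ANOMALY = "congenital-anomaly"
    DISABILITY = "disability"
    PERMANENT_IMPAIRMENT = "permanent-impairment"


def is_serious(reasons: Iterable[SeriousnessReason | str]) -> bool:
    """Return whether a consequence with these reasons counts as serious.

    A clinical consequence is serious if and only if at least one of the
    enumerated pharmacovigilance criteria applies — i.e. iff ``reasons`` is
    non-empty.  Tokens are validated against :class:`SeriousnessReason`.

    Raises
    ------
    VocabularyError
        If a token is not one of the enumerated reasons.
    """
    count = 0
    for r in reasons:
        _coerce_reason(r)
        count += 1
    return count > 0


def _coerce_reason(token: SeriousnessReason | str) -> SeriousnessReason:
    if isinstance(token, SeriousnessReason):
        return token
    try:
        return SeriousnessReason(token)
    except ValueError:
        raise VocabularyError(
            f"unknown seriousness reason {token!r}; expected one of "
            f"{[m.value for m in SeriousnessReason]}"
        ) from None


@dataclass(frozen=True)
class SeriousnessAssessment:
    """Whether a consequence is serious, with the criteria that apply.

    Invariant: ``serious`` is true iff ``reasons`` is non-empty, so the
    boolean is derived, never asserted independently.
    """

    reasons: tuple[SeriousnessReason, ...] = ()
    rationale: str = ""

    def __post_init__(self) -> None:
        coerced = tuple(_coerce_reason(r) for r in self.reasons)
        object.__setattr__(self, "reasons", coerced)

    @property
    def serious(self) -> bool:
        return len(self.reasons) > 0


@dataclass(frozen=True)
class ClinicalConsequence:
    """A possible health outcome of exposure to the interaction.

    ``concepts`` codes the outcome (ICD-10 / SNOMED-CT in real deployments);
    an empty list is permitted but draws a best-practice warning.
    ``seriousness`` is required by the model; it is Optional here only so
    the validator can diagnose its absence rather than the constructor.
    """

    description: str
    concepts: tuple[ConceptOrRef, ...] = ()
    seriousness: Optional[SeriousnessAssessment] = None


# ---------------------------------------------------------------------------
# Operational classification (ORCA) and recommended actions
# ---------------------------------------------------------------------------


class OrcaCategory(str, enum.Enum):
    """The five ORCA (OpeRational ClassificAtion of drug interactions)
    management categories, from most to least restrictive:

    * ``AVOID`` — risk of the combination outweighs benefit.
    * ``USUALLY_AVOID`` — use only under special circumstances.
    * ``MINIMIZE_RISK`` — assess risk and act if needed (sub-strategies:
      consider alternatives, circumvent, monitor).
    * ``NO_SPECIAL_PRECAUTIONS`` — risk of adverse outcome appears small.
    * ``IGNORE`` — evidence suggests the drugs do not interact.
    """

    AVOID = "AVOID"
    USUALLY_AVOID = "USUALLY_AVOID"
    MINIMIZE_RISK = "MINIMIZE_RISK"
    NO_SPECIAL_PRECAUTIONS = "NO_SPECIAL_PRECAUTIONS"
    IGNORE = "IGNORE"


#: Restrictiveness order: position in the ORCA list, least restrictive = 0.
_ORCA_RANK = {
    OrcaCategory.IGNORE: 0,
    OrcaCategory.NO_SPECIAL_PRECAUTIONS: 1,
    OrcaCategory.MINIMIZE_RISK: 2,
    OrcaCategory.USUALLY_AVOID: 3,
    OrcaCategory.AVOID: 4,
}


def restrictiveness_rank(category: OrcaCategory | str) -> int:
    """Ordinal position of an ORCA category on the restrictiveness scale.

    ``IGNORE`` = 0 < ``NO_SPECIAL_PRECAUTIONS`` = 1 < ``MINIMIZE_RISK`` = 2
    < ``USUALLY_AVOID`` = 3 < ``AVOID`` = 4.

    Raises
    ------
    VocabularyError
        If ``category`` is not one of the five ORCA categories.
    """
    try:
        cat = OrcaCategory(category)
    except ValueError:
        raise VocabularyError(
            f"unknown ORCA category {category!r}; expected one of "
            f"{[m.value for m in OrcaCategory]}"
        ) from None
    return _ORCA_RANK[cat]


def merge_classifications(
    categories: Sequence[OrcaCategory | str],
) -> OrcaCategory:
    """Combine several ORCA categories conservatively.

    Returns the most restrictive category of the list (maximum under
    :func:`restrictiveness_rank`).  The operation is commutative,
    associative and idempotent; it is the join of the restrictiveness
    lattice, used by the decision engine's conservative unknown-answer
    policy.

    Raises
    ------
    CardinalityError
        If the list is empty.
    VocabularyError
        If any entry is not an ORCA category.
    """
    if not categories:
        raise CardinalityError("merge_classifications requires a non-empty list")
    best = max(categories, key=restrictiveness_rank)
    return OrcaCategory(best)


class MinimizeRiskStrategy(str, enum.Enum):
    """Sub-strategies of the ORCA Minimize-Risk category."""

    CONSIDER_ALTERNATIVES = "consider-alternatives"
    CIRCUMVENT = "circumvent"
    MONITOR = "monitor"


@dataclass(frozen=True)
class OperationalClassification:
    """A short, patient-context-conditioned management directive.

    ``category`` is normally one of the five ORCA categories; adopters may
    use their own classification system, in which case it is a bare string
    (the validator then warns unless some other statement on the artifact
    uses a declared category).  ``sub_strategy`` is only valid under
    ``MINIMIZE_RISK``.
    """

    category: Union[OrcaCategory, str]
    statement: str = ""
    sub_strategy: Optional[MinimizeRiskStrategy] = None
    condition: str = ""
    evidence_refs: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.sub_strategy is not None:
            strat = MinimizeRiskStrategy(self.sub_strategy)
            object.__setattr__(self, "sub_strategy", strat)
            if self.category != OrcaCategory.MINIMIZE_RISK:
                raise ValueError(
                    "sub_strategy is only valid under MINIMIZE_RISK, got "
                    f"category {self.category!r}"
                )

    @property
    def orca_category(self) -> Optional[OrcaCategory]:
        """The category as an ORCA member, or None for adopter systems."""
        try:
            return OrcaCategory(self.category)
        except ValueError:
            return None


class ActionCategory(str, enum.Enum):
    """The three basic recommended-action categories.

    These double as the leaf vocabulary of the decision trees; the model
    treats the decision-tree actions and the artifact-level recommended
    actions as one shared enumeration.
    """

    NO_SPECIAL_PRECAUTIONS = "no-special-precautions"
    ASSESS_RISK_AND_TAKE_ACTION = "assess-risk-and-take-action"
    USE_ONLY_IF_BENEFIT_OUTWEIGHS_RISK = "use-only-if-benefit-outweighs-risk"


@dataclass(frozen=True)
class RecommendedAction:
    """An evidence-based strategy for mitigating the interaction.

    ``action_category`` is one of the three basic categories or an
    adopter-defined string.  Actions should be linked to justifying
    evidence via ``evidence_refs`` (best-practice rule, not a hard
    requirement).
    """

    action_text: str
    action_category: Union[ActionCategory, str] = ActionCategory.ASSESS_RISK_AND_TAKE_ACTION
    evidence_refs: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.action_text.strip():
            raise ValueError("RecommendedAction requires non-empty action_text")


# ---------------------------------------------------------------------------
# Mechanism, contextual factors
# ---------------------------------------------------------------------------

#: Marker text for interactions whose mechanism has not been established.
NOT_ELUCIDATED = "not well elucidated"


@dataclass(frozen=True)
class Mechanism:
    """The process(es) by which the drugs interact, written for clinicians.

    When the mechanism is not known, ``known=False`` with the explicit
    marker text :data:`NOT_ELUCIDATED` in the description still satisfies
    the required-element rule — the point is to state the limits of
    knowledge, not to invent a mechanism.
    """

    known: bool
    description: str = ""
    concepts: tuple[CodedConcept, ...] = ()

    def __post_init__(self) -> None:
        if not self.known and not self.description.strip():
            object.__setattr__(self, "description", NOT_ELUCIDATED)

    @property
    def marked_not_elucidated(self) -> bool:
        return (not self.known) and NOT_ELUCIDATED in self.description.lower()


class ContextualFactorKind(str, enum.Enum):
    """What sort of patient or formulation detail modifies the risk."""

    DEMOGRAPHIC = "demographic"
    CLINICAL_CONDITION = "clinical-condition"
    DRUG_DELIVERY = "drug-delivery"
    CO_MEDICATION = "co-medication"
    OBSERVATION = "observation"
    OTHER = "other"


@dataclass(frozen=True)
class ContextualFactor:
    """A modifying factor: route, co-medication, history, demographics...

    ``free_text_last_resort`` flags a factor that could not be coded; the
    validator accepts it but emits a best-practice warning unless flagged.
    """

    kind: ContextualFactorKind
    description: str
    concepts: tuple[ConceptOrRef, ...] = ()
    effect_note: str = ""
    free_text_last_resort: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "kind", ContextualFactorKind(self.kind))


# ---------------------------------------------------------------------------
# Frequency of exposure / harm
# ---------------------------------------------------------------------------


class FrequencyKind(str, enum.Enum):
    PROPORTION = "proportion"
    RELATIVE_RISK = "relative-risk"
    UNKNOWN = "unknown"


@dataclass(frozen=True)
class Frequency:
    """Frequency of exposure to the combination, or of harm among the
    exposed.

    Three kinds are supported: a proportion in [0, 1]; a relative-risk
    range (low, high); and *unknown*, which is itself information — it
    states that no population data exist, rather than that nobody looked.
    ``parsed`` is False when free text failed every parse dialect and was
    preserved verbatim in ``description``.
    """

    kind: FrequencyKind
    value: Optional[float] = None
    low: Optional[float] = None
    high: Optional[float] = None
    description: str = ""
    evidence_refs: tuple[str, ...] = ()
    parsed: bool = True

    def __post_init__(self) -> None:
        kind = FrequencyKind(self.kind)
        object.__setattr__(self, "kind", kind)
        if kind is FrequencyKind.PROPORTION:
            if self.value is None or not (0.0 <= self.value <= 1.0):
                raise FrequencyRangeError(
                    f"proportion must lie in [0, 1], got {self.value!r}"
                )
            if self.low is not None or self.high is not None:
                raise ValueError("proportion carries value only, not low/high")
        elif kind is FrequencyKind.RELATIVE_RISK:
            if self.low is None or self.high is None:
                raise ValueError("relative-risk requires low and high")
            if self.low <= 0 or self.high <= 0 or self.low > self.high:
                raise FrequencyRangeError(
                    f"relative-risk range must satisfy 0 < low <= high, got "
                    f"({self.low!r}, {self.high!r})"
                )
            if self.value is not None:
                raise ValueError("relative-risk carries low/high only, not value")
        else:  # UNKNOWN
            if self.value is not None or self.low is not None or self.high is not None:
                raise ValueError("unknown frequency stores no numeric value")


_PERCENT_RE = re.compile(r"^\s*(\d+(?:\.\d+)?)\s*%\s*$")
_PERCENT_ANY_RE = re.compile(r"(\d+(?:\.\d+)?)\s*%")
_RANGE_RE = re.compile(r"(\d+(?:\.\d+)?)\s*[–—-]\s*(\d+(?:\.\d+)?)")


def parse_frequency(text: str) -> Frequency:
    """Parse a free-text frequency statement into a :class:`Frequency`.

    Three dialects are recognized, in order:

    * a percentage ``"24.3%"`` (alone or embedded in a sentence) becomes a
      proportion 0.243;
    * a numeric range ``"2.9–3.3"`` (en-dash or hyphen, alone or embedded)
      becomes a relative-risk range;
    * the word ``"unknown"`` (case-insensitive) becomes kind ``unknown``.

    Anything else is preserved: the result has kind ``unknown``, the
    original text in ``description`` and ``parsed=False`` — free text is a
    legal last resort, never rejected.

    Raises
    ------
    FrequencyRangeError
        If a percentage is outside [0, 100].
    ValueError
        If ``text`` is empty.
    """
    if not text or not text.strip():
        raise ValueError("parse_frequency requires non-empty text")
    stripped = text.strip()

    m = _PERCENT_RE.match(stripped) or _PERCENT_ANY_RE.search(stripped)
    if m:
        pct = float(m.group(1))
        if pct > 100.0:
            raise FrequencyRangeError(f"percentage out of range [0, 100]: {pct}")
        return Frequency(
            kind=FrequencyKind.PROPORTION, value=pct / 100.0, description=stripped
        )

    m = _RANGE_RE.search(stripped)
    if m:
        low, high = float(m.group(1)), float(m.group(2))
        return Frequency(
            kind=FrequencyKind.RELATIVE_RISK, low=low, high=high, description=stripped
        )

    if stripped.lower() == "unknown":
        return Frequency(kind=FrequencyKind.UNKNOWN)

    return Frequency(kind=FrequencyKind.UNKNOWN, description=stripped, parsed=False)


def format_frequency(freq: Frequency) -> str:
    """Render a :class:`Frequency` back to a short display string.

    Proportions print as percentages rounded to three decimals, so
    ``parse_frequency("24.3%")`` formats back with numeric part 24.3.
    """
    if freq.kind is FrequencyKind.PROPORTION:
        return f"{round(freq.value * 100.0, 3):g}%"
    if freq.kind is FrequencyKind.RELATIVE_RISK:
        return f"{freq.low:g}–{freq.high:g}"
    if not freq.parsed and freq.description:
        return freq.description
    return "Unknown"


# ---------------------------------------------------------------------------
# Evidence
# ---------------------------------------------------------------------------


class EvidenceStance(str, enum.Enum):
    SUPPORTS = "supports"
    REFUTES = "refutes"


class EvidenceType(str, enum.Enum):
    CLINICAL_STUDY = "clinical-study"
    OBSERVATIONAL = "observational"
    CASE_REPORT = "case-report"
    PHYSIOLOGICAL_EXPERIMENT = "physiological-experiment"
    MECHANISTIC_EXTRAPOLATION = "mechanistic-extrapolation"
    PRODUCT_LABEL = "product-label"
    OTHER = "other"


@dataclass(frozen=True)
class EvidenceItem:
    """One piece of evidence for or against the interaction.

    ``id`` is local to the artifact and is the target of ``evidence_refs``
    elsewhere; it must be unique within the artifact.
    """

    id: str
    stance: EvidenceStance = EvidenceStance.SUPPORTS
    type: EvidenceType = EvidenceType.OTHER
    citation: str = ""
    summary: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("EvidenceItem requires a non-empty id")
        object.__setattr__(self, "stance", EvidenceStance(self.stance))
        object.__setattr__(self, "type", EvidenceType(self.type))


# ---------------------------------------------------------------------------
# The artifact itself
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PDDIArtifact:
    """One PDDI knowledge artifact housing the ten information items.

    The dataclass itself is structural and permissive — slots may be empty
    or None so that the validator can *diagnose* a non-conformant artifact
    instead of refusing to represent it.  Use :func:`new_artifact` to build
    artifacts with the hard invariants (at least two drugs, resolvable
    evidence references, unique evidence ids) enforced up front.

    ``extensions`` preserves adopter-defined top-level keys encountered
    during parsing so they survive a round-trip.
    """

    id: str
    title: str = ""
    version: str = "0.1"
    drugs: tuple[DrugInvolved, ...] = ()
    consequences: tuple[ClinicalConsequence, ...] = ()
    classifications: tuple[OperationalClassification, ...] = ()
    actions: tuple[RecommendedAction, ...] = ()
    mechanism: Optional[Mechanism] = None
    contextual_factors: tuple[ContextualFactor, ...] = ()
    evidence: tuple[EvidenceItem, ...] = ()
    frequency_exposure: Optional[Frequency] = None
    frequency_harm: Optional[Frequency] = None
    decision_tree: Optional["object"] = None  # DecisionTree; kept loose to avoid a cycle
    extensions: tuple[tuple[str, object], ...] = ()

    def evidence_ids(self) -> set[str]:
        return {e.id for e in self.evidence}

    def all_evidence_refs(self) -> list[str]:
        """Every evidence reference used anywhere on the artifact."""
        refs: list[str] = []
        for c in self.classifications:
            refs.extend(c.evidence_refs)
        for a in self.actions:
            refs.extend(a.evidence_refs)
        for f in (self.frequency_exposure, self.frequency_harm):
            if f is not None:
                refs.extend(f.evidence_refs)
        return refs


def new_artifact(
    *,
    id: str,
    title: str = "",
    version: str = "0.1",
    drugs: Sequence[DrugInvolved],
    consequences: Sequence[ClinicalConsequence] = (),
    classifications: Sequence[OperationalClassification] = (),
    actions: Sequence[RecommendedAction] = (),
    mechanism: Optional[Mechanism] = None,
    contextual_factors: Sequence[ContextualFactor] = (),
    evidence: Sequence[EvidenceItem] = (),
    frequency_exposure: Optional[Frequency] = None,
    frequency_harm: Optional[Frequency] = None,
    decision_tree: Optional["object"] = None,
    extensions: Sequence[tuple[str, object]] = (),
) -> PDDIArtifact:
    """Construct a :class:`PDDIArtifact` with hard invariants enforced.

    An interaction needs at least two participants, every evidence
    reference must resolve to a declared evidence item, and evidence ids
    must be unique.  Model *conformance* (required slots populated,
    best-practice recommendations followed) is not checked here — that is
    :func:`pddikit.validator.validate`'s job.

    Raises
    ------
    CardinalityError
        If fewer than two drug slots are supplied.
    DanglingReferenceError
        If an evidence_ref does not resolve, or evidence ids collide.
    """
    if len(drugs) < 2:
        raise CardinalityError(
            f"a PDDI involves at least two drugs, got {len(drugs)}"
        )
    ids = [e.id for e in evidence]
    if len(ids) != len(set(ids)):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise DanglingReferenceError(f"duplicate evidence ids: {dupes}")

    artifact = PDDIArtifact(
        id=id,
        title=title,
        version=version,
        drugs=tuple(drugs),
        consequences=tuple(consequences),
        classifications=tuple(classifications),
        actions=tuple(actions),
        mechanism=mechanism,
        contextual_factors=tuple(contextual_factors),
        evidence=tuple(evidence),
        frequency_exposure=frequency_exposure,
        frequency_harm=frequency_harm,
        decision_tree=decision_tree,
        extensions=tuple(extensions),
    )
    known = artifact.evidence_ids()
    dangling = [r for r in artifact.all_evidence_refs() if r not in known]
    if decision_tree is not None:
        for leaf_refs in _tree_evidence_refs(decision_tree):
            if leaf_refs not in known:
                dangling.append(leaf_refs)
    if dangling:
        raise DanglingReferenceError(
            f"evidence refs do not resolve: {sorted(set(dangling))}"
        )
    return artifact


def _tree_evidence_refs(tree: object) -> list[str]:
    refs: list[str] = []
    leaves = getattr(tree, "leaves", None)
    if callable(leaves):
        for leaf in leaves():
            refs.extend(getattr(leaf.outcome, "evidence_refs", ()))
    return refs


# ---------------------------------------------------------------------------
# Schema registry: the ten information items
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class InformationItem:
    """Descriptor of one information-item slot of the model."""

    key: str
    title: str
    required: bool
    definition: str


_INFORMATION_ITEMS: tuple[InformationItem, ...] = (
    InformationItem(
        "drugs",
        "Drugs involved",
        True,
        "At least two participating drug products, classes, or active ingredients.",
    ),
    InformationItem(
        "consequences",
        "Clinical consequences",
        True,
        "Known or anticipated health outcomes of exposure, stated as specifically "
        "as possible, ideally coded (ICD-10, SNOMED-CT) or via a value set.",
    ),
    InformationItem(
        "seriousness",
        "Seriousness",
        True,
        "Per consequence: serious iff it may result in death, life-threatening "
        "hospitalization, congenital anomaly, disability, or permanent impairment.",
    ),
    InformationItem(
        "classifications",
        "Operational classification statement",
        True,
        "A short management directive for a patient context, drawn from a "
        "classification system such as ORCA.",
    ),
    InformationItem(
        "actions",
        "Recommended action",
        False,
        "Evidence-based approaches to minimize risk, including alternative drugs.",
    ),
    InformationItem(
        "mechanism",
        "Mechanism of interaction",
        True,
        "The process(es) involved in the interaction; if not known, say so "
        "explicitly.",
    ),
    InformationItem(
        "contextual_factors",
        "Contextual information / modifying factors",
        True,
        "Demographic, clinical, or drug-delivery details that modify risk or "
        "management.",
    ),
    InformationItem(
        "evidence",
        "Evidence",
        True,
        "Support for, or refutation of, the interaction in humans.",
    ),
    InformationItem(
        "frequency_exposure",
        "Frequency of exposure",
        False,
        "Proportion of a cohort administered the combination over a period; "
        "'unknown' when no data exist.",
    ),
    InformationItem(
        "frequency_harm",
        "Frequency of harm",
        False,
        "Fraction of the exposed who experience harm; 'unknown' when no data "
        "exist.",
    ),
)


def information_items() -> tuple[InformationItem, ...]:
    """The schema registry: the ten information-item slots, in model order.

    Exactly seven are flagged required; seriousness is counted as its own
    item even though it nests inside each clinical consequence.
    """
    return _INFORMATION_ITEMS
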