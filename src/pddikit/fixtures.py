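"""Executable example artifacts, demo value sets, and synthetic patients.

Two interactions are reconstructed in full from their published
minimal-information-model descriptions:

* **warfarin – NSAIDs**: bleeding risk from anti-platelet effects of
  NSAIDs on top of anticoagulation; frequency data available (24.3% of
  warfarin courses see concomitant NSAIDs; upper-GI-bleed relative risk
  2.9–3.3).
* **tyrosine kinase inhibitors – proton pump inhibitors**: pH-dependent
  absorption; the management branches on which TKI is involved, and both
  frequency slots are honestly *unknown*.

A 14-entry exemplar registry covers the curated decision-tree collection
(one entry per unique drug pair, tagged with the situations each pair was
chosen to illustrate); entries other than the two above are conformant
stubs, flagged illustrative.

All drug and condition codes use the local ``DEMO-RX`` / ``DEMO-COND``
code systems with human-readable names as codes.  They are deliberately
illustrative: real deployments substitute RxNorm/ATC/SNOMED-CT value sets.
The decision-tree branch structure beyond the published branching (TKI
identity; topical route, gastroprotection, ulcer history for warfarin) is
an authored reconstruction, not normative.

Synthetic patient contexts come from :func:`generate_contexts`, seeded and
reproducible (stdlib ``random.Random``, i.e. Mersenne Twister, stable
across platforms).
"""

from __future__ import annotations

import random
from dataclasses import dataclass

from .engine import (
    Comparator,
    DecisionTree,
    InternalNode,
    Leaf,
    MedicationRecord,
    ObservationRecord,
    Outcome,
    PatientContext,
    Question,
    QuestionKind,
)
from .model import (
    NOT_ELUCIDATED,
    ActionCategory,
    ClinicalConsequence,
    CodedConcept,
    ContextualFactor,
    ContextualFactorKind,
    DrugInvolved,
    DrugLevel,
    DrugRole,
    EvidenceItem,
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
    new_artifact,
    parse_frequency,
)
from .value_sets import ValueSet, ValueSetRegistry

__all__ = [
    "RX",
    "COND",
    "OBS",
    "rx",
    "cond",
    "demo_value_sets",
    "demo_registry",
    "warfarin_nsaid_artifact",
    "tki_ppi_artifact",
    "ExemplarEntry",
    "exemplar_registry",
    "generate_contexts",
    "generate_artifacts",
    "INR",
]

RX = "DEMO-RX"
COND = "DEMO-COND"
OBS = "DEMO-OBS"


def rx(code: str, display: str = "") -> CodedConcept:
    return CodedConcept(RX, code, display or code.replace("-", " "))


def cond(code: str, display: str = "") -> CodedConcept:
    return CodedConcept(COND, code, display or code.replace("-", " "))


#: The INR observation concept used by observation questions.
INR = CodedConcept(OBS, "inr", "International normalized ratio")


# ---------------------------------------------------------------------------
# Demo value sets
# ---------------------------------------------------------------------------


def demo_value_sets() -> list[ValueSet]:
    """All demo value sets, in a stable order."""

    def vs(id: str, name: str, codes: list[str], system: str = RX) -> ValueSet:
        make = rx if system == RX else cond
        return ValueSet(id=id, name=name, members=tuple(make(c) for c in codes))

    return [
        vs("warfarin", "Warfarin", ["warfarin"]),
        vs(
            "nsaids",
            "Non-steroidal anti-inflammatory drugs",
            ["naproxen", "ibuprofen", "diclofenac", "ketorolac", "celecoxib",
             "indomethacin"],
        ),
        vs("diclofenac", "Diclofenac (any form)", ["diclofenac"]),
        vs("topical-nsaids", "Topical NSAID products", ["diclofenac-topical"]),
        vs(
            "gastroprotective-agents",
            "Proton pump inhibitors and misoprostol",
            ["omeprazole", "esomeprazole", "pantoprazole", "misoprostol"],
        ),
        vs(
            "ppis",
            "Proton pump inhibitors",
            ["omeprazole", "esomeprazole", "pantoprazole", "lansoprazole",
             "rabeprazole"],
        ),
        vs(
            "tkis",
            "Tyrosine kinase inhibitors",
            ["imatinib", "ponatinib", "nilotinib", "bosutinib", "dasatinib"],
        ),
        vs("tkis-ph-insensitive", "TKIs without pH-dependent exposure loss",
           ["imatinib", "ponatinib"]),
        vs("nilotinib", "Nilotinib", ["nilotinib"]),
        vs("tkis-ph-sensitive", "TKIs with pH-dependent exposure loss",
           ["bosutinib", "dasatinib"]),
        vs(
            "ulcer-ugib-history",
            "History of peptic ulcer or upper GI bleeding",
            ["peptic-ulcer", "upper-gi-bleeding"],
            system=COND,
        ),
        vs(
            "bleeding-consequences",
            "Bleeding outcomes",
            ["gastrointestinal-bleeding", "intracranial-hemorrhage",
             "cerebral-hemorrhage"],
            system=COND,
        ),
        vs("cml", "Chronic myeloid leukemia", ["chronic-myeloid-leukemia"],
           system=COND),
        # Drug sets for the stub exemplars.
        vs("tamoxifen", "Tamoxifen", ["tamoxifen"]),
        vs("paroxetine", "Paroxetine", ["paroxetine"]),
        vs("potassium-supplements", "Potassium supplements", ["potassium-chloride"]),
        vs("potassium-sparing-diuretics", "Potassium-sparing diuretics",
           ["spironolactone", "amiloride", "triamterene", "eplerenone"]),
        vs("maois", "Monoamine oxidase inhibitors",
           ["phenelzine", "tranylcypromine", "isocarboxazid", "selegiline"]),
        vs("indirect-sympathomimetics", "Indirect sympathomimetics",
           ["pseudoephedrine", "phenylephrine", "amphetamine", "ephedrine"]),
        vs("cyp2c9-inhibitors", "CYP2C9 inhibitors",
           ["sulfamethoxazole-trimethoprim", "fluconazole", "amiodarone"]),
        vs("digoxin", "Digoxin", ["digoxin"]),
        vs("cyclosporin", "Cyclosporin", ["cyclosporin"]),
        vs("epinephrine", "Epinephrine", ["epinephrine"]),
        vs("beta-blockers", "Non-selective beta-blockers",
           ["propranolol", "nadolol", "timolol"]),
        vs("ifosfamide-etoposide", "Ifosfamide / etoposide",
           ["ifosfamide", "etoposide"]),
        vs("statins-cyp3a4", "CYP3A4-metabolized statins",
           ["simvastatin", "atorvastatin", "lovastatin"]),
        vs("clarithromycin", "Clarithromycin", ["clarithromycin"]),
        vs("uncertain-cyp2c9-antibiotics",
           "Antibiotics with uncertain CYP2C9 inhibition",
           ["levofloxacin", "azithromycin", "doxycycline"]),
        vs("simvastatin", "Simvastatin", ["simvastatin"]),
        vs("fluconazole", "Fluconazole", ["fluconazole"]),
        vs("amiodarone", "Amiodarone", ["amiodarone"]),
    ]


def demo_registry() -> ValueSetRegistry:
    """A fresh registry holding every demo value set."""
    return ValueSetRegistry(demo_value_sets())


# ---------------------------------------------------------------------------
# Worked artifact: warfarin – NSAIDs
# ---------------------------------------------------------------------------


def warfarin_nsaid_artifact() -> PDDIArtifact:
    """The warfarin – NSAID knowledge artifact, frequency data available.

    Exposure: concomitant NSAIDs occur with 24.3% of warfarin courses of
    therapy.  Harm: the relative risk of upper GI bleeding on the
    combination is 2.9–3.3 times that of warfarin alone.  The decision
    tree branches on the contextual factors: topical diclofenac, history
    of ulcers / upper GI bleeding, elevated INR, and gastroprotection.
    """
    bleeding_serious = SeriousnessAssessment(
        reasons=(
            SeriousnessReason.DEATH,
            SeriousnessReason.LIFE_THREATENING_HOSPITALIZATION,
            SeriousnessReason.DISABILITY,
        ),
        rationale=(
            "Bleeding is serious because it may result in death, "
            "life-threatening hospitalization, and disability"
        ),
    )
    evidence = (
        EvidenceItem(
            id="ev-ugib-rr",
            type=EvidenceType.OBSERVATIONAL,
            citation="Cohort study of upper GI bleeding under concurrent "
                     "warfarin and NSAID use",
            summary="Relative risk of upper GI bleeding 2.9–3.3 versus "
                    "warfarin alone.",
        ),
        EvidenceItem(
            id="ev-exposure-cohort",
            type=EvidenceType.OBSERVATIONAL,
            citation="Prescription-claims analysis of warfarin courses of therapy",
            summary="Concomitant NSAIDs occur with 24.3% of warfarin courses "
                    "of therapy.",
        ),
        EvidenceItem(
            id="ev-gastroprotection",
            type=EvidenceType.CLINICAL_STUDY,
            citation="Corticosteroids and aldosterone antagonists increase "
                     "upper GI bleeding risk in NSAID users",
            summary="Risk modification by co-medication supports "
                    "gastroprotective co-prescription.",
        ),
        EvidenceItem(
            id="ev-antiplatelet",
            type=EvidenceType.PHYSIOLOGICAL_EXPERIMENT,
            citation="Platelet-aggregation studies of non-selective NSAIDs",
            summary="NSAIDs inhibit platelet aggregation, compounding "
                    "anticoagulant bleeding risk.",
        ),
    )

    def leaf(cat: ActionCategory, cls: OrcaCategory, text: str,
             refs: tuple[str, ...] = ()) -> Leaf:
        return Leaf(Outcome(action_category=cat, classification=cls,
                            action_text=text, evidence_refs=refs))

    tree = DecisionTree(
        root=InternalNode(
            question=Question(
                id="q-topical",
                kind=QuestionKind.MED_ROUTE_IS,
                text="Is the NSAID topical diclofenac?",
                value_set=ValueSetRef("diclofenac"),
                route="topical",
            ),
            yes=leaf(
                ActionCategory.NO_SPECIAL_PRECAUTIONS,
                OrcaCategory.NO_SPECIAL_PRECAUTIONS,
                "Topical diclofenac yields minimal systemic exposure; no "
                "special precautions.",
                ("ev-antiplatelet",),
            ),
            no=InternalNode(
                question=Question(
                    id="q-ulcer-history",
                    kind=QuestionKind.CONDITION_IN_VALUESET,
                    text="History of peptic ulcer or upper GI bleeding?",
                    value_set=ValueSetRef("ulcer-ugib-history"),
                ),
                yes=leaf(
                    ActionCategory.USE_ONLY_IF_BENEFIT_OUTWEIGHS_RISK,
                    OrcaCategory.USUALLY_AVOID,
                    "Prior ulcer or upper GI bleeding: use the combination "
                    "only if benefit outweighs the risk; prefer alternatives.",
                    ("ev-ugib-rr",),
                ),
                no=InternalNode(
                    question=Question(
                        id="q-inr-high",
                        kind=QuestionKind.OBSERVATION_COMPARE,
                        text="Is the INR above 3?",
                        observation=INR,
                        comparator=Comparator.GT,
                        threshold=3.0,
                        unit="ratio",
                    ),
                    yes=leaf(
                        ActionCategory.ASSESS_RISK_AND_TAKE_ACTION,
                        OrcaCategory.MINIMIZE_RISK,
                        "INR already elevated: intensify INR monitoring and "
                        "reassess the need for the NSAID.",
                        ("ev-ugib-rr",),
                    ),
                    no=InternalNode(
                        question=Question(
                            id="q-gastroprotection",
                            kind=QuestionKind.MED_IN_VALUESET,
                            text="Proton pump inhibitor or misoprostol "
                                 "co-administered?",
                            value_set=ValueSetRef("gastroprotective-agents"),
                        ),
                        yes=leaf(
                            ActionCategory.ASSESS_RISK_AND_TAKE_ACTION,
                            OrcaCategory.MINIMIZE_RISK,
                            "Gastroprotection on board: monitor INR and for "
                            "signs of bleeding.",
                            ("ev-gastroprotection",),
                        ),
                        no=leaf(
                            ActionCategory.ASSESS_RISK_AND_TAKE_ACTION,
                            OrcaCategory.MINIMIZE_RISK,
                            "Consider alternatives such as acetaminophen; "
                            "monitor INR if NSAID use continues.",
                            ("ev-ugib-rr", "ev-antiplatelet"),
                        ),
                    ),
                ),
            ),
        )
    )

    return new_artifact(
        id="warfarin-nsaids",
        title="Warfarin – non-steroidal anti-inflammatory drugs (NSAIDs)",
        drugs=(
            DrugInvolved(role=DrugRole.OBJECT, concept=rx("warfarin", "Warfarin"),
                         level=DrugLevel.INGREDIENT),
            DrugInvolved(role=DrugRole.PRECIPITANT,
                         value_set=ValueSetRef("nsaids"), level=DrugLevel.CLASS),
        ),
        consequences=(
            ClinicalConsequence(
                description="Increased risk of bleeding, including "
                            "gastrointestinal bleeding, intracranial "
                            "hemorrhage, and cerebral hemorrhage",
                concepts=(ValueSetRef("bleeding-consequences"),),
                seriousness=bleeding_serious,
            ),
        ),
        classifications=(
            OperationalClassification(
                category=OrcaCategory.MINIMIZE_RISK,
                sub_strategy=MinimizeRiskStrategy.CONSIDER_ALTERNATIVES,
                statement="Consider alternatives: Alternatives may be "
                          "available that are less likely to interact",
                evidence_refs=("ev-ugib-rr",),
            ),
        ),
        actions=(
            RecommendedAction(
                action_text="If the NSAID is being used as an analgesic or "
                            "antipyretic, consider alternatives such as "
                            "acetaminophen and monitor INR if use continues. "
                            "For severe pain, consider opioids in place of "
                            "the NSAID",
                action_category=ActionCategory.ASSESS_RISK_AND_TAKE_ACTION,
                evidence_refs=("ev-ugib-rr", "ev-antiplatelet"),
            ),
        ),
        mechanism=Mechanism(
            known=True,
            description="Anti-platelet effects of NSAIDs can increase "
                        "bleeding risks when combined with anticoagulants "
                        "such as warfarin",
        ),
        contextual_factors=(
            ContextualFactor(
                kind=ContextualFactorKind.DRUG_DELIVERY,
                description="NSAID is topical diclofenac",
                concepts=(ValueSetRef("topical-nsaids"),),
                effect_note="Minimal systemic absorption lowers the risk.",
            ),
            ContextualFactor(
                kind=ContextualFactorKind.CO_MEDICATION,
                description="Co-administration of proton pump inhibitors or "
                            "misoprostol",
                concepts=(ValueSetRef("gastroprotective-agents"),),
                effect_note="Gastroprotection mitigates upper GI bleeding risk.",
            ),
            ContextualFactor(
                kind=ContextualFactorKind.CLINICAL_CONDITION,
                description="History of ulcers or upper gastrointestinal "
                            "bleeding",
                concepts=(ValueSetRef("ulcer-ugib-history"),),
                effect_note="Prior ulcer or UGIB substantially raises the risk.",
            ),
        ),
        evidence=evidence,
        frequency_exposure=Frequency(
            kind=FrequencyKind.PROPORTION,
            value=parse_frequency("24.3%").value,
            description="Concomitant NSAIDs occur with 24.3% of warfarin "
                        "courses of therapy.",
            evidence_refs=("ev-exposure-cohort",),
        ),
        frequency_harm=Frequency(
            kind=FrequencyKind.RELATIVE_RISK,
            low=2.9,
            high=3.3,
            description="The relative risk of upper GI bleeding with "
                        "concurrent warfarin and NSAID use is 2.9–3.3 higher "
                        "than for warfarin alone.",
            evidence_refs=("ev-ugib-rr",),
        ),
        decision_tree=tree,
    )


# ---------------------------------------------------------------------------
# Worked artifact: TKIs – PPIs
# ---------------------------------------------------------------------------


def tki_ppi_artifact() -> PDDIArtifact:
    """The tyrosine-kinase-inhibitor – proton-pump-inhibitor artifact.

    The interaction does *not* apply at the class level: imatinib and
    ponatinib exposure is not appreciably reduced by acid suppression
    (no special precautions); nilotinib exposure drops but outcomes look
    unchanged (assess risk, space an antacid/H2 antagonist 2 h after the
    TKI); bosutinib and dasatinib labels advise against concomitant PPIs
    (use only if benefit outweighs risk).  Both frequency slots are
    *unknown* — no population data exist.
    """
    evidence = (
        EvidenceItem(
            id="ev-imatinib-auc",
            type=EvidenceType.CLINICAL_STUDY,
            citation="Pharmacokinetic studies of imatinib and ponatinib with "
                     "acid-suppressing agents",
            summary="Imatinib and ponatinib AUCs are not appreciably "
                    "decreased by PPI co-administration.",
        ),
        EvidenceItem(
            id="ev-nilotinib-esomeprazole",
            type=EvidenceType.CLINICAL_STUDY,
            citation="Esomeprazole interaction study of nilotinib",
            summary="Esomeprazole decreased the nilotinib AUC by 34%, but a "
                    "retrospective study showed no difference in cytogenetic "
                    "response rates for patients taking PPIs.",
        ),
        EvidenceItem(
            id="ev-bosutinib-dasatinib-label",
            type=EvidenceType.PRODUCT_LABEL,
            citation="Bosutinib and dasatinib product labeling",
            summary="Product labeling recommends avoiding concomitant PPIs "
                    "with bosutinib or dasatinib.",
        ),
    )

    def leaf(cat: ActionCategory, cls: OrcaCategory, text: str,
             refs: tuple[str, ...]) -> Leaf:
        return Leaf(Outcome(action_category=cat, classification=cls,
                            action_text=text, evidence_refs=refs))

    tree = DecisionTree(
        root=InternalNode(
            question=Question(
                id="q-ppi",
                kind=QuestionKind.MED_IN_VALUESET,
                text="Is the patient taking a proton pump inhibitor?",
                value_set=ValueSetRef("ppis"),
            ),
            no=leaf(
                ActionCategory.NO_SPECIAL_PRECAUTIONS,
                OrcaCategory.NO_SPECIAL_PRECAUTIONS,
                "No proton pump inhibitor on the medication list; the "
                "interaction does not arise.",
                ("ev-imatinib-auc",),
            ),
            yes=InternalNode(
                question=Question(
                    id="q-tki-ph-insensitive",
                    kind=QuestionKind.MED_IN_VALUESET,
                    text="Is the TKI imatinib or ponatinib?",
                    value_set=ValueSetRef("tkis-ph-insensitive"),
                ),
                yes=leaf(
                    ActionCategory.NO_SPECIAL_PRECAUTIONS,
                    OrcaCategory.NO_SPECIAL_PRECAUTIONS,
                    "Imatinib and ponatinib exposure is not appreciably "
                    "decreased by PPIs: no special precautions.",
                    ("ev-imatinib-auc",),
                ),
                no=InternalNode(
                    question=Question(
                        id="q-tki-nilotinib",
                        kind=QuestionKind.MED_IN_VALUESET,
                        text="Is the TKI nilotinib?",
                        value_set=ValueSetRef("nilotinib"),
                    ),
                    yes=leaf(
                        ActionCategory.ASSESS_RISK_AND_TAKE_ACTION,
                        OrcaCategory.MINIMIZE_RISK,
                        "Assess risk and take action if necessary: antacids "
                        "and H2 antagonists may be considered if the TKI is "
                        "given 2 h before the antacid/H2 antagonist.",
                        ("ev-nilotinib-esomeprazole",),
                    ),
                    no=InternalNode(
                        question=Question(
                            id="q-tki-ph-sensitive",
                            kind=QuestionKind.MED_IN_VALUESET,
                            text="Is the TKI bosutinib or dasatinib?",
                            value_set=ValueSetRef("tkis-ph-sensitive"),
                        ),
                        yes=leaf(
                            ActionCategory.USE_ONLY_IF_BENEFIT_OUTWEIGHS_RISK,
                            OrcaCategory.USUALLY_AVOID,
                            "Use only if benefit outweighs risk: product "
                            "labeling recommends avoiding concomitant PPIs "
                            "with bosutinib or dasatinib.",
                            ("ev-bosutinib-dasatinib-label",),
                        ),
                        no=leaf(
                            ActionCategory.NO_SPECIAL_PRECAUTIONS,
                            OrcaCategory.NO_SPECIAL_PRECAUTIONS,
                            "No pH-sensitive TKI on the medication list; no "
                            "special precautions.",
                            ("ev-imatinib-auc",),
                        ),
                    ),
                ),
            ),
        )
    )

    return new_artifact(
        id="tki-ppi",
        title="Tyrosine kinase inhibitors – proton pump inhibitors",
        drugs=(
            DrugInvolved(role=DrugRole.OBJECT, value_set=ValueSetRef("tkis"),
                         level=DrugLevel.CLASS),
            DrugInvolved(role=DrugRole.PRECIPITANT, value_set=ValueSetRef("ppis"),
                         level=DrugLevel.CLASS),
        ),
        consequences=(
            ClinicalConsequence(
                description="Decreased efficacy relative to treatment for "
                            "chronic myeloid leukemia",
                concepts=(ValueSetRef("cml"),),
                seriousness=SeriousnessAssessment(
                    reasons=(
                        SeriousnessReason.DEATH,
                        SeriousnessReason.LIFE_THREATENING_HOSPITALIZATION,
                        SeriousnessReason.DISABILITY,
                    ),
                    rationale="A decrease in chronic myeloid leukemia "
                              "treatment efficacy is a serious potential "
                              "clinical consequence because it can result in "
                              "death, life-threatening hospitalization, and "
                              "disability.",
                ),
            ),
        ),
        classifications=(
            OperationalClassification(
                category=OrcaCategory.NO_SPECIAL_PRECAUTIONS,
                condition="TKI is imatinib or ponatinib",
                statement="No special precautions",
                evidence_refs=("ev-imatinib-auc",),
            ),
            OperationalClassification(
                category=OrcaCategory.MINIMIZE_RISK,
                sub_strategy=MinimizeRiskStrategy.CIRCUMVENT,
                condition="TKI is nilotinib",
                statement="Assess risk and take action if necessary",
                evidence_refs=("ev-nilotinib-esomeprazole",),
            ),
            OperationalClassification(
                category=OrcaCategory.USUALLY_AVOID,
                condition="TKI is bosutinib or dasatinib",
                statement="Use only if benefit outweighs risk",
                evidence_refs=("ev-bosutinib-dasatinib-label",),
            ),
        ),
        actions=(
            RecommendedAction(
                action_text="Antacids and H2 antagonists may be considered "
                            "if the TKI is given 2 h before the antacid/H2 "
                            "antagonist",
                action_category=ActionCategory.ASSESS_RISK_AND_TAKE_ACTION,
                evidence_refs=("ev-nilotinib-esomeprazole",),
            ),
        ),
        mechanism=Mechanism(
            known=True,
            description="The TKIs demonstrate pH-dependent absorption for "
                        "oral administration, which may result in decreased "
                        "efficacy when given concomitantly with medications "
                        "that increase gastric pH.",
        ),
        contextual_factors=(
            ContextualFactor(
                kind=ContextualFactorKind.CO_MEDICATION,
                description="Imatinib and ponatinib AUCs are not appreciably "
                            "decreased by PPI co-administration",
                concepts=(ValueSetRef("tkis-ph-insensitive"),),
            ),
            ContextualFactor(
                kind=ContextualFactorKind.CO_MEDICATION,
                description="For nilotinib, esomeprazole decreased the AUC "
                            "by 34% but cytogenetic response rates were "
                            "unchanged in a retrospective study",
                concepts=(ValueSetRef("nilotinib"),),
            ),
            ContextualFactor(
                kind=ContextualFactorKind.CO_MEDICATION,
                description="Product labeling recommends avoiding concomitant "
                            "PPIs with bosutinib or dasatinib",
                concepts=(ValueSetRef("tkis-ph-sensitive"),),
            ),
        ),
        evidence=evidence,
        frequency_exposure=Frequency(kind=FrequencyKind.UNKNOWN),
        frequency_harm=Frequency(kind=FrequencyKind.UNKNOWN),
        decision_tree=tree,
    )


# ---------------------------------------------------------------------------
# The 14-entry exemplar registry
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ExemplarEntry:
    """One entry of the curated decision-tree collection."""

    slug: str
    drug_1: str
    drug_2: str
    situations: tuple[str, ...]
    artifact: PDDIArtifact
    full: bool = False  # True for the two fully reconstructed artifacts


def _stub(
    slug: str,
    title: str,
    vs1: str,
    vs2: str,
    consequence: str,
    reasons: tuple[SeriousnessReason, ...],
    category: OrcaCategory,
    *,
    sub_strategy: MinimizeRiskStrategy | None = None,
    statement: str = "",
    mechanism: Mechanism | None = None,
    frequency_exposure: Frequency | None = None,
    frequency_harm: Frequency | None = None,
    action: RecommendedAction | None = None,
) -> PDDIArtifact:
    """A conformant stub artifact (flagged illustrative in its title)."""
    ev = EvidenceItem(
        id="ev-1",
        type=EvidenceType.OTHER,
        citation=f"Illustrative evidence stub for {title}",
        summary="Synthetic placeholder; see the published artifact for the "
                "real evidence base.",
    )
    return new_artifact(
        id=slug,
        title=f"{title} (illustrative stub)",
        drugs=(
            DrugInvolved(role=DrugRole.OBJECT, value_set=ValueSetRef(vs1),
                         level=DrugLevel.CLASS),
            DrugInvolved(role=DrugRole.PRECIPITANT, value_set=ValueSetRef(vs2),
                         level=DrugLevel.CLASS),
        ),
        consequences=(
            ClinicalConsequence(
                description=consequence,
                seriousness=SeriousnessAssessment(
                    reasons=reasons,
                    rationale=f"{consequence} meets pharmacovigilance "
                              "seriousness criteria." if reasons else
                              "Not expected to meet seriousness criteria.",
                ),
            ),
        ),
        classifications=(
            OperationalClassification(
                category=category,
                sub_strategy=sub_strategy,
                statement=statement or category.value.replace("_", " ").title(),
            ),
        ),
        actions=(action,) if action else (),
        mechanism=mechanism or Mechanism(
            known=True,
            description=f"Illustrative mechanism stub for {title}.",
        ),
        contextual_factors=(
            ContextualFactor(
                kind=ContextualFactorKind.OTHER,
                description="Illustrative contextual factor stub.",
                free_text_last_resort=True,
            ),
        ),
        evidence=(ev,),
        frequency_exposure=frequency_exposure or Frequency(kind=FrequencyKind.UNKNOWN),
        frequency_harm=frequency_harm or Frequency(kind=FrequencyKind.UNKNOWN),
    )


def exemplar_registry() -> list[ExemplarEntry]:
    """The 14 exemplar interactions, one entry per unique drug pair.

    Each pair is tagged with the situations it was chosen to illustrate
    (some pairs illustrate several).  Two entries carry the fully
    reconstructed artifacts; the rest are conformant stubs, explicitly
    flagged illustrative.
    """
    serious3 = (
        SeriousnessReason.DEATH,
        SeriousnessReason.LIFE_THREATENING_HOSPITALIZATION,
        SeriousnessReason.DISABILITY,
    )
    entries = [
        ExemplarEntry(
            slug="tamoxifen-paroxetine",
            drug_1="Tamoxifen", drug_2="Paroxetine",
            situations=("contextualizable-for-specific-patients",),
            artifact=_stub(
                "tamoxifen-paroxetine", "Tamoxifen – paroxetine",
                "tamoxifen", "paroxetine",
                "Reduced tamoxifen efficacy via CYP2D6 inhibition",
                serious3, OrcaCategory.USUALLY_AVOID,
            ),
        ),
        ExemplarEntry(
            slug="potassium-potassium-sparing-diuretics",
            drug_1="Potassium (KCl)", drug_2="Potassium-sparing diuretics",
            situations=(
                "contextualizable-for-specific-patients",
                "recommended-action-monitor",
            ),
            artifact=_stub(
                "potassium-potassium-sparing-diuretics",
                "Potassium – potassium-sparing diuretics",
                "potassium-supplements", "potassium-sparing-diuretics",
                "Hyperkalemia",
                serious3, OrcaCategory.MINIMIZE_RISK,
                sub_strategy=MinimizeRiskStrategy.MONITOR,
                statement="Monitor: early detection of hyperkalemia can "
                          "minimize the risk of an adverse outcome",
            ),
        ),
        ExemplarEntry(
            slug="maois-indirect-sympathomimetics",
            drug_1="Monoamine oxidase inhibitors (MAOIs)",
            drug_2="Indirect sympathomimetics",
            situations=("applies-at-class-level", "recommended-action-avoid"),
            artifact=_stub(
                "maois-indirect-sympathomimetics",
                "MAOIs – indirect sympathomimetics",
                "maois", "indirect-sympathomimetics",
                "Hypertensive crisis",
                serious3, OrcaCategory.AVOID,
                statement="Avoid combination: risk outweighs benefit",
            ),
        ),
        ExemplarEntry(
            slug="tki-ppi",
            drug_1="Tyrosine kinase inhibitors", drug_2="Proton pump inhibitors",
            situations=("does-not-apply-at-class-level",),
            artifact=tki_ppi_artifact(),
            full=True,
        ),
        ExemplarEntry(
            slug="warfarin-cyp2c9-inhibitors",
            drug_1="Warfarin", drug_2="CYP2C9 inhibitors (e.g. Bactrim)",
            situations=("mechanism-known-pharmacokinetic",),
            artifact=_stub(
                "warfarin-cyp2c9-inhibitors", "Warfarin – CYP2C9 inhibitors",
                "warfarin", "cyp2c9-inhibitors",
                "Over-anticoagulation and bleeding",
                serious3, OrcaCategory.MINIMIZE_RISK,
                sub_strategy=MinimizeRiskStrategy.MONITOR,
            ),
        ),
        ExemplarEntry(
            slug="digoxin-cyclosporin",
            drug_1="Digoxin", drug_2="Cyclosporin",
            situations=("mechanism-known-pharmacokinetic",),
            artifact=_stub(
                "digoxin-cyclosporin", "Digoxin – cyclosporin",
                "digoxin", "cyclosporin",
                "Digoxin toxicity",
                serious3, OrcaCategory.MINIMIZE_RISK,
                sub_strategy=MinimizeRiskStrategy.MONITOR,
            ),
        ),
        ExemplarEntry(
            slug="epinephrine-beta-blockers",
            drug_1="Epinephrine", drug_2="Beta-blockers",
            situations=("mechanism-known-pharmacodynamic", "evidence-strong"),
            artifact=_stub(
                "epinephrine-beta-blockers", "Epinephrine – beta-blockers",
                "epinephrine", "beta-blockers",
                "Severe hypertension and reflex bradycardia",
                serious3, OrcaCategory.MINIMIZE_RISK,
                sub_strategy=MinimizeRiskStrategy.CIRCUMVENT,
            ),
        ),
        ExemplarEntry(
            slug="warfarin-ifosfamide-etoposide",
            drug_1="Warfarin", drug_2="Ifosfamide/Etoposide",
            situations=("mechanism-not-elucidated",),
            artifact=_stub(
                "warfarin-ifosfamide-etoposide",
                "Warfarin – ifosfamide/etoposide",
                "warfarin", "ifosfamide-etoposide",
                "Elevated INR and bleeding",
                serious3, OrcaCategory.MINIMIZE_RISK,
                sub_strategy=MinimizeRiskStrategy.MONITOR,
                mechanism=Mechanism(known=False, description=NOT_ELUCIDATED),
            ),
        ),
        ExemplarEntry(
            slug="statins-clarithromycin",
            drug_1="Simvastatin, atorvastatin, lovastatin",
            drug_2="Clarithromycin",
            situations=("evidence-strong",),
            artifact=_stub(
                "statins-clarithromycin", "CYP3A4 statins – clarithromycin",
                "statins-cyp3a4", "clarithromycin",
                "Rhabdomyolysis",
                serious3, OrcaCategory.USUALLY_AVOID,
            ),
        ),
        ExemplarEntry(
            slug="warfarin-uncertain-cyp2c9-antibiotics",
            drug_1="Warfarin",
            drug_2="Antibiotics with uncertain CYP2C9 inhibition",
            situations=("evidence-weak",),
            artifact=_stub(
                "warfarin-uncertain-cyp2c9-antibiotics",
                "Warfarin – antibiotics with uncertain CYP2C9 inhibition",
                "warfarin", "uncertain-cyp2c9-antibiotics",
                "Possible elevated INR",
                serious3, OrcaCategory.NO_SPECIAL_PRECAUTIONS,
            ),
        ),
        ExemplarEntry(
            slug="warfarin-nsaids",
            drug_1="Warfarin",
            drug_2="Non-steroidal anti-inflammatory drugs (NSAIDs)",
            situations=("frequency-of-exposure-available",),
            artifact=warfarin_nsaid_artifact(),
            full=True,
        ),
        ExemplarEntry(
            slug="simvastatin-fluconazole",
            drug_1="Simvastatin", drug_2="Fluconazole",
            situations=(
                "frequency-of-exposure-not-available",
                "frequency-of-harm-not-available",
            ),
            artifact=_stub(
                "simvastatin-fluconazole", "Simvastatin – fluconazole",
                "simvastatin", "fluconazole",
                "Myopathy and rhabdomyolysis",
                serious3, OrcaCategory.MINIMIZE_RISK,
                sub_strategy=MinimizeRiskStrategy.CONSIDER_ALTERNATIVES,
            ),
        ),
        ExemplarEntry(
            slug="spironolactone-potassium-supplements",
            drug_1="Spironolactone", drug_2="Potassium supplements",
            situations=("frequency-of-harm-available", "merged-entry"),
            artifact=_stub(
                "spironolactone-potassium-supplements",
                "Spironolactone – potassium supplements",
                "potassium-sparing-diuretics", "potassium-supplements",
                "Hyperkalemia",
                serious3, OrcaCategory.MINIMIZE_RISK,
                sub_strategy=MinimizeRiskStrategy.MONITOR,
                frequency_harm=Frequency(
                    kind=FrequencyKind.PROPORTION, value=0.1,
                    description="Illustrative harm frequency stub.",
                ),
            ),
        ),
        ExemplarEntry(
            slug="simvastatin-amiodarone",
            drug_1="Simvastatin", drug_2="Amiodarone",
            situations=("recommended-action-clear-alternative",),
            artifact=_stub(
                "simvastatin-amiodarone", "Simvastatin – amiodarone",
                "simvastatin", "amiodarone",
                "Rhabdomyolysis",
                serious3, OrcaCategory.MINIMIZE_RISK,
                sub_strategy=MinimizeRiskStrategy.CONSIDER_ALTERNATIVES,
                action=RecommendedAction(
                    action_text="Switch to an alternative statin (e.g. "
                                "pravastatin) or cap the simvastatin dose.",
                    action_category=ActionCategory.ASSESS_RISK_AND_TAKE_ACTION,
                    evidence_refs=("ev-1",),
                ),
            ),
        ),
    ]
    assert len(entries) == 14
    return entries


# ---------------------------------------------------------------------------
# Synthetic patient contexts
# ---------------------------------------------------------------------------

#: Medications that take part in no demo interaction (sampling noise).
_DISTRACTOR_MEDS = ["acetaminophen", "metformin", "lisinopril", "levothyroxine",
                    "sertraline", "albuterol"]
_DISTRACTOR_CONDS = ["hypertension", "type-2-diabetes", "asthma",
                     "osteoarthritis"]


def _med_pool(registry: ValueSetRegistry) -> list[str]:
    pool: list[str] = []
    for vs_id in registry.ids():
        for m in registry.get(vs_id):
            if m.system == RX and m.code not in pool:
                pool.append(m.code)
    pool.extend(c for c in _DISTRACTOR_MEDS if c not in pool)
    return pool


def _cond_pool(registry: ValueSetRegistry) -> list[str]:
    pool: list[str] = []
    for vs_id in registry.ids():
        for m in registry.get(vs_id):
            if m.system == COND and m.code not in pool:
                pool.append(m.code)
    pool.extend(c for c in _DISTRACTOR_CONDS if c not in pool)
    return pool


def generate_contexts(
    seed: int, n: int, registry: ValueSetRegistry | None = None
) -> list[PatientContext]:
    """Seeded synthetic patient contexts for exercising the fixture trees.

    Each context samples 1–6 medications from the demo drug pool (all
    registered demo drugs plus distractor codes), 0–3 conditions, and 0–2
    INR observations (values spanning the sub- and supra-therapeutic
    range, 0.8–6.0).  Diclofenac draws a topical route about a third of
    the time, so route-discriminating questions get exercised.  The same
    seed always yields the identical list (stdlib Mersenne Twister).

    Raises
    ------
    ValueError
        If ``n < 1``.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    registry = registry or demo_registry()
    rng = random.Random(seed)
    meds_pool = _med_pool(registry)
    conds_pool = _cond_pool(registry)

    contexts: list[PatientContext] = []
    for _ in range(n):
        n_meds = rng.randint(1, 6)
        med_codes = rng.sample(meds_pool, min(n_meds, len(meds_pool)))
        meds = []
        for code in med_codes:
            route = "oral"
            if code == "diclofenac" and rng.random() < 0.35:
                route = "topical"
            elif rng.random() < 0.05:
                route = rng.choice(["iv", "subcutaneous"])
            meds.append(MedicationRecord(concept=rx(code), route=route))
        n_conds = rng.randint(0, 3)
        conds = tuple(
            cond(c) for c in rng.sample(conds_pool, min(n_conds, len(conds_pool)))
        )
        n_obs = rng.randint(0, 2)
        obs = []
        if n_obs >= 1:
            obs.append(
                ObservationRecord(
                    concept=INR,
                    value=round(rng.uniform(0.8, 6.0), 2),
                    unit="ratio",
                )
            )
        if n_obs >= 2:
            obs.append(
                ObservationRecord(
                    concept=CodedConcept(OBS, "serum-potassium", "Serum potassium"),
                    value=round(rng.uniform(3.0, 6.5), 2),
                    unit="mmol/L",
                )
            )
        contexts.append(
            PatientContext(
                medications=tuple(meds),
                conditions=conds,
                observations=tuple(obs),
            )
        )
    return contexts


# ---------------------------------------------------------------------------
# Randomized artifacts (for round-trip / property testing)
# ---------------------------------------------------------------------------


def generate_artifacts(seed: int, n: int) -> list[PDDIArtifact]:
    """Seeded random-but-valid artifacts spanning the model's surface.

    Used to exercise serialization round-trips and validator purity beyond
    the curated fixtures: random slot counts, random frequency kinds
    (including honest *unknown*), adopter extension keys, optional trees.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    rng = random.Random(seed)
    vs_ids = [vs.id for vs in demo_value_sets()]
    artifacts: list[PDDIArtifact] = []
    for i in range(n):
        n_ev = rng.randint(1, 4)
        evidence = tuple(
            EvidenceItem(
                id=f"ev-{j}",
                stance=rng.choice(["supports", "refutes"]),
                type=rng.choice([t.value for t in EvidenceType]),
                citation=f"Synthetic citation {j} for artifact {i}",
            )
            for j in range(n_ev)
        )
        ev_ids = [e.id for e in evidence]

        def some_refs() -> tuple[str, ...]:
            k = rng.randint(0, min(2, len(ev_ids)))
            return tuple(rng.sample(ev_ids, k))

        drugs = tuple(
            DrugInvolved(
                role=rng.choice(list(DrugRole)),
                value_set=ValueSetRef(rng.choice(vs_ids)),
                level=rng.choice(list(DrugLevel)),
            )
            for _ in range(rng.randint(2, 3))
        )
        consequences = tuple(
            ClinicalConsequence(
                description=f"Synthetic consequence {j}",
                concepts=(ValueSetRef(rng.choice(vs_ids)),) if rng.random() < 0.7 else (),
                seriousness=SeriousnessAssessment(
                    reasons=tuple(
                        rng.sample(list(SeriousnessReason), rng.randint(0, 2))
                    ),
                    rationale="synthetic rationale" if rng.random() < 0.8 else "",
                ),
            )
            for j in range(rng.randint(1, 2))
        )
        cat = rng.choice(list(OrcaCategory))
        classifications = (
            OperationalClassification(
                category=cat,
                statement=f"Synthetic statement ({cat.value})",
                sub_strategy=(
                    rng.choice(list(MinimizeRiskStrategy))
                    if cat is OrcaCategory.MINIMIZE_RISK and rng.random() < 0.5
                    else None
                ),
                evidence_refs=some_refs(),
            ),
        )
        freq_choices = [
            Frequency(kind=FrequencyKind.UNKNOWN),
            Frequency(kind=FrequencyKind.PROPORTION,
                      value=round(rng.random(), 3)),
            Frequency(kind=FrequencyKind.RELATIVE_RISK,
                      low=round(rng.uniform(1, 3), 2),
                      high=round(rng.uniform(3, 6), 2)),
            None,
        ]
        extensions = (
            (("x-synthetic-tag", f"tag-{i}"),) if rng.random() < 0.5 else ()
        )
        artifacts.append(
            PDDIArtifact(
                id=f"synthetic-{i}",
                title=f"Synthetic artifact {i}",
                drugs=drugs,
                consequences=consequences,
                classifications=classifications,
                actions=(
                    RecommendedAction(
                        action_text=f"Synthetic action for artifact {i}",
                        action_category=rng.choice(list(ActionCategory)),
                        evidence_refs=some_refs(),
                    ),
                ) if rng.random() < 0.8 else (),
                mechanism=(
                    Mechanism(known=True, description="Synthetic mechanism.")
                    if rng.random() < 0.8
                    else Mechanism(known=False)
                ),
                contextual_factors=(
                    ContextualFactor(
                        kind=rng.choice(list(ContextualFactorKind)),
                        description="Synthetic contextual factor",
                        concepts=(ValueSetRef(rng.choice(vs_ids)),),
                    ),
                ),
                evidence=evidence,
                frequency_exposure=rng.choice(freq_choices),
                frequency_harm=rng.choice(freq_choices),
                extensions=extensions,
            )
        )
    return artifacts
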