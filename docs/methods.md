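# Methods

This note documents the modelling decisions behind pddikit: what the
minimal information model assumes, how the validator rules were
operationalized, how decision-tree evaluation handles missing data, what
the synthetic generators emulate (and what they do not), and the known
limitations.

## The information model

A PDDI knowledge artifact carries ten information items. Seven are
required — drugs involved, clinical consequences, seriousness (nested per
consequence), operational classification, mechanism, contextual factors,
evidence — and three are recommended: recommended action, frequency of
exposure, frequency of harm. The counts of 10 and 7 are fixed by the
schema registry (`pddikit.model.information_items`) and are load-bearing:
the validator's required-element rules are generated against them.

Two deliberate modelling positions:

* **Seriousness, not severity.** An outcome is serious iff at least one
  pharmacovigilance criterion applies (death, life-threatening
  hospitalization, congenital anomaly, disability, permanent impairment).
  The boolean is *derived* from the reason set — it cannot be asserted
  independently — which makes the monotonicity property (adding reasons
  never de-serializes an outcome) structural. Severity scales are out of
  scope by design; the operational classification fills that role at the
  point of care.
* **Mechanism is required, but ignorance is an acceptable value.** An
  artifact whose mechanism is genuinely unestablished satisfies the
  required-element rule with `known=False` and the marker text
  `"not well elucidated"`. The requirement is that the artifact *say
  something* about mechanism, including an honest "nobody knows".

### Frequencies

`Frequency` has three kinds: a proportion in [0, 1], a relative-risk range
(0 < low ≤ high), and *unknown*. Unknown is a first-class value, distinct
from an absent slot: "unknown" asserts that no population data exist,
which is itself useful evidence-gap information, while an absent slot just
means the curator didn't fill it in (and draws a best-practice warning).

The free-text parser recognizes three dialects — `"24.3%"` → proportion
0.243; `"2.9–3.3"` (en-dash or hyphen, possibly embedded in a sentence) →
relative-risk range; `"unknown"` (case-insensitive) → unknown — and
*preserves* anything else verbatim with `parsed=False` rather than
rejecting it, since free text is an accepted last resort in this domain.
Percentages above 100 are rejected as range errors. The percentage
dialect is checked before the range dialect, so "24.3%" can never be
misread as a degenerate range.

### The ORCA order

The five management categories form a total restrictiveness order,
`IGNORE=0 < NO_SPECIAL_PRECAUTIONS=1 < MINIMIZE_RISK=2 < USUALLY_AVOID=3 <
AVOID=4`, taken from the category list's most-to-least-restrictive
ordering. `merge_classifications` is the join of this chain (maximum by
rank): commutative, associative, idempotent. The three Minimize-Risk
sub-strategies (consider alternatives, circumvent, monitor) are modelled
as qualifiers valid only under `MINIMIZE_RISK`, reading the indentation of
the published category list as nesting.

### Drug slots and free text

The model wants drugs referenced through coded concepts or value sets. A
`DrugInvolved` slot therefore carries exactly one of: a coded concept, a
value-set reference, or — as a last resort — free text. The free-text arm
exists so that the corresponding best-practice rule (BP-1) has something
to warn about; without it, "drugs must be coded" would be enforced by the
type system and the rule would be dead code. Free-text slots are also
invisible to the screening gate (`applies`), which is the practical cost
the warning points at.

## Validator rules

Required-element violations are **errors**; best-practice violations are
**warnings** — they are recommendations, not conformance requirements, and
the `valid` flag ignores them. The eight best-practice rules (BP-1…BP-8:
coded drugs, coded consequences, justified seriousness, a declared
classification category, evidence-linked actions, explicit mechanism,
coded contextual factors, frequencies populated-or-unknown) are **this
package's reconstruction** from the model's element definitions; the
normative list lives in the published community report, which this
package does not vendor. Each rule descriptor embeds its rationale so
reports are self-documenting.

Validation is pure (no exceptions for bad content, identical reports on
repeated runs) and issues are stable-ordered by information-item slot,
then rule id, then path — so single-fault reports are deterministic and
diffable. The artifact dataclass is intentionally permissive (slots may
be empty) so the validator can *diagnose* non-conformance; the
`new_artifact` constructor enforces only the hard invariants that make an
artifact meaningless if broken: ≥ 2 drug slots, unique evidence ids,
resolvable evidence references.

## Decision-tree evaluation

Questions come in four kinds: medication-in-value-set,
condition-in-value-set, medication-route, and observation-comparison
(comparator ∈ {<, ≤, >, ≥} against a threshold with an exact-match unit).

**Membership questions treat absence as "no".** Medication and problem
lists are assumed complete — this mirrors order-entry screening, where the
list in front of the system *is* the patient's list. Only observation
questions can be *unknown* (the lab was never drawn). This asymmetry is
the central simplification of the engine and is stated prominently here
because it is wrong exactly when the medication list is incomplete —
medication reconciliation, the one workflow where that assumption fails,
should use the `abstain` policy and human review.

Unknown-answer policies:

* `strict`: raise, naming the unanswerable question.
* `conservative`: explore both subtrees and return the outcome with the
  maximal ORCA restrictiveness rank; ties break toward the yes-branch
  (deterministic and audit-friendly). Because the maximum over a tree is
  the maximum over its leaves, this provably equals
  `merge_classifications` over the brute-force enumeration of all 2^k
  completions of k unknown answers — the property the test suite and the
  acceptance script check empirically against `reachable_outcomes`.
* `abstain`: return the frozenset of all reachable leaf outcomes.

`reachable_outcomes` guards exhaustive completion at 20 distinct unknown
questions (2^20 paths); fixture trees have at most one observation
question, so the guard is a safety net for adopter-authored trees, not a
practical limit here.

The screening gate `applies` returns true iff the patient's medications
match at least two distinct drug slots of the artifact — co-exposure to
both sides of the interaction. For the shipped two-slot artifacts this is
"both slots matched".

## Serialization

The interchange dialect is JSON with camel-case keys in a fixed order
(diff-ability; FHIR-adjacent audiences expect the style), twelve fixed
top-level keys plus optional `decisionTree` and `valueSets`. Unknown
frequencies serialize as `{"kind": "unknown"}` and are never omitted.
Unknown top-level keys survive parsing in an extensions bag and are
re-emitted after the fixed keys in their original order, so adopter
extensions round-trip. `from_document(to_document(a)) == a` structurally,
and re-serialization is byte-identical — both properties are tested on
all fixtures and on randomized artifacts. Inline value sets make a
document self-contained; on parse they overwrite registry entries of the
same id (the document is authoritative for its own sets).

## Fixtures and synthetic data

The warfarin–NSAID and TKI–PPI artifacts are full reconstructions of the
two published worked examples: their drugs, consequences, seriousness
rationale, classifications (Minimize-Risk/consider-alternatives;
per-TKI branching), mechanisms, contextual factors, frequencies (24.3%
exposure and relative risk 2.9–3.3 for warfarin–NSAID; both *unknown* for
TKI–PPI) and evidence linkage. Their decision-tree **branch structure
beyond the published branching is an authored reconstruction and is
non-normative** — in particular the warfarin tree's leaf assignments
(topical diclofenac → no special precautions; ulcer/UGIB history →
usually avoid; elevated INR or gastroprotection → minimize risk) are
consistent with the published contextual factors but not dictated by
them. The other twelve exemplar-registry entries are conformant stubs,
flagged "illustrative stub" in their titles; the registry's situation
tags record which curation challenge each pair was chosen to illustrate
(the pair → situation mapping is documented, not uniquely determined, for
pairs listed under several situations; the spironolactone–potassium entry
is counted once despite sharing a merged publication record).

All codes live in local `DEMO-RX` / `DEMO-COND` / `DEMO-OBS` systems with
readable names as codes. They are placeholders: real deployments
substitute RxNorm/ATC/SNOMED-CT value sets, and nothing in the library
assumes anything about code syntax (codes are opaque, case-sensitive
strings).

`generate_contexts(seed, n)` produces synthetic patients: 1–6 medications
sampled from the demo drug pool plus distractors, 0–3 conditions, 0–2
observations (INR 0.8–6.0, spanning sub- to supra-therapeutic; serum
potassium as a second, unused-by-fixtures observation), diclofenac drawn
topical ~35% of the time so route questions get exercised. The PRNG is
the stdlib Mersenne Twister (`random.Random(seed)`), stable across
platforms; the same seed always reproduces the same list.
`generate_artifacts(seed, n)` similarly produces random-but-valid
artifacts spanning the serializer's surface (all frequency kinds,
optional slots, extension keys).

What the generators do **not** emulate: real prescribing correlations
(drug co-occurrence is uniform), dosing, temporal overlap of courses,
free-text medication entries, or incomplete medication lists. Passing the
coverage and oracle tests therefore shows the *engine logic* is sound on
its input contract, not that real EHR data will satisfy that contract.

Problem sizes in the tests and acceptance script — 200–1000 synthetic
contexts, 100 randomized artifacts, the exhaustive 31-subset check of the
ORCA join — were chosen as the smallest sizes that exercise every branch
and leaf with margin; everything runs in seconds.

## Known limitations

* No terminology-server integration: value sets are extensional only, no
  intensional (rule-defined) sets, no hierarchy-aware expansion, no code
  normalization.
* No OWL/RDF emission and no HL7 FHIR / CDS Hooks / CQL conformance; the
  JSON dialect here is self-defined, not the published note's (whose key
  names are not reproduced in the source material).
* Evidence is linkage-only: no quality grading (GRADE-style scales and
  causality scoring are adjacent work, deliberately excluded).
* The best-practice rule set is a reconstruction (see above); adopters
  tracking the normative report should review BP-1…BP-8 against it.
* The conservative policy's restrictiveness maximum is taken over *leaf
  classifications*; if an adopter authors a tree whose leaves carry
  classifications inconsistent with their action categories, the policy
  follows the classifications.
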