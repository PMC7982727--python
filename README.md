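# pddikit

Typed knowledge artifacts for **potential drug–drug interactions (PDDIs)**:
a minimal-information-model library for the people who curate drug-interaction
evidence (compendium editors, pharmacists, clinical-decision-support teams)
and for the tools that deliver it to clinicians.

Drug-interaction knowledge bases disagree wildly with one another, largely
because there is no shared model of *what a PDDI description must contain*.
pddikit implements a consensus minimal information model as executable
software:

* **Ten information items** per artifact — drugs involved, clinical
  consequences, seriousness, operational classification statement,
  recommended action, mechanism of interaction, contextual/modifying
  factors, evidence, frequency of exposure, frequency of harm — seven of
  them required.
* **Extensional value sets** (explicit lists of `system,code,display`
  entries) for drug classes and condition groups, with registration,
  membership, expansion and CSV/JSON I/O.
* **A conformance validator** — 7 required-element rules (errors) and 8
  best-practice rules (warnings), each self-documenting with its rationale.
* **Binary decision trees** evaluated against a patient context
  (medications with routes, conditions, observations), leading to one of
  three recommended actions: *no special precautions*, *assess risk and
  take action if necessary*, *use only if benefits outweigh the risk*.
  Missing observations are handled by an explicit policy: `strict` (fail),
  `conservative` (most restrictive reachable outcome, by the ORCA
  restrictiveness order), or `abstain` (return all reachable outcomes).
* **A lossless JSON interchange dialect** (fixed key order, adopter
  extensions preserved) and a clinician-facing Markdown narrative renderer.
* **Executable fixtures**: full reconstructions of the warfarin–NSAID and
  TKI–PPI worked examples, a 14-entry exemplar registry, and seeded
  synthetic patient/artifact generators.

The ORCA management vocabulary (OpeRational ClassificAtion of drug
interactions) is ordered by restrictiveness:

```
IGNORE (0) < NO_SPECIAL_PRECAUTIONS (1) < MINIMIZE_RISK (2)
           < USUALLY_AVOID (3) < AVOID (4)
```

with Minimize-Risk sub-strategies *consider alternatives*, *circumvent*,
*monitor*. A consequence is **serious** iff it may result in death,
life-threatening hospitalization, congenital anomaly, disability, or
permanent impairment — severity scales are deliberately out of scope.

## Worked example

```python
import json
from pddikit import fixtures, evaluate, validate
from pddikit.engine import PatientContext

registry = fixtures.demo_registry()
artifact = fixtures.tki_ppi_artifact()

print(validate(artifact, registry).valid)

patient = PatientContext.from_dict({
    "medications": [
        {"system": "DEMO-RX", "code": "nilotinib"},
        {"system": "DEMO-RX", "code": "omeprazole"},
    ]
})
outcome, trace = evaluate(artifact.decision_tree, patient, registry)
print(outcome.action_category.value)
print(trace.render())
```

prints

```
True
assess-risk-and-take-action
q-ppi: yes (medication 'omeprazole' in value set 'ppis')
  q-tki-ph-insensitive: no (no match in context)
    q-tki-nilotinib: yes (medication 'nilotinib' in value set 'nilotinib')
```

i.e. the artifact is conformant, and for a patient on nilotinib plus a
proton pump inhibitor the tree recommends *assess risk and take action if
necessary* (space an antacid/H2 antagonist 2 h after the TKI), having
answered three questions to get there. Swap in imatinib and the outcome
becomes *no special precautions*; with dasatinib it becomes *use only if
benefit outweighs risk* — the interaction genuinely does not apply at the
class level.

The same functionality is available from a shell:

```bash
pddi list                      # the 14 exemplar slugs
pddi validate tki-ppi          # exit 0 = conformant
pddi evaluate --artifact tki-ppi --context patient.json --policy conservative
pddi render warfarin-nsaids -o narrative.md
pddi expand nsaids             # value-set members, one per line
```

Exit codes: 0 success/valid, 1 validation errors or missing data, 2 usage
or format errors.

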