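# kips — Korean IPS data pipeline toolkit

Korea's national "My Health Record" platform exports personal health
records as FHIR R4 JSON built on the KR Core profiles.  The International
Patient Summary (IPS) — the minimal cross-border patient summary standard —
expects the same facts in a different shape: flat resources without
`contained` nesting, canonical code systems (SNOMED CT where Korean claims
data carries HIRA-EDI codes), stamped IPS profile URIs, populated mandatory
elements, and XHTML narratives.  `kips` is a deterministic, fully local
toolkit for that conversion, aimed at health-informatics engineers working
on Korean↔international interoperability:

- **Gap registry** — the seven IPS components (3 required / 4 recommended)
  and their profile mapping onto KR Core, as editable CSV data with
  computed coverage statistics.
- **Terminology** — total canonicalization of code-system labels
  (including the literal `"undefined"` seen in real exports) and
  exact-lookup ConceptMap tables (EDI→SNOMED CT, KCD→SNOMED CT excerpts).
- **Transform** — four rule-sets (Immunization, Medication,
  MedicationRequest, Procedure), shipped as YAML data, applied as
  idempotent projections with a complete, replayable action log.
- **Validate** — two tiers: FHIR R4 base structure, then IPS profile
  semantics, with a stable rule catalogue (`docs/rules.md`).
- **Synthetic** — a seedable generator of realistically messy source
  exports (3 subjects, six app files, one hospital bundle) so the whole
  pipeline is testable without personal data.
- **Pipeline / CLI** — `extract → transform → validate → load` writing
  per-type NDJSON stores; every stage also available as a `kips`
  subcommand.

## Worked example

One hospital procedure record, EDI-coded and missing its mandatory date,
through the procedure rule-set (`examples/worked_example.py`):

```python
from kips import TransformContext, transform_procedure, worked_example_procedure

source = worked_example_procedure()
report = transform_procedure(source, TransformContext(mode="strict"))
print("source coding:", source.get("code.coding.0"))
print("transformed coding:", report.output.get("code.coding.0"))
print("performedDateTime:", report.output.get("performedDateTime"))
```

prints

```
source coding: {'system': 'https://hira.or.kr/CodeSystem/edi', 'code': 'R4519', 'display': 'Cesarean section'}
transformed coding: {'system': 'http://snomed.info/sct', 'code': '11466000', 'display': 'Cesarean section'}
performedDateTime: 2023-11-20
```

The local claim code was replaced by its SNOMED CT concept (11466000)
straight from the mapping table — never inferred — and the missing
`performedDateTime` was recovered from the record's own period.  The
report's action log shows every step (`code_mapped`, `flattened`,
`defaulted_element`, …), and the output passes both validation tiers.

The gap report (`examples/gap_analysis.py`, or `kips gap-report`) prints
the coverage of the IPS components by KR Core: 7 components, 6 mapped,
86% coverage, 7 IPS profiles mapped to 11 KR Core profiles, with
MedicationStatement and the three Medical-Devices profiles unmapped.

A full run over the default synthetic cohort (`examples/full_pipeline.py`,
or `kips generate` + `kips run`) transforms 9 of 12 extracted resources
into the four output types (3 Medication, 3 Immunization, 1
MedicationRequest, 2 Procedure), skips the three context resources, and
ends with `n_error = 0`.

## Layout

```
src/kips/            library modules (fhir_core, gap_registry, terminology,
                     transform, validate, synthetic, pipeline, cli)
src/kips/data/       registry CSVs, concept-map excerpts, rule-set YAMLs
examples/            narrative scripts, one per capability
docs/methods.md      model, assumptions, parameters, limitations
docs/rules.md        validation rule catalogue + pathology traceability
tests/               pytest suite (unit, property, end-to-end)
```
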