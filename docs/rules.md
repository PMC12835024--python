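# Validation rule catalogue

Every issue the validator can raise carries one of the stable rule ids
below.  "Anchored" rules codify behaviour the study design requires of a
conformant record; "added" rules are this package's own base-structure
checks needed for a self-contained local validator.

## Tier 1 — syntax (FHIR R4 base structure)

| rule id     | severity | origin   | check |
|-------------|----------|----------|-------|
| SYN-RES-001 | error    | anchored | `resourceType` present and in the registered resource set |
| SYN-REQ-001 | error    | added    | per-type required base elements present (Immunization: status, vaccineCode, patient, occurrenceDateTime; Procedure: status, subject; MedicationRequest: status, intent, subject; MedicationDispense: status; Encounter: status, class; Bundle: type) |
| SYN-VS-001  | error    | added    | `status` / `intent` values inside their R4 value sets |
| SYN-DT-001  | error    | added    | date / dateTime / instant elements match the FHIR R4 lexical forms |
| SYN-REF-001 | error    | added    | reference strings are `Type/id`, `#local`, or absolute URLs |
| SYN-REF-002 | error    | anchored | a reference element carries inline resource members (a full resource duplicated inside the reference — the redundant-nesting pathology) |

Referential integrity (whether a well-formed reference resolves to a
stored resource) is **deliberately not checked**, matching a create-style
server interaction where ids are server-assigned.

## Tier 2 — profile (IPS-level checks for the four output types)

| rule id      | severity | origin   | applies to | check |
|--------------|----------|----------|------------|-------|
| IPS-PROF-001 | error    | anchored | Immunization, MedicationRequest | `meta.profile` contains the expected IPS canonical URI |
| IPS-CONT-001 | error    | anchored | all four | `contained` is empty (nesting flattened away) |
| IPS-SYS-001  | error    | anchored | all four | every coding system resolves to a canonical URI (no `"undefined"`) |
| IPS-PROC-001 | error    | anchored | Procedure | `code.coding[0].system` is SNOMED CT |
| IPS-PROC-002 | error    | anchored | Procedure | `performedDateTime` populated |
| IPS-MREQ-001 | error    | anchored | MedicationRequest | medication expressed as `medicationCodeableConcept`, never a reference |
| IPS-MED-001  | error    | anchored | Medication | `text.div` present, well-formed XHTML with content |
| IPS-IMM-001  | error    | anchored | Immunization | `meta.versionId`/`lastUpdated` absent; `meta.source` a real URI, not a tag-like string |

The Medication rule-set stamps no profile URI (its prompt transcription
defines structural and narrative requirements instead), and the Procedure
rule-set's metadata policy keeps only versionId/lastUpdated/source — so
IPS-PROF-001 applies only to the two types whose rule-sets stamp a profile.

## Pathology ↔ rule traceability matrix

Each synthetic-data messiness knob, enabled alone, trips exactly the rule
below on the raw export, and the rule no longer fires after transformation
(except unmapped codes, which are surfaced, never invented):

| knob | raw-data rule tripped | after transformation |
|------|----------------------|----------------------|
| `p_undefined_system` | IPS-SYS-001 | repaired (system defaulted by code policy) |
| `p_redundant_nested` | SYN-REF-002 | repaired (reference flattened to `Type/id`) |
| `p_missing_performed_date` | IPS-PROC-002 | repaired (date from the resource's own period or the encounter context) |
| `p_unmapped_edi` | IPS-PROC-001 | **survives** by design: the local code is kept and flagged `code_unmapped` |

This matrix is asserted by the mutation tests in the suite.
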