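# Methods

## Problem and approach

Korean personal health records are exportable as FHIR R4 JSON through the
national "My Health Record" platform, whose profiles inherit from KR Core.
The International Patient Summary (IPS) asks for a different shape of the
same clinical facts: flat resources (no `contained` nesting), canonical
code systems (SNOMED CT for procedures, ATC for drugs), stamped IPS profile
URIs, populated mandatory elements, and human-readable narratives.  This
package implements that conversion as a deterministic, auditable pipeline:

1. **Gap registry** — the IPS component/profile inventory and its mapping
   onto KR Core, kept as CSV data with computed coverage statistics.
2. **Terminology** — total canonicalization of code-system labels and
   exact-lookup concept maps (HIRA-EDI→SNOMED CT, KCD→SNOMED CT).
3. **Transform** — four declarative rule-sets (Immunization, Medication,
   MedicationRequest, Procedure) applied as pure projections with a
   complete per-resource action log.
4. **Validate** — a two-tier local validator: base-structure syntax, then
   IPS profile semantics (rule catalogue in `rules.md`).
5. **Synthetic** — a seedable generator of realistically messy source
   exports, so every stage is testable without any real personal data.
6. **Pipeline/CLI** — extract → transform → validate → load orchestration
   writing per-type NDJSON stores.

## The transformation model

Each transformer is a *projection*: the output is rebuilt from an empty
tree by copying whitelisted elements and applying declared repairs, so
applying a transformer to its own output is the identity (`f∘f == f`).
Every mutation is logged as exactly one action (`retained`, `removed`,
`flattened`, `code_mapped`, `code_defaulted`, `defaulted_element`,
`narrative_generated`, `profile_stamped`, `source_set`,
`extracted_from_contained`, `code_unmapped`), and replaying a log against
its input reproduces the output byte-for-byte — the audit log is complete
by construction, not by convention.

Rule-set specifics worth knowing:

- **Immunization** keeps resourceType, id, status, vaccineCode,
  occurrenceDateTime, lotNumber, primarySource and protocolApplied (with
  targetDisease); stamps the IPS Immunization profile; sets `meta.source`
  to the platform URI; drops versionId/lastUpdated (server-assigned) and
  encounter/location/note; flattens patient and performer actors to
  `Type/id` references.
- **Medication** extracts the contained Medication from a
  MedicationDispense (Substance contained entries are dropped), rebuilds
  `ingredient` with an `itemCodeableConcept` and a strength ratio whose
  denominator unit is taken from the dose-form display (the most defensible
  reading of "denominator as form"; flagged in the report whenever it
  changes the source value), gives the identifier a proper URL system, and
  generates an XHTML narrative containing the drug name and strength/form.
  The extracted resource reuses the contained id; if absent, a
  deterministic content-hash id is assigned.
- **MedicationRequest** keeps the codeable concept as-is (never converted
  to a reference), stamps the IPS profile, flattens the subject, retains
  the dosage essentials (text, timing, route — SNOMED coding untouched —
  doseAndRate) and removes encounter, identifier, requester and
  reportedBoolean.  Its output `meta` carries only the profile stamp.
- **Procedure** keeps only resourceType, id, meta (reduced to versionId,
  lastUpdated, source), status, code and subject; uses `coding[0]` only
  (literal first element, no re-ranking); defaults a missing/unresolvable
  system to SNOMED CT; replaces EDI codes through the concept map —
  replacements come from the mapping table or not at all, an unmapped code
  is flagged and kept (lenient) or aborts (strict); mirrors `code.text`
  from the coding display; and ensures `performedDateTime` from, in order:
  the resource's own performed element, its performedPeriod start, the
  referenced Encounter's period start.  A date is never fabricated.

System repair: source exports label code systems with the literal string
`"undefined"`.  Canonicalization is total — every raw label maps to a
canonical URI or an UNKNOWN marker — and each rule-set's code policy names
the system used to repair UNKNOWN labels (ATC for vaccine and drug codes,
SNOMED CT for dose forms and procedures).  Codes themselves are never
altered except through the concept map.

## Two-tier validation

Tier 1 emulates a create-style server interaction: base-structure
conformity only, with referential integrity explicitly out of scope
(server-side ids would be re-assigned anyway).  Tier 2 codifies the IPS
profile expectations for the four output types as a fixed local rule
catalogue (see `rules.md`) so validation is reproducible offline.  Base
violations and missing must-support elements are errors; unknown extra
elements warn.  The profile-URI rule applies to Immunization and
MedicationRequest only, because the Medication and Procedure rule-sets by
design do not stamp a profile (the Procedure metadata policy keeps only
versionId/lastUpdated/source).

## Synthetic study conditions

The generator reproduces the study's data situation: **3 subjects**, each
with one medication-record export (MedicationDispense with contained
Patient/Organization/Medication) and one immunization export — six app
files — plus **one** hospital "Medical MyData" collection bundle
(Patient, Organization, Encounter, MedicationRequest, EDI-coded
Procedures) for the single subject with retrievable hospital records.
Default messiness reflects the documented pathologies: undefined system
labels and redundant inline nesting always on (`p=1.0`), procedures
missing `performedDateTime` half the time (`p=0.5`; the study notes the
element had to be populated, without quantifying how often), unmapped EDI
codes off by default (`p=0.0`; the packaged excerpt covers the generated
pool by construction, and the knob exists to study the failure mode).

Code pools are small, clinically plausible sets (ATC drug and vaccine
codes, SNOMED dose forms and target diseases, EDI procedure codes drawn
from the packaged mapping excerpt).  The concept-map CSVs are
**synthetic-representative excerpts**, not copies of the published HIRA
(≈11k rows) or HINS (≈14k rows) tables; the worked-example row pairs a
placeholder EDI code (`R4519`) with its documented SNOMED CT target
11466000, because the source claim code behind that published example is
not public.  What passing tests show is therefore that the *pipeline
machinery* is correct under the documented pathologies — not that the
excerpt's clinical pairings generalize, nor that real exports contain no
pathology this generator does not model (e.g. free-text dosing quirks,
encoding issues, multi-day longitudinal records).

Determinism: one seed, subject-indexed substreams (`seed:subject:i:stream`),
so adding subjects never perturbs earlier subjects' bytes; manifests carry
SHA-256 hashes and equal configs produce byte-identical trees.

## Numerical and formatting choices

- Coverage percentage: round-half-away-from-zero to integer percent
  (6/7 → 86).
- JSON serialization: known elements in R4 definition order, unknown
  elements preserved in input order; decimals parsed as `Decimal` and
  re-emitted from their own text (no float re-rendering); NDJSON uses the
  same ordering, compact separators.
- Dotted paths address lists by zero-based index (`code.coding.0.system`).
- Dedup key for redundant source resources: (resourceType, id, content
  hash); first occurrence wins.
- Canonical URIs: SNOMED `http://snomed.info/sct`, LOINC
  `http://loinc.org`, ATC `http://www.whocc.no/atc`, KCD
  `http://hl7.org/fhir/sid/icd-10-kr`, and `https://hira.or.kr/CodeSystem/edi`
  as this package's identifier for HIRA-EDI (no official URI exists); all
  overridable through the alias table.
- Registered resource set: the twelve types the pipeline handles plus
  Substance and Practitioner, which occur only as contained resources in
  source exports.

## Known limitations

- Only the four validated rule-sets transform data; AllergyIntolerance,
  Condition, DiagnosticReport, Device and MedicationStatement appear in
  the gap registry only.
- Profile-level mapping, not element-level; no StructureDefinition or
  FHIRPath constraint engine, and no terminology-server binding checks.
- The KR Core profile count is carried as computed from the enumerated
  registry (eleven named profiles); summary prose elsewhere sometimes
  says ten — the registry follows the enumeration.
- The problem sizes used throughout (3-subject cohorts, excerpt-sized
  concept maps) are the package's study conditions; scaling to full
  mapping tables is a data swap, not a code change.
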