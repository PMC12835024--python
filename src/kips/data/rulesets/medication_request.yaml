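# MedicationRequest rule-set: keep the codeable concept (never a reference),
# flatten the subject, strip encounter/identifier/requester/reportedBoolean.
name: medication_request
input_resource_types: [MedicationRequest]
output_resource_type: MedicationRequest
ips_profile_uri: "http://hl7.org/fhir/uv/ips/StructureDefinition/MedicationRequest-uv-ips"
retain_paths: [resourceType, id, status, intent, authoredOn, medicationCodeableConcept]
remove_paths: [encounter, identifier, requester, reportedBoolean, contained]
flatten_reference_paths:
  - {path: subject, target_type: Patient}
meta_policy:
  stamp_profile: true
  drop_version_and_updated: true
  source_uri: null
code_policy:
  code_paths: []
  first_coding_only: false
  default_system: null
  map_via: null
  text_from_code: false
dosage_instruction_keys: [text, timing, route, doseAndRate]
narrative_policy: {required: false, template_id: null}
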