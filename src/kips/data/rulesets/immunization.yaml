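# Immunization rule-set: IPS-conformant immunization record.
name: immunization
input_resource_types: [Immunization]
output_resource_type: Immunization
ips_profile_uri: "http://hl7.org/fhir/uv/ips/StructureDefinition/Immunization-uv-ips"
retain_paths: [resourceType, id, status, occurrenceDateTime, lotNumber, primarySource, protocolApplied]
remove_paths: [encounter, location, note, contained]
flatten_reference_paths:
  - {path: patient, target_type: Patient}
meta_policy:
  stamp_profile: true
  drop_version_and_updated: true
  source_uri: "https://myhealthway.go.kr"
code_policy:
  code_paths: [vaccineCode]
  first_coding_only: false
  default_system: "http://www.whocc.no/atc"
  map_via: null
  text_from_code: false
narrative_policy: {required: false, template_id: null}
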