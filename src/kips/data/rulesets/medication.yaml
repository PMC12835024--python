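# Medication rule-set: extract the Medication from a dispense record and
# rebuild ingredient / form / narrative.
name: medication
input_resource_types: [MedicationDispense, Medication]
output_resource_type: Medication
ips_profile_uri: null
retain_paths: [resourceType, id, status]
remove_paths: [contained]
flatten_reference_paths: []
meta_policy:
  stamp_profile: false
  drop_version_and_updated: true
  source_uri: null
code_policy:
  code_paths: [code]
  first_coding_only: false
  default_system: "http://www.whocc.no/atc"
  map_via: null
  text_from_code: false
form_default_system: "http://snomed.info/sct"
identifier_default_system: "https://myhealthway.go.kr/identifier"
narrative_policy: {required: true, template_id: medication-summary}
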