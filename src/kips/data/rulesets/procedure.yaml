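# Procedure rule-set: whitelist projection, first coding only, EDI code
# replaced through the concept map, meta reduced to versionId/lastUpdated/source.
name: procedure
input_resource_types: [Procedure]
output_resource_type: Procedure
ips_profile_uri: null
retain_paths: [resourceType, id, status]
remove_paths: [encounter, performer, location, note, contained]
flatten_reference_paths:
  - {path: subject, target_type: Patient}
meta_policy:
  stamp_profile: false
  drop_version_and_updated: false
  source_uri: null
meta_keep: [versionId, lastUpdated, source]
code_policy:
  code_paths: [code]
  first_coding_only: true
  default_system: "http://snomed.info/sct"
  map_via: edi_snomed
  text_from_code: true
narrative_policy: {required: false, template_id: null}
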