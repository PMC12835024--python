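source_system,source_code,target_system,target_code,target_display,equivalence
http://hl7.org/fhir/sid/icd-10-kr,E11.9,http://snomed.info/sct,44054006,Type 2 diabetes mellitus,equal
http://hl7.org/fhir/sid/icd-10-kr,I10,http://snomed.info/sct,38341003,Essential hypertension,equal
http://hl7.org/fhir/sid/icd-10-kr,J45.9,http://snomed.info/sct,195967001,Asthma,equal
http://hl7.org/fhir/sid/icd-10-kr,K35.8,http://snomed.info/sct,74400008,Acute appendicitis,equal
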