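ips_profile,ips_system,kr_system
Procedure (IPS),http://snomed.info/sct,https://hira.or.kr/CodeSystem/edi
DiagnosticReport (IPS),http://loinc.org,https://hira.or.kr/CodeSystem/edi
Condition (IPS),http://snomed.info/sct,http://hl7.org/fhir/sid/icd-10-kr
AllergyIntolerance (IPS),http://www.whocc.no/atc,http://www.whocc.no/atc
Medication (IPS),http://www.whocc.no/atc,http://www.whocc.no/atc
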