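raw,canonical
http://snomed.info/sct,http://snomed.info/sct
snomed,http://snomed.info/sct
snomed ct,http://snomed.info/sct
snomed-ct,http://snomed.info/sct
sct,http://snomed.info/sct
http://loinc.org,http://loinc.org
loinc,http://loinc.org
http://www.whocc.no/atc,http://www.whocc.no/atc
atc,http://www.whocc.no/atc
who atc,http://www.whocc.no/atc
http://hl7.org/fhir/sid/icd-10-kr,http://hl7.org/fhir/sid/icd-10-kr
kcd,http://hl7.org/fhir/sid/icd-10-kr
kcd7,http://hl7.org/fhir/sid/icd-10-kr
kcd-7,http://hl7.org/fhir/sid/icd-10-kr
https://hira.or.kr/CodeSystem/edi,https://hira.or.kr/CodeSystem/edi
edi,https://hira.or.kr/CodeSystem/edi
hira-edi,https://hira.or.kr/CodeSystem/edi
http://www.hira.or.kr/CodeSystem/edi,https://hira.or.kr/CodeSystem/edi
http://unitsofmeasure.org,http://unitsofmeasure.org
ucum,http://unitsofmeasure.org
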