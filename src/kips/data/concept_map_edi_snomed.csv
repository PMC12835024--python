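source_system,source_code,target_system,target_code,target_display,equivalence
https://hira.or.kr/CodeSystem/edi,R4519,http://snomed.info/sct,11466000,Cesarean section,equal
https://hira.or.kr/CodeSystem/edi,Q2861,http://snomed.info/sct,80146002,Appendectomy,equal
https://hira.or.kr/CodeSystem/edi,Q7380,http://snomed.info/sct,38102005,Cholecystectomy,equal
https://hira.or.kr/CodeSystem/edi,E7660,http://snomed.info/sct,73761001,Colonoscopy,equal
https://hira.or.kr/CodeSystem/edi,E7611,http://snomed.info/sct,386831001,Gastroscopy,equal
https://hira.or.kr/CodeSystem/edi,HA101,http://snomed.info/sct,399208008,Plain chest X-ray,equal
https://hira.or.kr/CodeSystem/edi,HE101,http://snomed.info/sct,40701008,Echocardiography,equal
https://hira.or.kr/CodeSystem/edi,MM151,http://snomed.info/sct,71651007,Mammography,wider
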