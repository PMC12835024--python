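ips_profile,kr_profile
AllergyIntolerance (IPS),KR Core AllergyIntolerance Profile
Medication (IPS),KR Core Medication Profile
MedicationRequest (IPS),KR Core MedicationRequest Profile
Condition (IPS),KR Core Condition Profile for Chief Complaint
Condition (IPS),KR Core Condition Profile for Encounter Diagnosis
MedicationStatement (IPS),
DiagnosticReport (IPS),KR Core DiagnosticReport for Diagnostic Imaging
DiagnosticReport (IPS),KR Core DiagnosticReport for Function Tests
DiagnosticReport (IPS),KR Core DiagnosticReport for Laboratory Results
DiagnosticReport (IPS),KR Core DiagnosticReport for Pathology Results
Procedure (IPS),KR Core Procedure Profile
Immunization (IPS),KR Core Immunization Profile
Device (IPS),
Device - performer or observer (IPS),
DeviceUseStatement (IPS),
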