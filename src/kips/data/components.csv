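component,tier,ips_profile
Allergies and Intolerances,required,AllergyIntolerance (IPS)
Medication Summary,required,Medication (IPS)
Medication Summary,required,MedicationRequest (IPS)
Medication Summary,required,MedicationStatement (IPS)
Problems,required,Condition (IPS)
Results,recommended,DiagnosticReport (IPS)
History of Procedures,recommended,Procedure (IPS)
Immunizations,recommended,Immunization (IPS)
Medical Devices,recommended,Device (IPS)
Medical Devices,recommended,Device - performer or observer (IPS)
Medical Devices,recommended,DeviceUseStatement (IPS)
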