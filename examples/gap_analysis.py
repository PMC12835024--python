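"""Coverage of the IPS components by the Korean national FHIR profiles.

Loads the packaged profile-mapping registry and prints the gap report:
how many of the seven IPS components (three required, four recommended)
are representable with KR Core profiles, and where the code systems on the
two sides disagree.
"""

from kips import code_system_delta, compute_gap_report, load_default_registry

registry = load_default_registry()
report = compute_gap_report(registry)
print(report.to_text())
print()
delta = code_system_delta(registry, "Procedure (IPS)")[0]
print(
    f"Procedure coding gap: IPS wants {delta.ips_system}, "
    f"Korean sources carry {delta.kr_system} -> a concept map is required."
)
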