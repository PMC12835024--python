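"""The worked terminology example: one hospital procedure, EDI-coded,
carried through the procedure rule-set with the packaged EDI→SNOMED CT
concept-map excerpt, then validated on both tiers.

The printed code 11466000 is the SNOMED CT concept replacing the local
claim code; performedDateTime is recovered from the procedure's own
period because the source record lacked the mandatory element.
"""

from kips import TransformContext, transform_procedure, worked_example_procedure
from kips.validate import validate_ips_profile, validate_syntax

source = worked_example_procedure()
print("source coding:", source.get("code.coding.0"))

report = transform_procedure(source, TransformContext(mode="strict"))
out = report.output
print("transformed coding:", out.get("code.coding.0"))
print("performedDateTime:", out.get("performedDateTime"))
print("syntax tier valid:", validate_syntax(out).valid)
print("profile tier valid:", validate_ips_profile(out).valid)
print("\naction log:")
for action in report.actions:
    print(f"  {action.kind:20s} {action.path:25s} {action.detail}")
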