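"""Generate the default synthetic source cohort and inspect its pathologies.

Three subjects, one medication-record export and one immunization export
each (six app files), plus one hospital bundle for the single subject with
retrievable hospital records.  With the default messiness, code systems are
labelled "undefined" and patient details are duplicated inline — the
defects the transformation step must repair.
"""

import tempfile
from pathlib import Path

from kips import CohortConfig, generate_cohort, parse_resource
from kips.validate import validate_set

with tempfile.TemporaryDirectory() as tmp:
    manifest = generate_cohort(CohortConfig(seed=1), tmp)
    for f in manifest.files:
        print(f"{f['path']:30s} {f['resource_type']:20s} sha256={f['sha256'][:12]}…")
    resources = [
        parse_resource((Path(tmp) / f["path"]).read_text()) for f in manifest.files
    ]
    summary = validate_set(resources)
    print(
        f"\nraw data: {summary.n_valid}/{len(summary.reports)} files valid, "
        f"{summary.n_error} rule violations before transformation"
    )
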