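"""Cohort generator: study-condition counts, seed determinism, and the
behaviour of each messiness knob."""

import random

import pytest

from kips.synthetic import (
    CLEAN,
    CohortConfig,
    Messiness,
    build_subject,
    generate_cohort,
    generate_medication_dispense,
    generate_snuh_bundle,
)
from kips.fhir_core import ResourceBundle
from kips.terminology import EDI, canonicalize_system
from kips.validate import validate_syntax


def test_default_cohort_shape(tmp_path):
    manifest = generate_cohort(CohortConfig(seed=3), tmp_path)
    app_files = [f for f in manifest.files if f["resource_type"] != "Bundle"]
    bundles = [f for f in manifest.files if f["resource_type"] == "Bundle"]
    assert len(app_files) == 6  # 3 subjects x (1 medication + 1 immunization)
    assert len(bundles) == 1  # hospital data retrievable for one subject only
    assert sorted({f["resource_type"] for f in app_files}) == ["Immunization", "MedicationDispense"]


def test_same_seed_same_bytes(tmp_path):
    m1 = generate_cohort(CohortConfig(seed=11), tmp_path / "a")
    m2 = generate_cohort(CohortConfig(seed=11), tmp_path / "b")
    assert [f["sha256"] for f in m1.files] == [f["sha256"] for f in m2.files]
    m3 = generate_cohort(CohortConfig(seed=12), tmp_path / "c")
    assert [f["sha256"] for f in m1.files] != [f["sha256"] for f in m3.files]


def test_adding_subjects_preserves_earlier_streams(tmp_path):
    m3 = generate_cohort(CohortConfig(seed=5, n_subjects=3), tmp_path / "n3")
    m5 = generate_cohort(CohortConfig(seed=5, n_subjects=5), tmp_path / "n5")
    first = {f["path"]: f["sha256"] for f in m3.files}
    later = {f["path"]: f["sha256"] for f in m5.files}
    assert all(later[p] == h for p, h in first.items())


def test_config_validation():
    with pytest.raises(ValueError):
        generate_cohort(CohortConfig(n_subjects=0), ".")
    with pytest.raises(ValueError):
        CohortConfig(messiness=Messiness(p_undefined_system=1.5)).validate()
    with pytest.raises(ValueError):
        CohortConfig(n_subjects=2, snuh_subject_index=5).validate()


def _dispense(messiness, seed=9):
    cfg = CohortConfig(seed=seed, messiness=messiness)
    subject = build_subject(cfg, 0)
    rng = random.Random(f"{seed}:subject:0:medication")
    return generate_medication_dispense(subject, rng, messiness)


def test_undefined_system_knob():
    messy = _dispense(Messiness(1.0, 0, 0, 0))
    assert messy.find_contained(
        messy.get("medicationReference.reference")
    ).get("code.coding.0.system") == "undefined"
    clean = _dispense(CLEAN)
    med = clean.find_contained(clean.get("medicationReference.reference"))
    assert canonicalize_system(med.get("code.coding.0.system")).uri != "UNKNOWN"


def test_redundant_nested_knob():
    messy = _dispense(Messiness(0, 1.0, 0, 0))
    assert messy.get("subject.resource.resourceType") == "Patient"
    assert not _dispense(CLEAN).has("subject.resource")


def test_clean_dispense_passes_syntax_with_no_issues():
    report = validate_syntax(_dispense(CLEAN))
    assert report.issues == []


def test_snuh_bundle_contents():
    cfg = CohortConfig(seed=9)
    subject = build_subject(cfg, 0)
    bundle = generate_snuh_bundle(subject, random.Random("x"), cfg.messiness)
    entries = ResourceBundle.from_resource(bundle).entries
    types = {e.resource_type for e in entries}
    assert {"MedicationRequest", "Procedure", "Patient", "Organization", "Encounter"} <= types
    for proc in (e for e in entries if e.resource_type == "Procedure"):
        assert canonicalize_system(proc.get("code.coding.0.system")).uri == EDI


def test_missing_performed_date_knob():
    cfg = CohortConfig(seed=9, messiness=Messiness(0, 0, 1.0, 0))
    subject = build_subject(cfg, 0)
    bundle = generate_snuh_bundle(subject, random.Random("x"), cfg.messiness)
    procs = [e for e in ResourceBundle.from_resource(bundle).entries if e.resource_type == "Procedure"]
    assert procs and all(not p.has("performedDateTime") for p in procs)


def test_unmapped_edi_knob_draws_outside_the_excerpt():
    from kips.terminology import load_default_edi_map

    cfg = CohortConfig(seed=9, messiness=Messiness(0, 0, 0, 1.0))
    subject = build_subject(cfg, 0)
    mapped = {e.source_code for e in load_default_edi_map().entries}
    assert all(code not in mapped for code, _, _ in subject.procedures)
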