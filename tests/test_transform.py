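"""The four rule-set transformers: per-rule behaviour from the prompt
transcriptions plus the projection/replay/no-invention properties."""

import pytest

from kips.errors import (
    ExtractionError,
    MappingError,
    MissingElementError,
    TransformTypeError,
)
from kips.fhir_core import parse_resource
from kips.synthetic import CohortConfig, Messiness
from kips.terminology import ATC, EDI, SNOMED, load_default_edi_map
from kips.transform import (
    IMMUNIZATION_IPS_PROFILE,
    MEDICATION_REQUEST_IPS_PROFILE,
    OUTPUT_RESOURCE_TYPES,
    TransformContext,
    load_ruleset,
    replay_actions,
    transform_all,
    transform_immunization,
    transform_medication,
    transform_medication_request,
    transform_procedure,
)

from conftest import cohort_resources


def _first(resources, rtype):
    return next(r for r in resources if r.resource_type == rtype)


def _bundle_entries(resources, rtype):
    from kips.fhir_core import ResourceBundle

    bundle = _first(resources, "Bundle")
    return [e for e in ResourceBundle.from_resource(bundle).entries if e.resource_type == rtype]


# -- immunization ----------------------------------------------------------


def test_immunization_profile_stamp_and_flattening(messy_cohort):
    imm = _first(messy_cohort, "Immunization")
    out = transform_immunization(imm).output
    assert out.meta["profile"] == [IMMUNIZATION_IPS_PROFILE]
    assert out.meta["source"] == "https://myhealthway.go.kr"
    assert "versionId" not in out.meta and "lastUpdated" not in out.meta
    assert out.get("patient.reference").startswith("Patient/")
    assert out.get("patient") == {"reference": out.get("patient.reference")}
    assert out.contained == []
    for removed in ("note", "encounter", "location"):
        assert not out.has(removed)


def test_immunization_preserves_clinical_content(messy_cohort):
    imm = _first(messy_cohort, "Immunization")
    out = transform_immunization(imm).output
    assert out.get("vaccineCode.coding.0.code") == imm.get("vaccineCode.coding.0.code")
    assert out.get("vaccineCode.coding.0.system") == ATC  # 'undefined' repaired
    assert out.get("occurrenceDateTime") == imm.get("occurrenceDateTime")
    assert out.get("lotNumber") == imm.get("lotNumber")
    assert out.get("protocolApplied") == imm.get("protocolApplied")
    assert out.get("performer.0.actor.reference").startswith("Organization/")


def test_immunization_rejects_wrong_type(messy_cohort):
    with pytest.raises(TransformTypeError):
        transform_immunization(_first(messy_cohort, "MedicationDispense"))


# -- medication ------------------------------------------------------------


def test_medication_extracted_from_dispense(messy_cohort):
    dispense = _first(messy_cohort, "MedicationDispense")
    report = transform_medication(dispense)
    out = report.output
    med = next(c for c in dispense.contained if c.resource_type == "Medication")
    assert out.resource_type == "Medication"
    assert out.id == med.id
    assert out.get("ingredient.0.itemCodeableConcept.coding.0.system") == ATC
    assert out.get("ingredient.0.strength.numerator") == {
        "value": med.get("ingredient.0.strength.numerator.value"),
        "unit": "mg",
    }
    # denominator unit mirrors the dose form
    assert out.get("ingredient.0.strength.denominator.unit") == out.get("form.text")
    assert out.get("form.coding.0.system") == SNOMED
    assert out.get("identifier.0.system").startswith("https://")
    assert out.contained == []


def test_medication_narrative_is_xhtml_with_drug_name(messy_cohort):
    from lxml import etree

    dispense = _first(messy_cohort, "MedicationDispense")
    out = transform_medication(dispense).output
    div = out.get("text.div")
    root = etree.fromstring(div.encode())
    name = dispense.find_contained(
        dispense.get("medicationReference.reference")
    ).get("code.text")
    assert name in "".join(root.itertext())


def test_medication_requires_extractable_medication():
    bare = parse_resource(
        '{"resourceType":"MedicationDispense","id":"d1","status":"completed",'
        '"contained":[{"resourceType":"Patient","id":"p1"}]}'
    )
    with pytest.raises(ExtractionError):
        transform_medication(bare)


def test_conformant_medication_is_fixed_point(messy_cohort):
    out = transform_medication(_first(messy_cohort, "MedicationDispense")).output
    again = transform_medication(out)
    assert again.output == out
    assert all(a.kind in ("retained", "removed") for a in again.actions)


# -- medication request ----------------------------------------------------


def test_medication_request_rules(messy_cohort):
    mr = _bundle_entries(messy_cohort, "MedicationRequest")[0]
    report = transform_medication_request(mr)
    out = report.output
    assert out.meta["profile"] == [MEDICATION_REQUEST_IPS_PROFILE]
    assert out.get("medicationCodeableConcept") == mr.get("medicationCodeableConcept")
    assert not out.has("medicationReference")
    assert out.get("subject") == {"reference": f"Patient/{mr.get('subject.reference').split('/')[1]}"}
    # route coding kept verbatim; non-essential dosage members dropped
    assert out.get("dosageInstruction.0.route") == mr.get("dosageInstruction.0.route")
    assert not out.has("dosageInstruction.0.site")
    for removed in ("encounter", "identifier", "requester", "reportedBoolean"):
        assert not out.has(removed)
        assert any(a.kind == "removed" and a.path.startswith(removed) for a in report.actions)


# -- procedure -------------------------------------------------------------


def test_procedure_maps_edi_to_snomed(worked_example):
    report = transform_procedure(worked_example)
    out = report.output
    assert out.get("code.coding.0.code") == "11466000"
    assert out.get("code.coding.0.system") == SNOMED
    assert out.get("code.text") == out.get("code.coding.0.display")
    assert set(out.meta) <= {"versionId", "lastUpdated", "source"}
    assert out.has("performedDateTime")
    assert any(a.kind == "code_mapped" for a in report.actions)


def test_procedure_defaults_missing_system_to_snomed():
    proc = parse_resource(
        '{"resourceType":"Procedure","id":"x","status":"completed",'
        '"code":{"coding":[{"code":"11466000","display":"Cesarean section"},'
        '{"system":"http://loinc.org","code":"zz"},{"code":"third"}]},'
        '"subject":{"reference":"Patient/p1"},"performedDateTime":"2024-01-01"}'
    )
    out = transform_procedure(proc).output
    assert len(out.get("code.coding")) == 1  # coding[0] only
    assert out.get("code.coding.0.system") == SNOMED
    assert out.get("code.coding.0.code") == "11466000"


def test_procedure_unmapped_edi_lenient_vs_strict():
    proc = parse_resource(
        '{"resourceType":"Procedure","id":"x","status":"completed",'
        f'"code":{{"coding":[{{"system":"{EDI}","code":"X9901"}}]}},'
        '"subject":{"reference":"Patient/p1"},"performedDateTime":"2024-01-01"}'
    )
    report = transform_procedure(proc, TransformContext(mode="lenient"))
    assert any(a.kind == "code_unmapped" for a in report.actions)
    assert report.output.get("code.coding.0.system") == EDI  # never invented
    with pytest.raises(MappingError, match="X9901"):
        transform_procedure(proc, TransformContext(mode="strict"))


def test_procedure_date_backfill_from_encounter_context():
    proc = parse_resource(
        '{"resourceType":"Procedure","id":"x","status":"completed",'
        f'"code":{{"coding":[{{"system":"{EDI}","code":"R4519"}}]}},'
        '"subject":{"reference":"Patient/p1"},"encounter":{"reference":"Encounter/e1"}}'
    )
    ctx = TransformContext(encounter_periods={"Encounter/e1": "2023-06-01"})
    report = transform_procedure(proc, ctx)
    assert report.output.get("performedDateTime") == "2023-06-01"
    assert any(a.kind == "defaulted_element" and a.path == "performedDateTime" for a in report.actions)
    with pytest.raises(MissingElementError):
        transform_procedure(proc, TransformContext(mode="strict"))


# -- routing and properties ------------------------------------------------


def test_transform_all_routes_and_skips(messy_cohort):
    reports = transform_all(messy_cohort)
    outputs = [r.output for r in reports if r.output is not None]
    assert {o.resource_type for o in outputs} == set(OUTPUT_RESOURCE_TYPES)
    skipped = [r for r in reports if r.output is None]
    assert all(r.actions and r.actions[0].kind == "skipped" for r in skipped)
    assert {r.input.resource_type for r in skipped} == {"Patient", "Organization", "Encounter"}


def test_transform_all_patients_only_yields_nothing():
    patients = [parse_resource('{"resourceType":"Patient","id":"p1"}')]
    reports = transform_all(patients)
    assert len(reports) == 1 and reports[0].output is None


def test_lenient_run_collects_single_unmapped_warning():
    cfg = CohortConfig(seed=7, messiness=Messiness(0, 0, 0, 1.0))
    reports = transform_all(cohort_resources(cfg))
    bad = [r for r in reports if any("unmapped EDI" in w for w in r.warnings)]
    good = [r for r in reports if r.output is not None and not r.warnings]
    assert bad and len(bad) + len(good) == sum(1 for r in reports if r.output is not None)


def test_all_transformers_are_projections(messy_cohort, clean_cohort):
    """f(f(x)) == f(x) for every transformable resource in both cohorts."""
    ctx = TransformContext()
    for cohort in (messy_cohort, clean_cohort):
        for report in transform_all(cohort, ctx):
            if report.output is None:
                continue
            second = transform_all([report.output], ctx)[0]
            assert second.output == report.output


def test_replay_reproduces_output(messy_cohort):
    from kips.fhir_core import ResourceBundle

    flat = []
    for r in messy_cohort:
        flat.extend(ResourceBundle.from_resource(r).entries if r.resource_type == "Bundle" else [r])
    ctx = TransformContext()
    for report in transform_all(messy_cohort, ctx):
        if report.output is not None:
            assert replay_actions(report.input, report.actions) == report.output


def test_outputs_have_empty_contained_and_no_invented_codes(messy_cohort):
    allowed = {e.target_code for e in load_default_edi_map().entries}
    for report in transform_all(messy_cohort):
        if report.output is None:
            continue
        assert report.output.tree.get("contained", []) == []
        input_codes = {c.get("code") for c in report.input.codings()}
        for coding in report.output.codings():
            assert coding.get("code") in input_codes | allowed


def test_rulesets_load_with_disjoint_retain_remove():
    for name in ("immunization", "medication", "medication_request", "procedure"):
        rs = load_ruleset(name)
        assert not set(rs.retain_paths) & set(rs.remove_paths)
        assert rs.output_resource_type in OUTPUT_RESOURCE_TYPES
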