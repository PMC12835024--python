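"""Two-tier validation: base-structure rules, IPS profile rules, and the
pathology↔rule traceability matrix (mutation testing of the messiness
knobs)."""

import pytest

from kips.errors import ValidationTypeError
from kips.fhir_core import ResourceBundle, parse_resource
from kips.transform import TransformContext, transform_all
from kips.validate import (
    validate_ips_profile,
    validate_resource,
    validate_set,
    validate_syntax,
)


def _flat(resources):
    out = []
    for r in resources:
        out.extend(ResourceBundle.from_resource(r).entries if r.resource_type == "Bundle" else [r])
    return out


def _transformed(resources):
    return [r.output for r in transform_all(resources, TransformContext()) if r.output]


# -- syntax tier -----------------------------------------------------------


def test_transformed_worked_example_is_valid_end_to_end(worked_example):
    out = _transformed([worked_example])[0]
    assert validate_syntax(out).valid
    assert validate_ips_profile(out).valid


def test_status_outside_value_set_is_error():
    imm = parse_resource(
        '{"resourceType":"Immunization","status":"done","vaccineCode":{"text":"x"},'
        '"patient":{"reference":"Patient/p1"},"occurrenceDateTime":"2024-01-01"}'
    )
    report = validate_syntax(imm)
    assert not report.valid
    assert any(i.rule_id == "SYN-VS-001" and i.path == "status" for i in report.issues)


def test_missing_required_element_is_error():
    proc = parse_resource('{"resourceType":"Procedure","status":"completed"}')
    assert "SYN-REQ-001" in validate_syntax(proc).rule_ids()


@pytest.mark.parametrize(
    "value,ok",
    [
        ("2024-01-01", True),
        ("2024-13-01", False),
        ("2024-01-01T10:30:00Z", True),
        ("2024-01-01T10:30", False),
        ("yesterday", False),
    ],
)
def test_datetime_lexical_rules(value, ok):
    proc = parse_resource(
        '{"resourceType":"Procedure","status":"completed",'
        f'"subject":{{"reference":"Patient/p1"}},"performedDateTime":"{value}"}}'
    )
    assert ("SYN-DT-001" in validate_syntax(proc).rule_ids()) != ok


def test_malformed_reference_is_error_but_dangling_target_is_not():
    proc = parse_resource(
        '{"resourceType":"Procedure","status":"completed",'
        '"subject":{"reference":"not a ref !!"}}'
    )
    assert "SYN-REF-001" in validate_syntax(proc).rule_ids()
    # referential integrity is out of scope: a well-formed reference to an
    # absent resource raises no issue
    dangling = parse_resource(
        '{"resourceType":"Procedure","status":"completed",'
        '"subject":{"reference":"Patient/nobody"},"performedDateTime":"2024-01-01"}'
    )
    assert validate_syntax(dangling).valid


# -- profile tier ----------------------------------------------------------


def test_profile_tier_rejects_unsupported_types():
    with pytest.raises(ValidationTypeError):
        validate_ips_profile(parse_resource('{"resourceType":"Patient","id":"p"}'))


def test_profile_tier_detects_injected_defects(worked_example):
    out = _transformed([worked_example])[0]

    broken = out.copy()
    broken.set("code.coding.0.system", "undefined")
    ids = validate_ips_profile(broken).rule_ids()
    assert {"IPS-SYS-001", "IPS-PROC-001"} <= ids

    broken = out.copy()
    broken.delete("performedDateTime")
    assert "IPS-PROC-002" in validate_ips_profile(broken).rule_ids()

    broken = out.copy()
    broken.tree["contained"] = [{"resourceType": "Patient", "id": "p"}]
    assert "IPS-CONT-001" in validate_ips_profile(broken).rule_ids()


def test_medication_narrative_rule(messy_cohort):
    med = next(o for o in _transformed(messy_cohort) if o.resource_type == "Medication")
    assert validate_ips_profile(med).valid
    broken = med.copy()
    broken.set("text.div", "<div>unclosed")
    assert "IPS-MED-001" in validate_ips_profile(broken).rule_ids()
    broken.delete("text")
    assert "IPS-MED-001" in validate_ips_profile(broken).rule_ids()


def test_immunization_meta_rules(messy_cohort):
    imm = next(o for o in _transformed(messy_cohort) if o.resource_type == "Immunization")
    broken = imm.copy()
    broken.set("meta.versionId", "9")
    assert "IPS-IMM-001" in validate_ips_profile(broken).rule_ids()
    broken = imm.copy()
    broken.set("meta.source", "#SystemGenerated")
    assert "IPS-IMM-001" in validate_ips_profile(broken).rule_ids()


def test_medication_request_reference_rule(messy_cohort):
    mr = next(o for o in _transformed(messy_cohort) if o.resource_type == "MedicationRequest")
    broken = mr.copy()
    broken.delete("medicationCodeableConcept")
    broken.set("medicationReference", {"reference": "Medication/m1"})
    assert "IPS-MREQ-001" in validate_ips_profile(broken).rule_ids()


# -- aggregation -----------------------------------------------------------


def test_validate_set_totals(messy_cohort):
    assert validate_set([]).to_dict()["n_resources"] == 0
    empty = validate_set([])
    assert (empty.n_valid, empty.n_error, empty.n_warning) == (0, 0, 0)
    summary = validate_set(_transformed(messy_cohort))
    assert summary.n_error == 0
    assert summary.n_valid == len(summary.reports)


def test_operation_outcome_export(worked_example):
    out = _transformed([worked_example])[0]
    broken = out.copy()
    broken.delete("performedDateTime")
    oo = validate_ips_profile(broken).to_operation_outcome()
    assert oo["resourceType"] == "OperationOutcome"
    assert any("IPS-PROC-002" in i["diagnostics"] for i in oo["issue"])


# -- pathology ↔ rule traceability matrix ----------------------------------

KNOB_RULES = {
    "p_undefined_system": "IPS-SYS-001",
    "p_redundant_nested": "SYN-REF-002",
    "p_missing_performed_date": "IPS-PROC-002",
    "p_unmapped_edi": "IPS-PROC-001",
}


@pytest.mark.parametrize("knob,rule_id", KNOB_RULES.items())
def test_each_knob_alone_trips_its_rule_on_raw_data(single_knob, knob, rule_id):
    raw = _flat(single_knob(knob))
    raw_ids = set()
    for r in raw:
        raw_ids |= validate_resource(r).rule_ids()
    assert rule_id in raw_ids


@pytest.mark.parametrize("knob,rule_id", KNOB_RULES.items())
def test_knob_pathologies_resolved_by_transformation(single_knob, knob, rule_id):
    """After transformation the pathology's rule no longer fires — except the
    unmapped-EDI code, which survives by design (no code invention)."""
    outputs = _transformed(single_knob(knob))
    post_ids = set()
    for o in outputs:
        post_ids |= validate_resource(o).rule_ids()
    if knob == "p_unmapped_edi":
        assert rule_id in post_ids
    else:
        assert rule_id not in post_ids


def test_transform_outputs_always_base_valid(messy_cohort, clean_cohort):
    for cohort in (messy_cohort, clean_cohort):
        for o in _transformed(cohort):
            assert validate_syntax(o).valid
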