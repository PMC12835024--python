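"""Two-tier local validation.

Tier 1 (``syntax``) checks conformity to the FHIR R4 base structure:
registered resourceType, required base elements, status codes within their
R4 value sets, date/dateTime/instant lexical forms, and well-formed
reference strings.  Referential integrity against a server-side store is
deliberately out of scope.

Tier 2 (``profile``) checks the IPS-level expectations for the four
transformed resource types: expected profile URIs, empty contained lists,
resolvable code systems (no 'undefined'), SNOMED-coded procedures with a
performedDateTime, medicationCodeableConcept rather than a reference, and a
well-formed XHTML medication narrative.

Every check has a stable ``rule_id`` documented in ``docs/rules.md``.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field

from lxml import etree

from .errors import ValidationTypeError
from .fhir_core import REGISTERED_RESOURCE_TYPES, FhirResource, classify_reference
from .terminology import SNOMED, UNKNOWN, canonicalize_system
from .transform import IMMUNIZATION_IPS_PROFILE, MEDICATION_REQUEST_IPS_PROFILE

# FHIR R4 primitive lexical forms.
_DATE_RE = re.compile(
    r"^([0-9]([0-9]([0-9][1-9]|[1-9]0)|[1-9]00)|[1-9]000)"
    r"(-(0[1-9]|1[0-2])(-(0[1-9]|[1-2][0-9]|3[0-1]))?)?$"
)
_DATETIME_RE = re.compile(
    r"^([0-9]([0-9]([0-9][1-9]|[1-9]0)|[1-9]00)|[1-9]000)"
    r"(-(0[1-9]|1[0-2])(-(0[1-9]|[1-2][0-9]|3[0-1])"
    r"(T([01][0-9]|2[0-3]):[0-5][0-9]:([0-5][0-9]|60)(\.[0-9]+)?"
    r"(Z|(\+|-)((0[0-9]|1[0-3]):[0-5][0-9]|14:00)))?)?)?$"
)
_INSTANT_RE = re.compile(
    r"^([0-9]{4})-(0[1-9]|1[0-2])-(0[1-9]|[1-2][0-9]|3[0-1])"
    r"T([01][0-9]|2[0-3]):[0-5][0-9]:([0-5][0-9]|60)(\.[0-9]+)?"
    r"(Z|(\+|-)((0[0-9]|1[0-3]):[0-5][0-9]|14:00))$"
)

#: element name → lexical category, scanned anywhere in the tree
_TEMPORAL_ELEMENTS = {
    "occurrenceDateTime": "dateTime",
    "performedDateTime": "dateTime",
    "authoredOn": "dateTime",
    "recorded": "dateTime",
    "whenPrepared": "dateTime",
    "whenHandedOver": "dateTime",
    "onsetDateTime": "dateTime",
    "recordedDate": "dateTime",
    "effectiveDateTime": "dateTime",
    "timestamp": "instant",
    "lastUpdated": "instant",
    "birthDate": "date",
    "expirationDate": "date",
    "start": "dateTime",
    "end": "dateTime",
}

_STATUS_VALUE_SETS = {
    "Immunization": {"completed", "entered-in-error", "not-done"},
    "Procedure": {
        "preparation", "in-progress", "not-done", "on-hold", "stopped",
        "completed", "entered-in-error", "unknown",
    },
    "MedicationRequest": {
        "active", "on-hold", "cancelled", "completed", "entered-in-error",
        "stopped", "draft", "unknown",
    },
    "MedicationDispense": {
        "preparation", "in-progress", "cancelled", "on-hold", "completed",
        "entered-in-error", "stopped", "declined", "unknown",
    },
    "Encounter": {
        "planned", "arrived", "triaged", "in-progress", "onleave",
        "finished", "cancelled", "entered-in-error", "unknown",
    },
    "Medication": {"active", "inactive", "entered-in-error"},
}

_REQUIRED_ELEMENTS = {
    "Immunization": ["status", "vaccineCode", "patient", "occurrenceDateTime"],
    "Procedure": ["status", "subject"],
    "MedicationRequest": ["status", "intent", "subject"],
    "MedicationDispense": ["status"],
    "Encounter": ["status", "class"],
    "Bundle": ["type"],
}

_REFERENCE_MEMBERS = {"reference", "type", "identifier", "display", "id", "extension"}

PROFILE_VALIDATABLE_TYPES = ("Medication", "MedicationRequest", "Immunization", "Procedure")


@dataclass
class ValidationIssue:
    severity: str  # error | warning | info
    tier: str  # syntax | profile
    path: str
    rule_id: str
    message: str

    def to_dict(self) -> dict:
        return {
            "severity": self.severity,
            "tier": self.tier,
            "path": self.path,
            "rule_id": self.rule_id,
            "message": self.message,
        }


@dataclass
class ValidationReport:
    resource_type: str
    resource_id: str
    issues: list[ValidationIssue] = field(default_factory=list)

    @property
    def valid(self) -> bool:
        return not any(i.severity == "error" for i in self.issues)

    def rule_ids(self) -> set[str]:
        return {i.rule_id for i in self.issues}

    def to_dict(self) -> dict:
        return {
            "resource_type": self.resource_type,
            "resource_id": self.resource_id,
            "valid": self.valid,
            "issues": [i.to_dict() for i in self.issues],
        }

    def to_operation_outcome(self) -> dict:
        """OperationOutcome-shaped JSON for interoperability with FHIR tooling."""
        issues = [
            {
                "severity": i.severity if i.severity != "warning" else "warning",
                "code": "invariant",
                "diagnostics": f"{i.rule_id}: {i.message}",
                "expression": [i.path],
            }
            for i in self.issues
        ] or [{"severity": "information", "code": "informational", "diagnostics": "no issues"}]
        return {"resourceType": "OperationOutcome", "issue": issues}


def _walk(node, path=""):
    if isinstance(node, dict):
        yield path or "(resource)", node
        for k, v in node.items():
            yield from _walk(v, f"{path}.{k}" if path else k)
    elif isinstance(node, list):
        for i, v in enumerate(node):
            yield from _walk(v, f"{path}.{i}")


def validate_syntax(resource: FhirResource) -> ValidationReport:
    """Tier 1: FHIR R4 base-structure conformity (no referential checks)."""
    report = ValidationReport(resource.resource_type, resource.id or "")
    issues = report.issues
    rt = resource.resource_type
    if rt not in REGISTERED_RESOURCE_TYPES:
        issues.append(
            ValidationIssue("error", "syntax", "resourceType", "SYN-RES-001", f"unregistered resourceType {rt!r}")
        )
        return report

    for elem in _REQUIRED_ELEMENTS.get(rt, []):
        if not resource.has(elem):
            issues.append(
                ValidationIssue("error", "syntax", elem, "SYN-REQ-001", f"{rt}.{elem} is required")
            )
    if rt in _STATUS_VALUE_SETS and resource.has("status"):
        status = resource.get("status")
        if status not in _STATUS_VALUE_SETS[rt]:
            issues.append(
                ValidationIssue(
                    "error", "syntax", "status", "SYN-VS-001",
                    f"status {status!r} not in the {rt} value set",
                )
            )
    if rt == "MedicationRequest" and resource.has("intent"):
        intents = {
            "proposal", "plan", "order", "original-order", "reflex-order",
            "filler-order", "instance-order", "option",
        }
        if resource.get("intent") not in intents:
            issues.append(
                ValidationIssue(
                    "error", "syntax", "intent", "SYN-VS-001",
                    f"intent {resource.get('intent')!r} not in the value set",
                )
            )

    for path, node in _walk(resource.tree):
        if not isinstance(node, dict):
            continue
        for name, value in node.items():
            if name in _TEMPORAL_ELEMENTS and isinstance(value, str):
                cat = _TEMPORAL_ELEMENTS[name]
                regex = {"date": _DATE_RE, "dateTime": _DATETIME_RE, "instant": _INSTANT_RE}[cat]
                if not regex.match(value):
                    issues.append(
                        ValidationIssue(
                            "error", "syntax",
                            f"{path}.{name}" if path != "(resource)" else name,
                            "SYN-DT-001", f"{value!r} is not a valid FHIR {cat}",
                        )
                    )
        if "reference" in node and isinstance(node["reference"], str):
            ref_path = path if path != "(resource)" else "reference"
            try:
                classify_reference(node["reference"])
            except ValueError:
                issues.append(
                    ValidationIssue(
                        "error", "syntax", ref_path, "SYN-REF-001",
                        f"malformed reference string {node['reference']!r}",
                    )
                )
            extra = set(node) - _REFERENCE_MEMBERS
            if extra:
                issues.append(
                    ValidationIssue(
                        "error", "syntax", ref_path, "SYN-REF-002",
                        f"reference element carries inline resource members: {sorted(extra)}",
                    )
                )
    return report


def _xhtml_well_formed(div: str) -> bool:
    try:
        root = etree.fromstring(div.encode("utf-8"))
    except etree.XMLSyntaxError:
        return False
    return root.tag.endswith("div") and bool("".join(root.itertext()).strip())


def validate_ips_profile(resource: FhirResource) -> ValidationReport:
    """Tier 2: IPS profile-level checks for the four transformed types."""
    rt = resource.resource_type
    if rt not in PROFILE_VALIDATABLE_TYPES:
        raise ValidationTypeError(f"profile validation unsupported for {rt!r}")
    report = ValidationReport(rt, resource.id or "")
    issues = report.issues

    if resource.tree.get("contained"):
        issues.append(
            ValidationIssue(
                "error", "profile", "contained", "IPS-CONT-001",
                "contained must be empty in IPS output",
            )
        )
    for coding in resource.codings():
        system = coding.get("system")
        canon, _ = canonicalize_system(system)
        if canon == UNKNOWN:
            issues.append(
                ValidationIssue(
                    "error", "profile", "(resource)", "IPS-SYS-001",
                    f"code system {system!r} does not resolve to a canonical URI "
                    f"(code {coding.get('code')!r})",
                )
            )

    expected_profile = {
        "Immunization": IMMUNIZATION_IPS_PROFILE,
        "MedicationRequest": MEDICATION_REQUEST_IPS_PROFILE,
    }.get(rt)
    if expected_profile is not None:
        profiles = resource.meta.get("profile", [])
        if expected_profile not in profiles:
            issues.append(
                ValidationIssue(
                    "error", "profile", "meta.profile", "IPS-PROF-001",
                    f"meta.profile must contain {expected_profile}",
                )
            )

    if rt == "Immunization":
        if "versionId" in resource.meta or "lastUpdated" in resource.meta:
            issues.append(
                ValidationIssue(
                    "error", "profile", "meta", "IPS-IMM-001",
                    "meta.versionId/lastUpdated must be absent (server-assigned)",
                )
            )
        source = resource.meta.get("source")
        if not source or source.startswith("#"):
            issues.append(
                ValidationIssue(
                    "error", "profile", "meta.source", "IPS-IMM-001",
                    "meta.source must be a URI, not absent or a tag-like string",
                )
            )

    if rt == "Procedure":
        codings = resource.tree.get("code", {}).get("coding", [])
        if not codings or codings[0].get("system") != SNOMED:
            issues.append(
                ValidationIssue(
                    "error", "profile", "code.coding.0.system", "IPS-PROC-001",
                    "procedure code must carry a SNOMED CT coding",
                )
            )
        if not resource.has("performedDateTime"):
            issues.append(
                ValidationIssue(
                    "error", "profile", "performedDateTime", "IPS-PROC-002",
                    "performedDateTime is mandatory for the IPS procedure entry",
                )
            )

    if rt == "MedicationRequest":
        if resource.has("medicationReference") or not resource.has("medicationCodeableConcept"):
            issues.append(
                ValidationIssue(
                    "error", "profile", "medicationCodeableConcept", "IPS-MREQ-001",
                    "medication must be expressed as medicationCodeableConcept",
                )
            )

    if rt == "Medication":
        div = resource.tree.get("text", {}).get("div")
        if not div or not _xhtml_well_formed(div):
            issues.append(
                ValidationIssue(
                    "error", "profile", "text.div", "IPS-MED-001",
                    "text.div must be present, well-formed XHTML with content",
                )
            )
    return report


@dataclass
class ValidationSummary:
    reports: list[ValidationReport]
    n_valid: int
    n_error: int
    n_warning: int

    def to_dict(self) -> dict:
        return {
            "n_resources": len(self.reports),
            "n_valid": self.n_valid,
            "n_error": self.n_error,
            "n_warning": self.n_warning,
            "reports": [r.to_dict() for r in self.reports],
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, ensure_ascii=False)


def validate_resource(resource: FhirResource, tiers: tuple[str, ...] = ("syntax", "profile")) -> ValidationReport:
    """Run the requested tiers; profile tier is skipped silently for types it
    does not cover when combined with the syntax tier."""
    report = ValidationReport(resource.resource_type, resource.id or "")
    if "syntax" in tiers:
        report.issues.extend(validate_syntax(resource).issues)
    if "profile" in tiers and resource.resource_type in PROFILE_VALIDATABLE_TYPES:
        report.issues.extend(validate_ips_profile(resource).issues)
    return report


def validate_set(
    resources: list[FhirResource], tiers: tuple[str, ...] = ("syntax", "profile")
) -> ValidationSummary:
    """Per-resource reports plus deterministic totals."""
    reports = [validate_resource(r, tiers) for r in resources]
    return ValidationSummary(
        reports=reports,
        n_valid=sum(1 for r in reports if r.valid),
        n_error=sum(1 for r in reports for i in r.issues if i.severity == "error"),
        n_warning=sum(1 for r in reports for i in r.issues if i.severity == "warning"),
    )
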