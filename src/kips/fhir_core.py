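"""Minimal FHIR R4 data model with deterministic JSON round-tripping.

The model is a thin wrapper over the parsed JSON element tree.  Unknown
elements are preserved verbatim at parse time — removals are the business of
explicit transform rules, never of the parser.  Serialization is
byte-deterministic: known elements are emitted in R4 definition order,
unknown elements follow in input order, and decimals are re-emitted exactly
as written (parsed as :class:`decimal.Decimal`, never as binary floats).

Dotted paths address elements; list entries are addressed by zero-based
index, e.g. ``"code.coding.0.system"``.
"""

from __future__ import annotations

import copy
import hashlib
import json
import re
from decimal import Decimal
from typing import Any, Iterator

from .errors import (
    FhirParseError,
    InvalidArgumentError,
    PathNotFoundError,
    UnsupportedResourceError,
)

#: Resource types the toolkit understands.  Substance and Practitioner are
#: included because source exports embed them as contained resources
#: (Substance is explicitly stripped by the Medication rule-set; Practitioner
#: appears as an immunization performer).
REGISTERED_RESOURCE_TYPES = frozenset(
    {
        "Patient",
        "Organization",
        "Encounter",
        "Medication",
        "MedicationDispense",
        "MedicationRequest",
        "Immunization",
        "Procedure",
        "Condition",
        "AllergyIntolerance",
        "DiagnosticReport",
        "Bundle",
        "Substance",
        "Practitioner",
    }
)

# R4 definition order: base resource elements first, then per-type elements.
_BASE_ORDER = [
    "resourceType",
    "id",
    "meta",
    "implicitRules",
    "language",
    "text",
    "contained",
    "extension",
    "modifierExtension",
]

_TYPE_ORDER: dict[str, list[str]] = {
    "Patient": ["identifier", "active", "name", "telecom", "gender", "birthDate", "address", "managingOrganization"],
    "Organization": ["identifier", "active", "type", "name", "telecom", "address"],
    "Practitioner": ["identifier", "active", "name", "telecom", "address", "gender", "birthDate"],
    "Encounter": ["identifier", "status", "class", "type", "subject", "participant", "period", "serviceProvider"],
    "Medication": ["identifier", "code", "status", "manufacturer", "form", "amount", "ingredient", "batch"],
    "Substance": ["identifier", "status", "category", "code", "description", "instance", "ingredient"],
    "MedicationDispense": [
        "identifier", "partOf", "status", "category", "medicationCodeableConcept", "medicationReference",
        "subject", "context", "performer", "location", "authorizingPrescription", "type", "quantity",
        "daysSupply", "whenPrepared", "whenHandedOver", "destination", "receiver", "note", "dosageInstruction",
    ],
    "MedicationRequest": [
        "identifier", "status", "statusReason", "intent", "category", "priority", "doNotPerform",
        "reportedBoolean", "reportedReference", "medicationCodeableConcept", "medicationReference",
        "subject", "encounter", "supportingInformation", "authoredOn", "requester", "performer",
        "recorder", "reasonCode", "reasonReference", "note", "dosageInstruction", "dispenseRequest",
    ],
    "Immunization": [
        "identifier", "status", "statusReason", "vaccineCode", "patient", "encounter",
        "occurrenceDateTime", "occurrenceString", "recorded", "primarySource", "reportOrigin",
        "location", "manufacturer", "lotNumber", "expirationDate", "site", "route", "doseQuantity",
        "performer", "note", "reasonCode", "isSubpotent", "protocolApplied",
    ],
    "Procedure": [
        "identifier", "instantiatesCanonical", "instantiatesUri", "basedOn", "partOf", "status",
        "statusReason", "category", "code", "subject", "encounter", "performedDateTime",
        "performedPeriod", "recorder", "asserter", "performer", "location", "reasonCode",
        "reasonReference", "bodySite", "outcome", "report", "complication", "followUp", "note",
    ],
    "Condition": [
        "identifier", "clinicalStatus", "verificationStatus", "category", "severity", "code",
        "bodySite", "subject", "encounter", "onsetDateTime", "recordedDate",
    ],
    "AllergyIntolerance": [
        "identifier", "clinicalStatus", "verificationStatus", "type", "category", "criticality",
        "code", "patient", "encounter", "onsetDateTime", "recordedDate", "reaction",
    ],
    "DiagnosticReport": [
        "identifier", "basedOn", "status", "category", "code", "subject", "encounter",
        "effectiveDateTime", "issued", "performer", "result", "conclusion", "conclusionCode",
    ],
    "Bundle": ["identifier", "type", "timestamp", "total", "link", "entry"],
}

# Generic rank for nested complex-type elements (Coding, Meta, Reference,
# Quantity, Ratio, Dosage, Bundle.entry ...).  Unknown keys keep input order
# after ranked ones; determinism holds either way.
_NESTED_RANK = {
    k: i
    for i, k in enumerate(
        [
            "id",
            "extension",
            "versionId",
            "lastUpdated",
            "source",
            "profile",
            "security",
            "tag",
            "use",
            "sequence",
            "function",
            "type",
            "system",
            "version",
            "code",
            "display",
            "userSelected",
            "value",
            "comparator",
            "unit",
            "coding",
            "text",
            "status",
            "div",
            "reference",
            "identifier",
            "numerator",
            "denominator",
            "start",
            "end",
            "period",
            "assigner",
            "itemCodeableConcept",
            "itemReference",
            "isActive",
            "strength",
            "series",
            "authority",
            "targetDisease",
            "doseNumberPositiveInt",
            "doseNumberString",
            "timing",
            "route",
            "method",
            "doseAndRate",
            "doseQuantity",
            "actor",
            "fullUrl",
            "resource",
            "search",
            "request",
            "response",
        ]
    )
}

_TYPE_ID_RE = re.compile(r"^[A-Za-z]+/[A-Za-z0-9\-.]{1,64}$")


def classify_reference(reference_string: str) -> str:
    """Classify a reference string as ``relative``, ``local`` or ``absolute``.

    Raises ``ValueError`` for strings matching none of the three forms.
    """
    if reference_string.startswith("#"):
        if len(reference_string) == 1:
            raise ValueError("empty local reference '#'")
        return "local"
    if re.match(r"^https?://", reference_string):
        return "absolute"
    if _TYPE_ID_RE.match(reference_string):
        return "relative"
    raise ValueError(f"malformed reference string: {reference_string!r}")


def _order_tree(node: Any, resource_type: str | None = None) -> Any:
    """Return a copy of *node* with dict keys in canonical order, recursively."""
    if isinstance(node, list):
        return [_order_tree(v) for v in node]
    if not isinstance(node, dict):
        return node
    if "resourceType" in node:
        resource_type = node.get("resourceType")
    if resource_type is not None and "resourceType" in node:
        known = _BASE_ORDER + _TYPE_ORDER.get(resource_type, [])
        rank = {k: i for i, k in enumerate(known)}
    else:
        rank = _NESTED_RANK
    keys = list(node.keys())
    known_keys = sorted((k for k in keys if k in rank), key=lambda k: rank[k])
    unknown_keys = [k for k in keys if k not in rank]
    ordered: dict[str, Any] = {}
    for k in known_keys + unknown_keys:
        ordered[k] = _order_tree(node[k])
    return ordered


def _emit(node: Any, indent: int, level: int) -> str:
    """Deterministic JSON emitter; Decimals re-rendered from their own text."""
    pad = " " * (indent * level)
    inner = " " * (indent * (level + 1))
    if isinstance(node, dict):
        if not node:
            return "{}"
        items = [
            f"{inner}{json.dumps(k, ensure_ascii=False)}: {_emit(v, indent, level + 1)}"
            for k, v in node.items()
        ]
        return "{\n" + ",\n".join(items) + "\n" + pad + "}"
    if isinstance(node, list):
        if not node:
            return "[]"
        items = [f"{inner}{_emit(v, indent, level + 1)}" for v in node]
        return "[\n" + ",\n".join(items) + "\n" + pad + "]"
    if isinstance(node, bool) or node is None:
        return json.dumps(node)
    if isinstance(node, Decimal):
        return str(node)
    if isinstance(node, (int, float)):
        return json.dumps(node)
    return json.dumps(node, ensure_ascii=False)


def _emit_compact(node: Any) -> str:
    if isinstance(node, dict):
        return "{" + ",".join(f"{json.dumps(k, ensure_ascii=False)}:{_emit_compact(v)}" for k, v in node.items()) + "}"
    if isinstance(node, list):
        return "[" + ",".join(_emit_compact(v) for v in node) + "]"
    if isinstance(node, bool) or node is None:
        return json.dumps(node)
    if isinstance(node, Decimal):
        return str(node)
    if isinstance(node, (int, float)):
        return json.dumps(node)
    return json.dumps(node, ensure_ascii=False)


class FhirResource:
    """A FHIR R4 resource as an ordered element tree.

    The wrapped ``tree`` is plain Python (dicts, lists, str, bool, int,
    :class:`~decimal.Decimal`).  Equality compares canonically ordered trees.
    """

    def __init__(self, tree: dict):
        if not isinstance(tree, dict):
            raise UnsupportedResourceError("resource must be a JSON object")
        rt = tree.get("resourceType")
        if not rt or not isinstance(rt, str):
            raise UnsupportedResourceError("missing resourceType")
        if rt not in REGISTERED_RESOURCE_TYPES:
            raise UnsupportedResourceError(f"unregistered resourceType: {rt!r}")
        for i, entry in enumerate(tree.get("contained", [])):
            if not isinstance(entry, dict) or "resourceType" not in entry:
                raise UnsupportedResourceError(f"contained[{i}] is not a resource")
            if not entry.get("id"):
                raise UnsupportedResourceError(f"contained[{i}] has no id")
        self.tree = tree

    # -- typed accessors ---------------------------------------------------
    @property
    def resource_type(self) -> str:
        return self.tree["resourceType"]

    @property
    def id(self) -> str | None:
        return self.tree.get("id")

    @property
    def meta(self) -> dict:
        return self.tree.get("meta", {})

    @property
    def contained(self) -> list["FhirResource"]:
        return [FhirResource(c) for c in self.tree.get("contained", [])]

    def find_contained(self, local_id: str) -> "FhirResource | None":
        local_id = local_id.lstrip("#")
        for c in self.tree.get("contained", []):
            if c.get("id") == local_id:
                return FhirResource(c)
        return None

    def codings(self) -> Iterator[dict]:
        """Yield every Coding object anywhere in the tree (dicts with a code
        member under a ``coding`` list, or loose system/code pairs)."""

        def walk(node: Any) -> Iterator[dict]:
            if isinstance(node, dict):
                if "code" in node and ("system" in node or "display" in node) and isinstance(node.get("code"), str):
                    yield node
                for v in node.values():
                    yield from walk(v)
            elif isinstance(node, list):
                for v in node:
                    yield from walk(v)

        yield from walk(self.tree)

    # -- dotted-path access ------------------------------------------------
    @staticmethod
    def _segments(path: str) -> list[str]:
        if not path:
            raise InvalidArgumentError("empty path")
        return path.split(".")

    def get(self, path: str) -> Any:
        node: Any = self.tree
        for seg in self._segments(path):
            if isinstance(node, list):
                if not seg.isdigit() or int(seg) >= len(node):
                    raise PathNotFoundError(f"path not found: {path}")
                node = node[int(seg)]
            elif isinstance(node, dict):
                if seg not in node:
                    raise PathNotFoundError(f"path not found: {path}")
                node = node[seg]
            else:
                raise PathNotFoundError(f"path not found: {path}")
        return node

    def has(self, path: str) -> bool:
        try:
            self.get(path)
            return True
        except PathNotFoundError:
            return False

    def set(self, path: str, value: Any) -> None:
        segs = self._segments(path)
        node: Any = self.tree
        for seg in segs[:-1]:
            if isinstance(node, list):
                node = node[int(seg)]
            else:
                node = node.setdefault(seg, {})
        last = segs[-1]
        if isinstance(node, list):
            node[int(last)] = value
        else:
            node[last] = value

    def delete(self, path: str) -> None:
        segs = self._segments(path)
        parent = self.get(".".join(segs[:-1])) if len(segs) > 1 else self.tree
        last = segs[-1]
        if isinstance(parent, list):
            del parent[int(last)]
        elif isinstance(parent, dict) and last in parent:
            del parent[last]
        else:
            raise PathNotFoundError(f"path not found: {path}")

    # -- serialization -----------------------------------------------------
    def ordered(self) -> dict:
        return _order_tree(copy.deepcopy(self.tree))

    def to_json(self, indent: int = 2) -> str:
        return _emit(self.ordered(), indent, 0)

    def to_json_line(self) -> str:
        return _emit_compact(self.ordered())

    def content_hash(self) -> str:
        return hashlib.sha256(self.to_json_line().encode("utf-8")).hexdigest()

    def copy(self) -> "FhirResource":
        return FhirResource(copy.deepcopy(self.tree))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, FhirResource):
            return NotImplemented
        return self.ordered() == other.ordered()

    def __repr__(self) -> str:
        return f"<FhirResource {self.resource_type}/{self.id}>"


class ResourceBundle:
    """A FHIR Bundle seen as an ordered list of entry resources."""

    def __init__(self, bundle_type: str, entries: list[FhirResource], tree: dict | None = None):
        self.bundle_type = bundle_type
        self.entries = entries
        self._tree = tree

    @classmethod
    def from_resource(cls, resource: FhirResource) -> "ResourceBundle":
        if resource.resource_type != "Bundle":
            raise UnsupportedResourceError("not a Bundle")
        entries = [
            FhirResource(e["resource"])
            for e in resource.tree.get("entry", [])
            if isinstance(e, dict) and "resource" in e
        ]
        return cls(resource.tree.get("type", "collection"), entries, resource.tree)

    def to_resource(self) -> FhirResource:
        if self._tree is not None:
            return FhirResource(self._tree)
        return FhirResource(
            {
                "resourceType": "Bundle",
                "type": self.bundle_type,
                "entry": [{"resource": e.tree} for e in self.entries],
            }
        )


def parse_resource(json_text: str) -> FhirResource:
    """Parse one FHIR R4 resource from JSON text.

    Decimals are preserved as written; unknown elements pass through
    untouched.  Malformed JSON raises :class:`FhirParseError` naming the byte
    offset; a missing or unregistered resourceType raises
    :class:`UnsupportedResourceError`.
    """
    try:
        tree = json.loads(json_text, parse_float=Decimal)
    except json.JSONDecodeError as exc:
        raise FhirParseError(f"malformed JSON: {exc.msg}", offset=exc.pos) from exc
    return FhirResource(tree)


def serialize_resource(resource: FhirResource, indent: int = 2) -> str:
    """Serialize deterministically: R4 definition order for known elements,
    input order for unknown ones; byte-identical across runs."""
    return resource.to_json(indent=indent)


def list_contained(resource: FhirResource) -> list[FhirResource]:
    """The contained resources (possibly empty); never raises."""
    return resource.contained


def rewrite_reference(
    resource: FhirResource, element_path: str, target_type: str, target_id: str
) -> FhirResource:
    """Collapse the reference element at *element_path* to
    ``{"reference": "Type/id"}``, dropping any inline sibling members.

    Idempotent; returns a new resource.
    """
    if not target_id:
        raise InvalidArgumentError("target_id must be non-empty")
    out = resource.copy()
    if not out.has(element_path):
        raise PathNotFoundError(f"path not found: {element_path}")
    out.set(element_path, {"reference": f"{target_type}/{target_id}"})
    return out


def write_ndjson(resources: list[FhirResource], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for r in resources:
            fh.write(r.to_json_line() + "\n")


def read_ndjson(path) -> list[FhirResource]:
    out = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line:
                out.append(parse_resource(line))
    return out
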