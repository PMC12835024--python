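"""Deterministic rule engine producing IPS-conformant resources.

Four rule-sets — Immunization, Medication, MedicationRequest, Procedure —
are shipped as YAML data files and applied by pure functions.  Each
transformer is a *projection*: the output is rebuilt from scratch by copying
exactly the whitelisted elements and applying the declared repairs
(reference flattening, metadata policy, system defaulting, EDI→SNOMED code
replacement, narrative generation).  Every mutation is logged as one
:class:`TransformAction`; replaying a report's action log against its input
reproduces its output byte-for-byte, and applying a transformer to its own
output is the identity on the resource (``f∘f == f``).
"""

from __future__ import annotations

import copy
import hashlib
import html
from dataclasses import dataclass, field
from importlib import resources as importlib_resources
from typing import Any

import yaml

from .errors import (
    ExtractionError,
    InvalidArgumentError,
    MappingError,
    MissingElementError,
    MissingIdError,
    TransformTypeError,
)
from .fhir_core import FhirResource, ResourceBundle, classify_reference
from .terminology import (
    EDI,
    SNOMED,
    UNKNOWN,
    ConceptMapTable,
    canonicalize_system,
    load_default_edi_map,
    map_code,
)

IMMUNIZATION_IPS_PROFILE = "http://hl7.org/fhir/uv/ips/StructureDefinition/Immunization-uv-ips"
MEDICATION_REQUEST_IPS_PROFILE = (
    "http://hl7.org/fhir/uv/ips/StructureDefinition/MedicationRequest-uv-ips"
)

#: Action kinds that set a value at ``path`` when a log is replayed.
VALUE_SETTING_KINDS = frozenset(
    {
        "flattened",
        "profile_stamped",
        "source_set",
        "code_defaulted",
        "code_mapped",
        "narrative_generated",
        "defaulted_element",
    }
)


@dataclass
class TransformAction:
    kind: str
    path: str
    detail: str = ""
    value: Any = None

    def to_dict(self) -> dict:
        d = {"kind": self.kind, "path": self.path, "detail": self.detail}
        if self.value is not None:
            d["value"] = self.value
        return d


@dataclass
class TransformReport:
    input_id: str
    input: FhirResource
    output: FhirResource | None
    actions: list[TransformAction] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def transformed(self) -> bool:
        return self.output is not None


@dataclass
class TransformRuleSet:
    name: str
    input_resource_types: list[str]
    output_resource_type: str
    ips_profile_uri: str | None
    retain_paths: list[str]
    remove_paths: list[str]
    flatten_reference_paths: list[dict]
    meta_policy: dict
    code_policy: dict
    narrative_policy: dict
    extra: dict = field(default_factory=dict)

    @classmethod
    def from_dict(cls, data: dict) -> "TransformRuleSet":
        known = {
            "name", "input_resource_types", "output_resource_type", "ips_profile_uri",
            "retain_paths", "remove_paths", "flatten_reference_paths", "meta_policy",
            "code_policy", "narrative_policy",
        }
        overlap = set(data.get("retain_paths", [])) & set(data.get("remove_paths", []))
        if overlap:
            raise InvalidArgumentError(f"rule-set {data.get('name')}: retain∩remove = {overlap}")
        return cls(
            name=data["name"],
            input_resource_types=list(data["input_resource_types"]),
            output_resource_type=data["output_resource_type"],
            ips_profile_uri=data.get("ips_profile_uri"),
            retain_paths=list(data.get("retain_paths", [])),
            remove_paths=list(data.get("remove_paths", [])),
            flatten_reference_paths=list(data.get("flatten_reference_paths", []) or []),
            meta_policy=dict(data.get("meta_policy", {})),
            code_policy=dict(data.get("code_policy", {})),
            narrative_policy=dict(data.get("narrative_policy", {})),
            extra={k: v for k, v in data.items() if k not in known},
        )


def load_ruleset(name: str) -> TransformRuleSet:
    """Load a packaged rule-set by name (immunization, medication,
    medication_request, procedure)."""
    path = importlib_resources.files("kips.data.rulesets").joinpath(f"{name}.yaml")
    with path.open(encoding="utf-8") as fh:
        return TransformRuleSet.from_dict(yaml.safe_load(fh))


_RULESETS: dict[str, TransformRuleSet] = {}


def _ruleset(name: str) -> TransformRuleSet:
    if name not in _RULESETS:
        _RULESETS[name] = load_ruleset(name)
    return _RULESETS[name]


@dataclass
class TransformContext:
    """Shared state for a transformation pass."""

    concept_map: ConceptMapTable | None = None
    mode: str = "lenient"  # or "strict"
    encounter_periods: dict[str, str] = field(default_factory=dict)

    def edi_map(self) -> ConceptMapTable:
        if self.concept_map is None:
            self.concept_map = load_default_edi_map()
        return self.concept_map


# ---------------------------------------------------------------------------
# output builder / replay


def _set_path(tree: dict, path: str, value: Any) -> None:
    segs = path.split(".")
    node: Any = tree
    for i, seg in enumerate(segs[:-1]):
        nxt_is_index = segs[i + 1].isdigit()
        if isinstance(node, list):
            idx = int(seg)
            while len(node) <= idx:
                node.append([] if nxt_is_index else {})
            node = node[idx]
        else:
            if seg not in node:
                node[seg] = [] if nxt_is_index else {}
            node = node[seg]
    last = segs[-1]
    if isinstance(node, list):
        idx = int(last)
        while len(node) <= idx:
            node.append(None)
        node[idx] = value
    else:
        node[last] = value


class _Builder:
    def __init__(self, original: FhirResource):
        self.original = original
        self.src = original
        self.out: dict = {}
        self.actions: list[TransformAction] = []
        self.warnings: list[str] = []

    def switch_to_contained(self, contained: FhirResource) -> None:
        self.actions.append(
            TransformAction("extracted_from_contained", "(resource)", contained.id or "")
        )
        self.src = contained

    def retain(self, path: str, detail: str = "") -> bool:
        if not self.src.has(path):
            return False
        _set_path(self.out, path, copy.deepcopy(self.src.get(path)))
        self.actions.append(TransformAction("retained", path, detail))
        return True

    def removed(self, path: str, detail: str = "") -> None:
        if self.src.has(path):
            self.actions.append(TransformAction("removed", path, detail))

    def mutate(self, kind: str, path: str, value: Any, detail: str = "") -> None:
        _set_path(self.out, path, copy.deepcopy(value))
        self.actions.append(TransformAction(kind, path, detail, copy.deepcopy(value)))

    def retain_or(self, kind: str, path: str, value: Any, detail: str = "") -> None:
        """Log ``retained`` when the computed value equals the source value,
        otherwise log the given mutation kind carrying the new value."""
        if self.src.has(path) and self.src.get(path) == value:
            self.retain(path)
        else:
            self.mutate(kind, path, value, detail)

    def note(self, kind: str, path: str, detail: str = "") -> None:
        self.actions.append(TransformAction(kind, path, detail))

    def warn(self, message: str) -> None:
        self.warnings.append(message)

    def log_dropped_top_level(self) -> None:
        """One ``removed`` action per source top-level element absent from
        the output (log completeness for the whitelist projection)."""
        logged = {a.path for a in self.actions if a.kind == "removed"}
        for key in self.src.tree:
            if key not in self.out and key not in logged:
                self.actions.append(TransformAction("removed", key))

    def report(self) -> TransformReport:
        return TransformReport(
            input_id=self.original.id or "",
            input=self.original,
            output=FhirResource(self.out),
            actions=self.actions,
            warnings=self.warnings,
        )


def replay_actions(input_resource: FhirResource, actions: list[TransformAction]) -> FhirResource:
    """Re-apply an action log to the input; reproduces the report's output."""
    src = input_resource
    out: dict = {}
    for a in actions:
        if a.kind == "extracted_from_contained":
            found = input_resource.find_contained(a.detail)
            if found is None:
                raise ExtractionError(f"replay: contained {a.detail!r} not found")
            src = found
        elif a.kind == "retained":
            _set_path(out, a.path, copy.deepcopy(src.get(a.path)))
        elif a.kind in VALUE_SETTING_KINDS:
            _set_path(out, a.path, copy.deepcopy(a.value))
        # removed / code_unmapped / skipped carry no replayable mutation
    return FhirResource(out)


# ---------------------------------------------------------------------------
# shared repairs


def _resolve_reference_target(
    src: FhirResource, path: str, default_type: str
) -> tuple[str, str]:
    """Recover (target_type, target_id) from a reference element that may be
    a clean ``Type/id`` string, a ``#local`` pointer into contained, or an
    inline duplicated resource object."""
    elem = src.get(path)
    if not isinstance(elem, dict):
        raise MissingIdError(f"{path}: not a reference element")
    ref = elem.get("reference")
    if isinstance(ref, str) and ref:
        try:
            kind = classify_reference(ref)
        except ValueError:
            kind = None
        if kind == "relative":
            rtype, rid = ref.split("/", 1)
            return rtype, rid
        if kind == "local":
            contained = src.find_contained(ref)
            if contained is not None and contained.id:
                return contained.resource_type, contained.id
            raise MissingIdError(f"{path}: local reference {ref!r} has no contained target")
        if kind == "absolute":
            tail = ref.rstrip("/").split("/")
            if len(tail) >= 2 and tail[-2] and tail[-1]:
                return tail[-2], tail[-1]
    inline = elem.get("resource")
    if isinstance(inline, dict) and inline.get("id") and inline.get("resourceType"):
        return inline["resourceType"], inline["id"]
    raise MissingIdError(f"{path}: no recoverable target id")


def _flatten(b: _Builder, path: str, default_type: str) -> None:
    rtype, rid = _resolve_reference_target(b.src, path, default_type)
    b.mutate("flattened", path, {"reference": f"{rtype}/{rid}"}, f"{rtype}/{rid}")


def _repair_codeable_concept(cc: dict, default_system: str | None) -> tuple[dict, bool]:
    """Fill missing/'undefined' coding systems with *default_system*.
    Returns (repaired copy, changed?)."""
    out = copy.deepcopy(cc)
    changed = False
    for coding in out.get("coding", []):
        canon, _ = canonicalize_system(coding.get("system"))
        if canon == UNKNOWN and default_system:
            coding["system"] = default_system
            changed = True
        elif canon != UNKNOWN and coding.get("system") != canon:
            coding["system"] = canon
            changed = True
    return out, changed


def _apply_meta_policy(b: _Builder, rs: TransformRuleSet) -> None:
    policy = rs.meta_policy
    if rs.extra.get("meta_keep"):
        for sub in rs.extra["meta_keep"]:
            b.retain(f"meta.{sub}")
        for key in b.src.meta:
            if key not in rs.extra["meta_keep"]:
                b.removed(f"meta.{key}")
        return
    if policy.get("drop_version_and_updated"):
        b.removed("meta.versionId", "assigned by the server")
        b.removed("meta.lastUpdated", "assigned by the server")
    if policy.get("stamp_profile") and rs.ips_profile_uri:
        b.retain_or("profile_stamped", "meta.profile", [rs.ips_profile_uri])
    if policy.get("source_uri"):
        b.retain_or("source_set", "meta.source", policy["source_uri"])


# ---------------------------------------------------------------------------
# the four transformers


def _require_type(resource: FhirResource, allowed: list[str], name: str) -> None:
    if resource.resource_type not in allowed:
        raise TransformTypeError(
            f"{name} rule-set cannot transform {resource.resource_type!r}"
        )


def transform_immunization(
    resource: FhirResource, ctx: TransformContext | None = None
) -> TransformReport:
    """Apply the immunization rule-set: whitelist projection, IPS profile
    stamp, platform source URI, flattened patient/performer references."""
    ctx = ctx or TransformContext()
    rs = _ruleset("immunization")
    _require_type(resource, rs.input_resource_types, rs.name)
    b = _Builder(resource)

    for path in ["resourceType", "id", "status"]:
        b.retain(path)
    _apply_meta_policy(b, rs)
    if b.src.has("vaccineCode"):
        repaired, changed = _repair_codeable_concept(
            b.src.get("vaccineCode"), rs.code_policy.get("default_system")
        )
        if changed:
            b.mutate("code_defaulted", "vaccineCode", repaired, "system canonicalized")
        else:
            b.retain("vaccineCode")
    _flatten(b, "patient", "Patient")
    for path in ["occurrenceDateTime", "lotNumber", "primarySource", "protocolApplied"]:
        b.retain(path)
    if b.src.has("performer"):
        for i, entry in enumerate(b.src.get("performer")):
            if "function" in entry:
                b.retain(f"performer.{i}.function")
            if "actor" in entry:
                rtype, rid = _resolve_reference_target(b.src, f"performer.{i}.actor", "Organization")
                if rtype not in ("Organization", "Practitioner"):
                    rtype = "Organization"
                b.mutate(
                    "flattened", f"performer.{i}.actor",
                    {"reference": f"{rtype}/{rid}"}, f"{rtype}/{rid}",
                )
    for path in rs.remove_paths:
        b.removed(path)
    b.log_dropped_top_level()
    return b.report()


def _medication_narrative(med: dict) -> dict:
    code = med.get("code", {})
    name = code.get("text")
    if not name:
        codings = code.get("coding", [])
        name = codings[0].get("display") if codings else None
    name = name or "Medication"
    form = med.get("form", {})
    form_str = form.get("text") or (
        form.get("coding", [{}])[0].get("display") if form.get("coding") else None
    )
    parts = []
    for ing in med.get("ingredient", []):
        num = ing.get("strength", {}).get("numerator", {})
        if "value" in num:
            parts.append(f"{num['value']} {num.get('unit', '')}".strip())
    strength_str = ", ".join(parts)
    desc = " ".join(x for x in [strength_str, form_str] if x)
    div = (
        '<div xmlns="http://www.w3.org/1999/xhtml"><p><b>'
        + html.escape(str(name))
        + "</b>"
        + (": " + html.escape(desc) if desc else "")
        + "</p></div>"
    )
    return {"status": "generated", "div": div}


def transform_medication(
    resource: FhirResource, ctx: TransformContext | None = None
) -> TransformReport:
    """Apply the medication rule-set: extract the contained Medication from a
    dispense record, rebuild ingredient/form/identifier, generate the XHTML
    narrative.  Substance contained resources are dropped."""
    ctx = ctx or TransformContext()
    rs = _ruleset("medication")
    _require_type(resource, rs.input_resource_types, rs.name)
    b = _Builder(resource)

    if resource.resource_type == "MedicationDispense":
        med = next((c for c in resource.contained if c.resource_type == "Medication"), None)
        if med is None:
            raise ExtractionError(
                f"MedicationDispense/{resource.id}: no contained Medication to extract"
            )
        for c in resource.contained:
            if c.resource_type == "Substance":
                b.note("removed", "contained", f"Substance/{c.id}")
        b.switch_to_contained(med)

    b.retain("resourceType")
    if not b.retain("id"):
        digest = hashlib.sha256(b.src.to_json_line().encode()).hexdigest()[:12]
        b.mutate("defaulted_element", "id", f"med-{digest}", "content-hash id")
    if b.src.has("identifier"):
        idents = copy.deepcopy(b.src.get("identifier"))
        changed = False
        for ident in idents:
            system = ident.get("system")
            canon, _ = canonicalize_system(system)
            if canon == UNKNOWN and not str(system or "").startswith("http"):
                ident["system"] = rs.extra.get("identifier_default_system")
                changed = True
        if changed:
            b.mutate("code_defaulted", "identifier", idents, "identifier system set to URL")
        else:
            b.retain("identifier")
    src_code = b.src.get("code") if b.src.has("code") else None
    if src_code is not None:
        repaired, changed = _repair_codeable_concept(src_code, rs.code_policy.get("default_system"))
        if changed:
            b.mutate("code_defaulted", "code", repaired, "system canonicalized")
        else:
            b.retain("code")
    b.retain("status")

    form = b.src.get("form") if b.src.has("form") else None
    form_display = None
    if form is not None:
        repaired_form, changed = _repair_codeable_concept(form, rs.extra.get("form_default_system"))
        form_display = repaired_form.get("text") or (
            repaired_form.get("coding", [{}])[0].get("display")
            if repaired_form.get("coding")
            else None
        )
        if changed:
            b.mutate("code_defaulted", "form", repaired_form, "dose form system set to SNOMED CT")
        else:
            b.retain("form")

    if b.src.has("ingredient"):
        new_ingredients = []
        denominator_changed = False
        for ing in b.src.get("ingredient"):
            item = ing.get("itemCodeableConcept")
            if item is None and src_code is not None:
                item = src_code
            if item is None or (not item.get("coding") and not item.get("text")):
                raise InvalidArgumentError(
                    f"Medication/{b.src.id}: ingredient lacks both code and text"
                )
            item, _ = _repair_codeable_concept(item, rs.code_policy.get("default_system"))
            new_ing: dict = {"itemCodeableConcept": item}
            strength = ing.get("strength")
            if strength and "numerator" in strength:
                num = {
                    k: v for k, v in strength["numerator"].items() if k in ("value", "unit")
                }
                denom_src = strength.get("denominator", {})
                denom = {"value": denom_src.get("value", 1)}
                if form_display:
                    denom["unit"] = form_display
                    if denom_src.get("unit") != form_display:
                        denominator_changed = True
                elif "unit" in denom_src:
                    denom["unit"] = denom_src["unit"]
                new_ing["strength"] = {"numerator": num, "denominator": denom}
            new_ingredients.append(new_ing)
        b.retain_or(
            "defaulted_element", "ingredient", new_ingredients,
            "ingredient rebuilt (itemCodeableConcept + numerator/denominator)",
        )
        if denominator_changed:
            b.warn("strength denominator unit taken from the dose-form display")
    elif src_code is None:
        raise InvalidArgumentError(
            f"Medication/{b.src.id}: neither ingredient nor code present"
        )

    narrative = _medication_narrative(b.out)
    b.retain_or("narrative_generated", "text", narrative, "generated XHTML narrative")
    for path in rs.remove_paths:
        b.removed(path)
    b.log_dropped_top_level()
    return b.report()


def transform_medication_request(
    resource: FhirResource, ctx: TransformContext | None = None
) -> TransformReport:
    """Apply the medication-request rule-set: keep medicationCodeableConcept
    (never converted to a reference), flatten the subject, retain the dosage
    instruction essentials, strip encounter/identifier/requester."""
    ctx = ctx or TransformContext()
    rs = _ruleset("medication_request")
    _require_type(resource, rs.input_resource_types, rs.name)
    b = _Builder(resource)

    for path in ["resourceType", "id", "status", "intent"]:
        b.retain(path)
    _apply_meta_policy(b, rs)
    b.retain("medicationCodeableConcept")
    _flatten(b, "subject", "Patient")
    b.retain("authoredOn")
    if b.src.has("dosageInstruction"):
        keys = rs.extra.get("dosage_instruction_keys", [])
        for i, dosage in enumerate(b.src.get("dosageInstruction")):
            for key in dosage:
                if key in keys:
                    b.retain(f"dosageInstruction.{i}.{key}")
                else:
                    b.removed(f"dosageInstruction.{i}.{key}")
    for path in rs.remove_paths:
        b.removed(path)
    b.log_dropped_top_level()
    return b.report()


def transform_procedure(
    resource: FhirResource, ctx: TransformContext | None = None
) -> TransformReport:
    """Apply the procedure rule-set: whitelist projection, meta reduced to
    versionId/lastUpdated/source, first coding only with the EDI→SNOMED
    concept-map replacement, code.text mirrored from the coding, subject
    flattened, performedDateTime ensured (never fabricated)."""
    ctx = ctx or TransformContext()
    rs = _ruleset("procedure")
    _require_type(resource, rs.input_resource_types, rs.name)
    b = _Builder(resource)

    for path in ["resourceType", "id"]:
        b.retain(path)
    _apply_meta_policy(b, rs)
    b.retain("status")

    if not b.src.has("code") or not b.src.get("code").get("coding"):
        raise InvalidArgumentError(f"Procedure/{resource.id}: no coding present")
    coding = copy.deepcopy(b.src.get("code")["coding"][0])
    n_codings = len(b.src.get("code")["coding"])
    kind = "defaulted_element"
    detail = "coding reduced to coding[0]" if n_codings > 1 else ""
    canon, _ = canonicalize_system(coding.get("system"))
    if canon == UNKNOWN:
        coding["system"] = rs.code_policy.get("default_system", SNOMED)
        kind, detail = "code_defaulted", "missing system set to SNOMED CT"
    elif coding.get("system") != canon:
        coding["system"] = canon
    unmapped_code = None
    if coding.get("system") == EDI and rs.code_policy.get("map_via"):
        entry = map_code(ctx.edi_map(), EDI, coding["code"])
        if entry.matched:
            old = coding["code"]
            coding = {
                "system": entry.target_system,
                "code": entry.target_code,
            }
            if entry.target_display:
                coding["display"] = entry.target_display
            kind, detail = "code_mapped", f"EDI {old} -> SNOMED {entry.target_code}"
        else:
            unmapped_code = coding["code"]
            if ctx.mode == "strict":
                raise MappingError(
                    f"Procedure/{resource.id}: EDI code {unmapped_code!r} has no "
                    "entry in the concept map"
                )
    new_code = {"coding": [coding], "text": coding.get("display", coding.get("code"))}
    b.retain_or(kind, "code", new_code, detail)
    if unmapped_code is not None:
        b.note("code_unmapped", "code.coding.0.code", unmapped_code)
        b.warn(f"unmapped EDI code: {unmapped_code}")

    _flatten(b, "subject", "Patient")

    if b.src.has("performedDateTime"):
        b.retain("performedDateTime")
    elif b.src.has("performedPeriod.start"):
        b.mutate(
            "defaulted_element", "performedDateTime",
            b.src.get("performedPeriod.start"), "taken from performedPeriod.start",
        )
    else:
        enc_ref = (
            b.src.get("encounter").get("reference") if b.src.has("encounter") else None
        )
        start = ctx.encounter_periods.get(enc_ref or "")
        if start:
            b.mutate(
                "defaulted_element", "performedDateTime", start,
                f"taken from {enc_ref} period start",
            )
        elif ctx.mode == "strict":
            raise MissingElementError(
                f"Procedure/{resource.id}: performedDateTime missing and no "
                "source date available"
            )
        else:
            b.warn("performedDateTime missing; no source date available")
    for path in rs.remove_paths:
        b.removed(path)
    b.log_dropped_top_level()
    return b.report()


# ---------------------------------------------------------------------------
# routing

_ROUTES = {
    "Immunization": transform_immunization,
    "MedicationDispense": transform_medication,
    "Medication": transform_medication,
    "MedicationRequest": transform_medication_request,
    "Procedure": transform_procedure,
}

OUTPUT_RESOURCE_TYPES = ("Medication", "MedicationRequest", "Immunization", "Procedure")


def harvest_encounter_periods(resources: list[FhirResource]) -> dict[str, str]:
    """Map ``Encounter/{id}`` → period start for performedDateTime backfill."""
    periods: dict[str, str] = {}
    for r in resources:
        if r.resource_type == "Encounter" and r.id and r.has("period.start"):
            periods[f"Encounter/{r.id}"] = r.get("period.start")
    return periods


def expand_inputs(items: list[FhirResource]) -> list[FhirResource]:
    """Flatten Bundles into their entry resources, preserving order."""
    out: list[FhirResource] = []
    for r in items:
        if r.resource_type == "Bundle":
            out.extend(ResourceBundle.from_resource(r).entries)
        else:
            out.append(r)
    return out


def transform_all(
    inputs: list[FhirResource], ctx: TransformContext | None = None
) -> list[TransformReport]:
    """Route every input resource to its rule-set.

    Bundles are expanded; Encounter periods are harvested first so procedure
    date backfill can see them.  Resources with no rule-set (Patient,
    Organization, Encounter, ...) are skipped with an info action.  In
    lenient mode per-resource failures become warning-bearing reports; in
    strict mode the first failure raises.
    """
    ctx = ctx or TransformContext()
    resources = expand_inputs(inputs)
    ctx.encounter_periods.update(harvest_encounter_periods(resources))
    reports: list[TransformReport] = []
    for r in resources:
        fn = _ROUTES.get(r.resource_type)
        if fn is None:
            reports.append(
                TransformReport(
                    input_id=r.id or "",
                    input=r,
                    output=None,
                    actions=[
                        TransformAction("skipped", "(resource)", f"no rule-set for {r.resource_type}")
                    ],
                )
            )
            continue
        try:
            reports.append(fn(r, ctx))
        except Exception as exc:
            if ctx.mode == "strict":
                raise
            reports.append(
                TransformReport(
                    input_id=r.id or "",
                    input=r,
                    output=None,
                    warnings=[f"{type(exc).__name__}: {exc}"],
                )
            )
    return reports
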