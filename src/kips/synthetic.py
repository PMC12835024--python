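"""Seedable generator of messy personal-health-record exports.

Emulates the three source classes of the study data: per-subject
medication-record exports (a MedicationDispense with contained Patient /
Organization / Medication), immunization exports (an Immunization with
contained resources), and a single hospital "Medical MyData" collection
Bundle (MedicationRequest, Procedure, Patient, Organization, Encounter with
EDI-coded procedures).  The default cohort is three subjects with one
medication and one immunization export each (six app files) plus one
hospital bundle for one subject.

Messiness knobs reproduce the documented source-data pathologies:

``p_undefined_system``
    code systems emitted as the literal string ``"undefined"``;
``p_redundant_nested``
    a duplicate inline Patient embedded inside the subject reference;
``p_missing_performed_date``
    hospital procedures lack performedDateTime (the encounter period
    remains the only recoverable date);
``p_unmapped_edi``
    procedure EDI codes drawn from outside the packaged mapping excerpt.

Outputs are byte-deterministic for a fixed config: each subject draws from
its own seeded substream, so adding subjects never perturbs earlier ones.
"""

from __future__ import annotations

import datetime
import hashlib
import json
import random
from dataclasses import dataclass, field
from pathlib import Path

from .fhir_core import FhirResource, serialize_resource
from .terminology import ATC, EDI, SNOMED, load_default_edi_map

# (ATC code, display, strength mg, dose-form SNOMED code, dose-form display)
MED_POOL = [
    ("A02BC01", "Omeprazole", 20, "385055001", "Tablet"),
    ("N02BE01", "Paracetamol", 500, "385055001", "Tablet"),
    ("C09AA02", "Enalapril", 10, "385055001", "Tablet"),
    ("A10BA02", "Metformin", 500, "385055001", "Tablet"),
    ("J01CA04", "Amoxicillin", 250, "385049006", "Capsule"),
    ("C10AA01", "Simvastatin", 20, "385055001", "Tablet"),
    ("R06AE07", "Cetirizine", 10, "385055001", "Tablet"),
    ("M01AE01", "Ibuprofen", 200, "385055001", "Tablet"),
]

# (ATC vaccine code, display, target-disease SNOMED code, disease display)
VACCINE_POOL = [
    ("J07BB02", "Influenza, inactivated, split virus", "6142004", "Influenza"),
    ("J07BC01", "Hepatitis B vaccine", "66071002", "Viral hepatitis type B"),
    ("J07AL02", "Pneumococcus, purified polysaccharide", "16814004", "Pneumococcal infectious disease"),
    ("J07BH01", "Rotavirus, live attenuated", "18624000", "Disease due to Rotavirus"),
]

#: EDI codes with no entry in the packaged concept-map excerpt.
UNMAPPED_EDI_POOL = ["X9901", "X9902"]

_BASE_DATE = datetime.date(2024, 1, 15)


@dataclass
class Messiness:
    p_undefined_system: float = 1.0
    p_redundant_nested: float = 1.0
    p_missing_performed_date: float = 0.5
    p_unmapped_edi: float = 0.0

    def validate(self) -> None:
        for name, p in vars(self).items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be a probability, got {p}")


CLEAN = Messiness(0.0, 0.0, 0.0, 0.0)


@dataclass
class CohortConfig:
    n_subjects: int = 3
    snuh_subject_index: int | None = 0
    seed: int = 0
    messiness: Messiness = field(default_factory=Messiness)

    def validate(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.snuh_subject_index is not None and not (
            0 <= self.snuh_subject_index < self.n_subjects
        ):
            raise ValueError("snuh_subject_index out of range")
        self.messiness.validate()


@dataclass
class SubjectProfile:
    subject_id: str
    patient_id: str
    gender: str
    birth_date: str
    med: tuple
    vaccine: tuple
    procedures: list[tuple[str, str, str]]  # (edi code, display, iso date)


def _subject_rng(seed: int, index: int, stream: str) -> random.Random:
    return random.Random(f"{seed}:subject:{index}:{stream}")


def _date_str(rng: random.Random, spread_days: int = 300) -> str:
    return (_BASE_DATE - datetime.timedelta(days=rng.randrange(spread_days))).isoformat()


def build_subject(config: CohortConfig, index: int) -> SubjectProfile:
    rng = _subject_rng(config.seed, index, "profile")
    edi_map = load_default_edi_map()
    edi_codes = [(e.source_code, e.target_display or e.source_code) for e in edi_map.entries]
    procedures = []
    for _ in range(2):
        if rng.random() < config.messiness.p_unmapped_edi:
            code = rng.choice(UNMAPPED_EDI_POOL)
            display = "Local procedure"
        else:
            code, display = rng.choice(edi_codes)
        procedures.append((code, display, _date_str(rng)))
    return SubjectProfile(
        subject_id=f"subj-{index + 1}",
        patient_id=f"p-{index + 1}",
        gender=rng.choice(["male", "female"]),
        birth_date=f"{rng.randrange(1950, 2005)}-{rng.randrange(1, 13):02d}-{rng.randrange(1, 29):02d}",
        med=rng.choice(MED_POOL),
        vaccine=rng.choice(VACCINE_POOL),
        procedures=procedures,
    )


def _maybe(rng: random.Random, p: float) -> bool:
    return rng.random() < p


def _system(rng: random.Random, p_undef: float, proper: str) -> str:
    return "undefined" if _maybe(rng, p_undef) else proper


def _patient_tree(subject: SubjectProfile) -> dict:
    return {
        "resourceType": "Patient",
        "id": subject.patient_id,
        "gender": subject.gender,
        "birthDate": subject.birth_date,
    }


def _org_tree(org_id: str, name: str) -> dict:
    return {"resourceType": "Organization", "id": org_id, "name": name}


def _subject_reference(subject: SubjectProfile, rng: random.Random, m: Messiness, local: bool) -> dict:
    ref = {"reference": f"#{subject.patient_id}" if local else f"Patient/{subject.patient_id}"}
    if _maybe(rng, m.p_redundant_nested):
        # §-style pathology: full Patient details duplicated inside the
        # reference element itself.
        ref["resource"] = _patient_tree(subject)
    return ref


def generate_medication_dispense(subject: SubjectProfile, rng: random.Random, m: Messiness) -> FhirResource:
    """A messy app-export medication record (single MedicationDispense)."""
    atc, name, strength, form_code, form_display = subject.med
    p_undef = m.p_undefined_system
    med_id = f"med-{subject.subject_id}"
    med = {
        "resourceType": "Medication",
        "id": med_id,
        "code": {
            "coding": [{"system": _system(rng, p_undef, ATC), "code": atc, "display": name}],
            "text": name,
        },
        "form": {
            "coding": [
                {"system": _system(rng, p_undef, SNOMED), "code": form_code, "display": form_display}
            ],
            "text": form_display,
        },
        "ingredient": [
            {
                "itemCodeableConcept": {
                    "coding": [
                        {"system": _system(rng, p_undef, ATC), "code": atc, "display": name}
                    ],
                    "text": name,
                },
                "strength": {
                    "numerator": {"value": strength, "unit": "mg"},
                    "denominator": {"value": 1, "unit": form_display},
                },
            }
        ],
    }
    if _maybe(rng, p_undef):
        med["identifier"] = [{"system": "undefined", "value": f"KR-MED-{subject.subject_id}"}]
    tree = {
        "resourceType": "MedicationDispense",
        "id": f"md-{subject.subject_id}",
        "meta": {
            "versionId": "1",
            "lastUpdated": "2024-02-01T09:00:00Z",
            "source": "#SystemGenerated",
        },
        "contained": [
            _patient_tree(subject),
            _org_tree(f"org-{subject.subject_id}", "Community Pharmacy"),
            med,
        ],
        "status": "completed",
        "medicationReference": {"reference": f"#{med_id}"},
        "subject": _subject_reference(subject, rng, m, local=True),
        "whenHandedOver": _date_str(rng),
    }
    return FhirResource(tree)


def generate_immunization(subject: SubjectProfile, rng: random.Random, m: Messiness) -> FhirResource:
    """A messy app-export immunization record (single Immunization)."""
    code, display, disease_code, disease_display = subject.vaccine
    org_id = f"org-imm-{subject.subject_id}"
    tree = {
        "resourceType": "Immunization",
        "id": f"imm-{subject.subject_id}",
        "meta": {
            "versionId": "1",
            "lastUpdated": "2024-02-01T09:00:00Z",
            "source": "#SystemGenerated",
        },
        "contained": [
            _patient_tree(subject),
            _org_tree(org_id, "Public Health Center"),
        ],
        "status": "completed",
        "vaccineCode": {
            "coding": [
                {"system": _system(rng, m.p_undefined_system, ATC), "code": code, "display": display}
            ],
            "text": display,
        },
        "patient": _subject_reference(subject, rng, m, local=True),
        "occurrenceDateTime": _date_str(rng),
        "primarySource": True,
        "lotNumber": f"LOT-{rng.randrange(10000, 99999)}",
        "performer": [{"actor": {"reference": f"#{org_id}"}}],
        "note": [{"text": "auto-generated export note"}],
        "protocolApplied": [
            {
                "targetDisease": [
                    {"coding": [{"system": SNOMED, "code": disease_code, "display": disease_display}]}
                ],
                "doseNumberPositiveInt": 1,
            }
        ],
    }
    return FhirResource(tree)


def generate_snuh_bundle(subject: SubjectProfile, rng: random.Random, m: Messiness) -> FhirResource:
    """The hospital 'Medical MyData' collection Bundle: Patient,
    Organization, Encounter, MedicationRequest and EDI-coded Procedures."""
    if not subject.procedures or not subject.med:
        raise ValueError("subject needs at least one procedure and one medication")
    atc, name, strength, _fc, form_display = subject.med
    enc_id = f"enc-{subject.subject_id}"
    encounter_date = subject.procedures[0][2]
    entries = [
        _patient_tree(subject),
        _org_tree("org-snuh", "Seoul National University Hospital"),
        {
            "resourceType": "Encounter",
            "id": enc_id,
            "status": "finished",
            "class": {
                "system": "http://terminology.hl7.org/CodeSystem/v3-ActCode",
                "code": "AMB",
                "display": "ambulatory",
            },
            "subject": {"reference": f"Patient/{subject.patient_id}"},
            "period": {"start": encounter_date, "end": encounter_date},
            "serviceProvider": {"reference": "Organization/org-snuh"},
        },
        {
            "resourceType": "MedicationRequest",
            "id": f"mr-{subject.subject_id}",
            "meta": {"versionId": "3", "lastUpdated": "2024-02-02T10:30:00Z"},
            "status": "active",
            "intent": "order",
            "reportedBoolean": False,
            "medicationCodeableConcept": {
                "coding": [{"system": ATC, "code": atc, "display": name}],
                "text": name,
            },
            "subject": _subject_reference(subject, rng, m, local=False),
            "encounter": {"reference": f"Encounter/{enc_id}"},
            "authoredOn": encounter_date,
            "requester": {"reference": "Organization/org-snuh"},
            "identifier": [{"system": "https://snuh.org/order", "value": f"ORD-{rng.randrange(1000, 9999)}"}],
            "dosageInstruction": [
                {
                    "text": f"{strength} mg once daily",
                    "timing": {"repeat": {"frequency": 1, "period": 1, "periodUnit": "d"}},
                    "route": {
                        "coding": [{"system": SNOMED, "code": "26643006", "display": "Oral route"}]
                    },
                    "doseAndRate": [
                        {"doseQuantity": {"value": 1, "unit": form_display}}
                    ],
                    "site": {"text": "n/a"},
                }
            ],
        },
    ]
    for i, (code, display, date) in enumerate(subject.procedures):
        proc = {
            "resourceType": "Procedure",
            "id": f"proc-{subject.subject_id}-{i + 1}",
            "meta": {
                "versionId": "2",
                "lastUpdated": "2024-02-02T10:30:00Z",
                "source": "https://snuh.org",
                "profile": ["http://www.hl7korea.or.kr/fhir/krcore/StructureDefinition/krcore-procedure"],
            },
            "status": "completed",
            "code": {
                "coding": [{"system": EDI, "code": code, "display": display}],
                "text": display,
            },
            "subject": _subject_reference(subject, rng, m, local=False),
            "encounter": {"reference": f"Encounter/{enc_id}"},
        }
        if not _maybe(rng, m.p_missing_performed_date):
            proc["performedDateTime"] = date
        entries.append(proc)
    tree = {
        "resourceType": "Bundle",
        "id": f"snuh-{subject.subject_id}",
        "type": "collection",
        "entry": [{"resource": e} for e in entries],
    }
    return FhirResource(tree)


@dataclass
class CohortManifest:
    config: dict
    files: list[dict]

    def to_json(self) -> str:
        return json.dumps({"config": self.config, "files": self.files}, indent=2, ensure_ascii=False)


def generate_cohort(config: CohortConfig, out_dir) -> CohortManifest:
    """Write the cohort to *out_dir*; returns the manifest (also written as
    ``manifest.json``).  Same config ⇒ byte-identical files."""
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files: list[dict] = []

    def write(name: str, resource: FhirResource, subject: str) -> None:
        text = serialize_resource(resource) + "\n"
        path = out / name
        path.write_text(text, encoding="utf-8")
        files.append(
            {
                "path": name,
                "resource_type": resource.resource_type,
                "subject": subject,
                "sha256": hashlib.sha256(text.encode("utf-8")).hexdigest(),
            }
        )

    for i in range(config.n_subjects):
        subject = build_subject(config, i)
        rng_med = _subject_rng(config.seed, i, "medication")
        rng_imm = _subject_rng(config.seed, i, "immunization")
        write(
            f"{subject.subject_id}-medication.json",
            generate_medication_dispense(subject, rng_med, config.messiness),
            subject.subject_id,
        )
        write(
            f"{subject.subject_id}-immunization.json",
            generate_immunization(subject, rng_imm, config.messiness),
            subject.subject_id,
        )
        if config.snuh_subject_index == i:
            rng_snuh = _subject_rng(config.seed, i, "snuh")
            write(
                f"{subject.subject_id}-snuh-bundle.json",
                generate_snuh_bundle(subject, rng_snuh, config.messiness),
                subject.subject_id,
            )
    manifest = CohortManifest(
        config={
            "n_subjects": config.n_subjects,
            "snuh_subject_index": config.snuh_subject_index,
            "seed": config.seed,
            "messiness": vars(config.messiness),
        },
        files=files,
    )
    (out / "manifest.json").write_text(manifest.to_json() + "\n", encoding="utf-8")
    return manifest


def worked_example_procedure() -> FhirResource:
    """The worked-example hospital Procedure: EDI-coded, date recoverable
    only from its performedPeriod, subject held as a local contained Patient.

    Synthetic reconstruction — its EDI source code is the packaged
    placeholder whose official SNOMED CT target is 11466000.
    """
    return FhirResource(
        {
            "resourceType": "Procedure",
            "id": "proc-example",
            "meta": {
                "versionId": "1",
                "lastUpdated": "2024-02-02T10:30:00Z",
                "source": "https://snuh.org",
                "profile": ["http://www.hl7korea.or.kr/fhir/krcore/StructureDefinition/krcore-procedure"],
            },
            "contained": [
                {"resourceType": "Patient", "id": "p-example", "gender": "female", "birthDate": "1990-05-01"}
            ],
            "status": "completed",
            "code": {
                "coding": [{"system": EDI, "code": "R4519", "display": "Cesarean section"}],
                "text": "Cesarean section",
            },
            "subject": {"reference": "#p-example"},
            "performedPeriod": {"start": "2023-11-20", "end": "2023-11-20"},
        }
    )
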