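"""ETL orchestration: extract → transform → validate → load.

The load target is a directory of per-type NDJSON stores (one line per
resource), a run manifest, and JSON validation reports — diffable and
streamable.  Re-running with identical inputs and config reproduces an
identical store.  Duplicate source resources (same resourceType, id and
content hash) are removed once at extract time; the first occurrence wins.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path

from .errors import PipelineError, TransformError
from .fhir_core import FhirResource, parse_resource, write_ndjson
from .terminology import ConceptMapTable, load_concept_map
from .transform import (
    OUTPUT_RESOURCE_TYPES,
    TransformContext,
    expand_inputs,
    transform_all,
)
from .validate import validate_set

EXIT_OK = 0
EXIT_VALIDATION = 2
EXIT_TRANSFORM = 3
EXIT_IO = 4


@dataclass
class PipelineConfig:
    input_paths: list
    output_dir: Path
    mode: str = "lenient"  # strict | lenient
    concept_map_paths: list = field(default_factory=list)
    dedup: bool = True
    write_gap_report: bool = False

    def validate(self) -> None:
        if self.mode not in ("strict", "lenient"):
            raise PipelineError(f"unknown mode {self.mode!r}")
        if not self.input_paths:
            self.input_paths = []


@dataclass
class RunSummary:
    n_inputs: int = 0
    n_routed: int = 0
    n_transformed: dict = field(default_factory=dict)
    n_skipped: int = 0
    n_failed: int = 0
    n_dedup_removed: int = 0
    n_valid: int = 0
    n_error: int = 0
    n_warning: int = 0
    timings: dict = field(default_factory=dict)
    written_files: list = field(default_factory=list)
    status: str = "OK"
    exit_code: int = EXIT_OK

    @property
    def n_transformed_total(self) -> int:
        return sum(self.n_transformed.values())

    def to_dict(self) -> dict:
        return {
            "status": self.status,
            "exit_code": self.exit_code,
            "n_inputs": self.n_inputs,
            "n_routed": self.n_routed,
            "n_transformed": self.n_transformed,
            "n_transformed_total": self.n_transformed_total,
            "n_skipped": self.n_skipped,
            "n_failed": self.n_failed,
            "n_dedup_removed": self.n_dedup_removed,
            "n_valid": self.n_valid,
            "n_error": self.n_error,
            "n_warning": self.n_warning,
            "timings_s": self.timings,
            "written_files": self.written_files,
        }


def collect_input_files(paths) -> list[Path]:
    files: list[Path] = []
    for p in paths:
        p = Path(p)
        if p.is_dir():
            files.extend(
                sorted(f for f in p.glob("*.json") if not f.name.startswith("manifest"))
            )
        elif p.exists():
            files.append(p)
        else:
            raise PipelineError(f"input path does not exist: {p}")
    return files


def extract(paths, dedup: bool = True) -> tuple[list[FhirResource], int]:
    """Read and parse inputs (loose resources and bundles), deduplicating by
    (resourceType, id, content hash); returns (resources, n_removed)."""
    resources: list[FhirResource] = []
    for f in collect_input_files(paths):
        resources.append(parse_resource(f.read_text(encoding="utf-8")))
    resources = expand_inputs(resources)
    if not dedup:
        return resources, 0
    seen: set[tuple[str, str, str]] = set()
    unique: list[FhirResource] = []
    removed = 0
    for r in resources:
        key = (r.resource_type, r.id or "", r.content_hash())
        if key in seen:
            removed += 1
            continue
        seen.add(key)
        unique.append(r)
    return unique, removed


def _load_concept_map(config: PipelineConfig) -> ConceptMapTable | None:
    if not config.concept_map_paths:
        return None  # TransformContext falls back to the packaged excerpt
    entries = []
    for p in config.concept_map_paths:
        entries.extend(load_concept_map(p).entries)
    return ConceptMapTable(entries)


def run_etl(config: PipelineConfig) -> RunSummary:
    """Run the full pipeline; never raises for per-resource problems in
    lenient mode.  A failed run leaves a FAILED marker in the manifest."""
    config.validate()
    summary = RunSummary()
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    t0 = time.perf_counter()

    try:
        resources, summary.n_dedup_removed = extract(config.input_paths, config.dedup)
    except (PipelineError, OSError) as exc:
        summary.status, summary.exit_code = "FAILED", EXIT_IO
        _write_manifest(out_dir, summary, error=str(exc))
        return summary
    summary.n_inputs = len(resources)
    summary.timings["extract"] = round(time.perf_counter() - t0, 4)

    t1 = time.perf_counter()
    ctx = TransformContext(concept_map=_load_concept_map(config), mode=config.mode)
    try:
        reports = transform_all(resources, ctx)
    except TransformError as exc:
        summary.status, summary.exit_code = "FAILED", EXIT_TRANSFORM
        _write_manifest(out_dir, summary, error=str(exc))
        return summary
    summary.n_routed = len(reports)
    outputs = [r.output for r in reports if r.output is not None]
    summary.n_skipped = sum(
        1 for r in reports if r.output is None and not r.warnings
    )
    summary.n_failed = sum(1 for r in reports if r.output is None and r.warnings)
    for o in outputs:
        summary.n_transformed[o.resource_type] = summary.n_transformed.get(o.resource_type, 0) + 1
    summary.timings["transform"] = round(time.perf_counter() - t1, 4)

    t2 = time.perf_counter()
    vsummary = validate_set(outputs)
    summary.n_valid = vsummary.n_valid
    summary.n_error = vsummary.n_error
    summary.n_warning = vsummary.n_warning
    summary.timings["validate"] = round(time.perf_counter() - t2, 4)

    t3 = time.perf_counter()
    for rtype in OUTPUT_RESOURCE_TYPES:
        group = [o for o in outputs if o.resource_type == rtype]
        if group:
            path = out_dir / f"{rtype}.ndjson"
            write_ndjson(group, path)
            summary.written_files.append(path.name)
    (out_dir / "validation_report.json").write_text(
        vsummary.to_json() + "\n", encoding="utf-8"
    )
    summary.written_files.append("validation_report.json")
    if config.write_gap_report:
        from .gap_registry import compute_gap_report, load_default_registry

        (out_dir / "gap_report.json").write_text(
            compute_gap_report(load_default_registry()).to_json() + "\n", encoding="utf-8"
        )
        summary.written_files.append("gap_report.json")
    summary.timings["load"] = round(time.perf_counter() - t3, 4)

    if summary.n_failed and config.mode == "strict":
        summary.status, summary.exit_code = "FAILED", EXIT_TRANSFORM
    elif summary.n_error:
        summary.status = "VALIDATION_ERRORS"
        summary.exit_code = EXIT_VALIDATION
    _write_manifest(out_dir, summary)
    return summary


def _write_manifest(out_dir: Path, summary: RunSummary, error: str | None = None) -> None:
    doc = summary.to_dict()
    # timings vary run to run; the manifest keeps them out of the stable part
    doc.pop("timings_s", None)
    if error:
        doc["error"] = error
    (out_dir / "run_manifest.json").write_text(
        json.dumps(doc, indent=2, ensure_ascii=False) + "\n", encoding="utf-8"
    )
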