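"""Code-system canonicalization and local→international concept mapping.

Korean source exports identify code systems loosely — the literal strings
``"undefined"`` and ``"resource identifier (undefined)"`` are seen in the
wild — while the international profiles require canonical URIs (SNOMED CT,
LOINC, ATC, and the Korean KCD / HIRA-EDI identifiers).  This module makes
system identification total (:func:`canonicalize_system`) and implements
local→SNOMED code replacement as a pure, exact lookup over ConceptMap-style
tables (:func:`map_code`): a code is either in the table or reported
unmatched — it is never inferred.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources as importlib_resources
from typing import NamedTuple

import pandas as pd

from .errors import ConceptMapError

SNOMED = "http://snomed.info/sct"
LOINC = "http://loinc.org"
ATC = "http://www.whocc.no/atc"
KCD = "http://hl7.org/fhir/sid/icd-10-kr"
EDI = "https://hira.or.kr/CodeSystem/edi"

#: Marker for a system that cannot be resolved to a canonical URI.
UNKNOWN = "UNKNOWN"

_UNDEFINED_MARKERS = {"", "undefined", "resource identifier (undefined)", "#systemgenerated"}

EQUIVALENCES = ("equal", "wider", "narrower", "unmatched")
_CONCEPT_MAP_COLUMNS = [
    "source_system",
    "source_code",
    "target_system",
    "target_code",
    "target_display",
    "equivalence",
]


class Canonicalization(NamedTuple):
    """Result of system canonicalization; ``warning`` flags an unrecognized
    non-empty string (as opposed to a known 'undefined' marker)."""

    uri: str
    warning: bool


def _load_alias_table() -> dict[str, str]:
    path = importlib_resources.files("kips.data").joinpath("system_aliases.csv")
    df = pd.read_csv(path, dtype=str).fillna("")
    return {row["raw"].strip().lower(): row["canonical"] for _, row in df.iterrows()}


_ALIASES: dict[str, str] | None = None


def _aliases() -> dict[str, str]:
    global _ALIASES
    if _ALIASES is None:
        _ALIASES = _load_alias_table()
    return _ALIASES


def canonicalize_system(raw: str | None, extra_aliases: dict[str, str] | None = None) -> Canonicalization:
    """Map a raw system string to a canonical URI or :data:`UNKNOWN`.

    Total: never raises.  Known aliases (packaged table plus
    *extra_aliases*) resolve to their URI; the 'undefined' markers, empty
    and absent values resolve to UNKNOWN quietly; any other non-empty string
    resolves to UNKNOWN with ``warning=True``.
    """
    if raw is None:
        return Canonicalization(UNKNOWN, False)
    key = raw.strip().lower()
    if key in _UNDEFINED_MARKERS:
        return Canonicalization(UNKNOWN, False)
    table = _aliases()
    if extra_aliases:
        table = {**table, **{k.strip().lower(): v for k, v in extra_aliases.items()}}
    if key in table:
        return Canonicalization(table[key], False)
    return Canonicalization(UNKNOWN, True)


@dataclass(frozen=True)
class ConceptMapEntry:
    source_system: str
    source_code: str
    target_system: str
    target_code: str
    target_display: str | None
    equivalence: str

    @property
    def matched(self) -> bool:
        return self.equivalence != "unmatched"


def unmatched_entry(system: str, code: str) -> ConceptMapEntry:
    """Marker for a lookup miss, carrying the queried key."""
    return ConceptMapEntry(system, code, "", "", None, "unmatched")


class ConceptMapTable:
    """(source_system, source_code) → target lookup with no duplicates."""

    def __init__(self, entries: list[ConceptMapEntry]):
        self._index: dict[tuple[str, str], ConceptMapEntry] = {}
        for e in entries:
            key = (e.source_system, e.source_code)
            if key in self._index:
                raise ConceptMapError(f"duplicate concept-map key: {key}")
            if not e.source_system or not e.source_code:
                raise ConceptMapError(f"empty source key in entry: {e}")
            if e.matched and (not e.target_system or not e.target_code):
                raise ConceptMapError(f"matched entry lacks target: {e}")
            self._index[key] = e
        self.entries = list(self._index.values())

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, key: tuple[str, str]) -> bool:
        return key in self._index

    def lookup(self, system: str, code: str) -> ConceptMapEntry | None:
        return self._index.get((system, code))

    def source_codes(self, system: str) -> list[str]:
        return [e.source_code for e in self.entries if e.source_system == system]


def map_code(table: ConceptMapTable, system: str, code: str) -> ConceptMapEntry:
    """Exact-key lookup: the entry on a hit, an unmatched marker on a miss.

    No fuzzy matching and no inference — replacement codes come from the
    official mapping table or not at all.
    """
    hit = table.lookup(system, code)
    return hit if hit is not None else unmatched_entry(system, code)


def load_concept_map(path) -> ConceptMapTable:
    """Load a ConceptMap CSV (columns: source_system, source_code,
    target_system, target_code, target_display, equivalence)."""
    try:
        df = pd.read_csv(path, dtype=str)
    except FileNotFoundError:
        raise ConceptMapError(f"concept map not found: {path}") from None
    missing = [c for c in _CONCEPT_MAP_COLUMNS if c not in df.columns]
    if missing:
        raise ConceptMapError(f"concept map {path} missing columns: {missing}")
    df = df.fillna("")
    entries = []
    for _, row in df.iterrows():
        eq = row["equivalence"] or "equal"
        if eq not in EQUIVALENCES:
            raise ConceptMapError(f"bad equivalence {eq!r} for {row['source_code']!r}")
        entries.append(
            ConceptMapEntry(
                source_system=row["source_system"],
                source_code=row["source_code"],
                target_system=row["target_system"],
                target_code=row["target_code"],
                target_display=row["target_display"] or None,
                equivalence=eq,
            )
        )
    return ConceptMapTable(entries)


def load_default_edi_map() -> ConceptMapTable:
    """Packaged HIRA-EDI→SNOMED CT excerpt.

    Synthetic-representative rows (the full published table is ~11k items);
    includes the worked-example pair whose SNOMED target is 11466000.
    """
    return load_concept_map(importlib_resources.files("kips.data").joinpath("concept_map_edi_snomed.csv"))


def load_default_kcd_map() -> ConceptMapTable:
    """Packaged KCD→SNOMED CT excerpt (synthetic-representative rows)."""
    return load_concept_map(importlib_resources.files("kips.data").joinpath("concept_map_kcd_snomed.csv"))
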