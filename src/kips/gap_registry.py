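"""Machine-readable IPS↔KR Core gap registry and coverage statistics.

The registry encodes, as data: the seven IPS components (three required —
Allergies and Intolerances, Medication Summary, Problems — and four
recommended — Results, History of Procedures, Immunizations, Medical
Devices) with their IPS profiles; the profile-level mapping to the KR Core
implementation guide, where an empty KR side means NO MATCH (the Medical
Devices profiles and MedicationStatement have no KR Core counterpart); and
the per-profile code-system discrepancies (SNOMED CT vs EDI for procedures,
LOINC vs EDI for diagnostic reports, SNOMED CT vs KCD for conditions, with
ATC agreeing on both sides for allergies and medications).

Coverage is computed, never hard-coded: a component counts as mapped iff at
least one of its IPS profiles has at least one KR Core mapping.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from importlib import resources as importlib_resources

import pandas as pd

from .errors import RegistryError

TIERS = ("required", "recommended")


@dataclass(frozen=True)
class IpsComponent:
    name: str
    tier: str
    ips_profiles: tuple[str, ...]


@dataclass(frozen=True)
class ProfileMapping:
    ips_profile: str
    kr_profiles: tuple[str, ...]

    @property
    def cardinality(self) -> str:
        n = len(self.kr_profiles)
        return "unmapped" if n == 0 else ("one_to_one" if n == 1 else "one_to_many")


@dataclass(frozen=True)
class CodeSystemDelta:
    ips_profile: str
    ips_system: str
    kr_system: str

    @property
    def agrees(self) -> bool:
        return self.ips_system == self.kr_system


@dataclass
class Registry:
    components: list[IpsComponent]
    mappings: dict[str, ProfileMapping]
    deltas: list[CodeSystemDelta]

    def component(self, name: str) -> IpsComponent:
        for c in self.components:
            if c.name == name:
                return c
        raise RegistryError(f"unknown component: {name}")


@dataclass
class GapReport:
    n_components: int
    n_components_mapped: int
    component_coverage_pct: int
    n_ips_profiles_mapped: int
    unmapped_ips_profiles: list[str]
    kr_profiles_referenced: list[str]
    deltas: list[CodeSystemDelta] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "n_components": self.n_components,
            "n_components_mapped": self.n_components_mapped,
            "component_coverage_pct": self.component_coverage_pct,
            "n_ips_profiles_mapped": self.n_ips_profiles_mapped,
            "unmapped_ips_profiles": self.unmapped_ips_profiles,
            "kr_profiles_referenced": self.kr_profiles_referenced,
            "code_system_deltas": [
                {
                    "ips_profile": d.ips_profile,
                    "ips_system": d.ips_system,
                    "kr_system": d.kr_system,
                    "agrees": d.agrees,
                }
                for d in self.deltas
            ],
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, ensure_ascii=False)

    def to_text(self) -> str:
        lines = [
            "IPS / KR Core gap report",
            "------------------------",
            f"components:            {self.n_components}",
            f"components mapped:     {self.n_components_mapped}",
            f"component coverage:    {self.component_coverage_pct}%",
            f"IPS profiles mapped:   {self.n_ips_profiles_mapped}",
            "unmapped IPS profiles: " + (", ".join(self.unmapped_ips_profiles) or "(none)"),
            f"KR Core profiles referenced: {len(self.kr_profiles_referenced)}",
            "code-system deltas:",
        ]
        for d in self.deltas:
            mark = "agrees" if d.agrees else "DIFFERS"
            lines.append(f"  {d.ips_profile}: {d.ips_system} vs {d.kr_system} [{mark}]")
        return "\n".join(lines)


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def load_registry(components_path=None, mappings_path=None, deltas_path=None) -> Registry:
    """Load a registry from CSV files; defaults to the packaged tables."""
    data = importlib_resources.files("kips.data")
    components_path = components_path or data.joinpath("components.csv")
    mappings_path = mappings_path or data.joinpath("mappings.csv")
    deltas_path = deltas_path or data.joinpath("deltas.csv")

    try:
        comp_df = pd.read_csv(components_path, dtype=str)
        map_df = pd.read_csv(mappings_path, dtype=str)
        delta_df = pd.read_csv(deltas_path, dtype=str)
    except FileNotFoundError as exc:
        raise RegistryError(f"registry file missing: {exc}") from exc

    for df, cols, name in (
        (comp_df, ["component", "tier", "ips_profile"], components_path),
        (map_df, ["ips_profile", "kr_profile"], mappings_path),
        (delta_df, ["ips_profile", "ips_system", "kr_system"], deltas_path),
    ):
        missing = [c for c in cols if c not in df.columns]
        if missing:
            raise RegistryError(f"{name}: missing columns {missing}")

    components: list[IpsComponent] = []
    seen_profiles: set[str] = set()
    for name, grp in comp_df.groupby("component", sort=False):
        tiers = set(grp["tier"])
        if len(tiers) != 1 or tiers - set(TIERS):
            raise RegistryError(f"component {name!r} has bad tier(s): {tiers}")
        profiles = tuple(grp["ips_profile"])
        dup = seen_profiles & set(profiles)
        if dup:
            raise RegistryError(f"IPS profile(s) listed under two components: {dup}")
        seen_profiles |= set(profiles)
        components.append(IpsComponent(name, tiers.pop(), profiles))

    map_df = map_df.fillna("")
    mappings: dict[str, ProfileMapping] = {}
    for prof, grp in map_df.groupby("ips_profile", sort=False):
        kr = tuple(k for k in grp["kr_profile"] if k)
        mappings[prof] = ProfileMapping(prof, kr)

    deltas = [
        CodeSystemDelta(row["ips_profile"], row["ips_system"], row["kr_system"])
        for _, row in delta_df.iterrows()
    ]
    return Registry(components, mappings, deltas)


def load_default_registry() -> Registry:
    return load_registry()


def compute_gap_report(registry: Registry) -> GapReport:
    """Coverage statistics; pure function of the registry."""
    if not registry.components:
        raise RegistryError("undefined coverage: registry has no components")

    def profile_mapped(profile: str) -> bool:
        m = registry.mappings.get(profile)
        return m is not None and len(m.kr_profiles) > 0

    n_components = len(registry.components)
    n_mapped = sum(
        1 for c in registry.components if any(profile_mapped(p) for p in c.ips_profiles)
    )
    all_profiles = [p for c in registry.components for p in c.ips_profiles]
    mapped_profiles = [p for p in all_profiles if profile_mapped(p)]
    unmapped = [p for p in all_profiles if not profile_mapped(p)]
    kr_referenced: list[str] = []
    for p in all_profiles:
        for kr in registry.mappings.get(p, ProfileMapping(p, ())).kr_profiles:
            if kr not in kr_referenced:
                kr_referenced.append(kr)
    return GapReport(
        n_components=n_components,
        n_components_mapped=n_mapped,
        component_coverage_pct=_round_half_away(100.0 * n_mapped / n_components),
        n_ips_profiles_mapped=len(mapped_profiles),
        unmapped_ips_profiles=unmapped,
        kr_profiles_referenced=kr_referenced,
        deltas=list(registry.deltas),
    )


def code_system_delta(registry: Registry, ips_profile: str) -> list[CodeSystemDelta]:
    """Deltas recorded for one IPS profile (empty list if none)."""
    known = {p for c in registry.components for p in c.ips_profiles}
    if ips_profile not in known:
        raise RegistryError(f"unknown IPS profile: {ips_profile}")
    return [d for d in registry.deltas if d.ips_profile == ips_profile]
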