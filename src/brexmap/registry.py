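"""Controlled domain vocabulary and the component rule table.

The registry maps each domain name to a synthetic signature block (used by
the signature matcher on generated proteins) and a family class. Component
rules map ordered domain architectures onto canonical component names; they
encode the domain grammars of the BREX, BR and BRC systems.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from functools import lru_cache


@dataclass(frozen=True)
class DomainEntry:
    name: str
    signature: str
    family_class: str
    description: str = ""
    walker_intact: bool | None = None


class DomainRegistry:
    """Domain name -> signature/family lookup, loaded from a JSON resource."""

    def __init__(self, entries: dict[str, DomainEntry], version: str = "custom"):
        self.entries = entries
        self.version = version

    def __contains__(self, name: str) -> bool:
        return name in self.entries

    def __getitem__(self, name: str) -> DomainEntry:
        return self.entries[name]

    def __iter__(self):
        return iter(self.entries.values())

    def __len__(self) -> int:
        return len(self.entries)

    @classmethod
    def from_json(cls, text: str) -> "DomainRegistry":
        raw = json.loads(text)
        entries = {
            name: DomainEntry(
                name=name,
                signature=rec["signature"],
                family_class=rec["family_class"],
                description=rec.get("description", ""),
                walker_intact=rec.get("walker_intact"),
            )
            for name, rec in raw["entries"].items()
        }
        return cls(entries, version=raw.get("registry_version", "?"))


@lru_cache(maxsize=1)
def default_registry() -> DomainRegistry:
    text = (
        resources.files("brexmap.data").joinpath("domain_registry.json").read_text()
    )
    return DomainRegistry.from_json(text)


@dataclass(frozen=True)
class ComponentRule:
    """One architecture -> component mapping.

    ``mandatory`` must appear as an ordered subsequence of the architecture's
    domain list (extra, uncalled segments are tolerated: lineage-specific
    insertions are common). ``exact`` rules instead require the architecture
    to consist of nothing but the listed domains (with ``max_repeat`` allowed
    repetitions for single-domain exact rules). ``flag_domains`` map optional
    domains to fusion flags. ``tier`` orders rules most-specific-first;
    evaluation order within a tier must not matter.
    """

    component: str
    mandatory: tuple[str, ...]
    tier: int
    forbidden: frozenset[str] = frozenset()
    optional: tuple[str, ...] = ()
    flag_domains: tuple[tuple[str, str], ...] = ()
    exact: bool = False
    min_repeat: int = 1
    max_repeat: int = 1
    fixed_flags: tuple[str, ...] = ()


# Ordered most-specific-first. Tier = rules whose relative order is immaterial.
COMPONENT_RULES: tuple[ComponentRule, ...] = (
    ComponentRule(
        "PglW",
        ("NERD", "pseudokinase", "STY_kinase", "RNApolA_CTD", "wHTH", "wHTH", "wHTH", "iSTAND"),
        tier=0,
    ),
    ComponentRule(
        "DUF499_ATPase",
        ("AAA_ATPase", "wHTH", "alphabeta_core", "wHTH", "RRM"),
        tier=1,
        optional=("FnIII",),
        flag_domains=(("HEPN", "DUF499:HEPN_fused"),),
    ),
    ComponentRule(
        "BrxHI",
        ("Ski2_helicase", "wHTH", "HAS_barrel", "Lhr_CTD"),
        tier=1,
    ),
    ComponentRule(
        "BrxXI",
        ("N6_MTase", "TRD_nested", "HTH", "wHTH", "HTH"),
        tier=1,
        forbidden=frozenset({"DUF1156_helical"}),
    ),
    ComponentRule(
        "BrxC",
        ("AAA_ATPase", "wHTH", "alphabeta_core", "wHTH"),
        tier=2,
        forbidden=frozenset({"RRM"}),
        optional=("coiledcoil", "terminal_subdomain"),
    ),
    ComponentRule(
        "BR_MTase",
        ("DUF1156_helical", "N6_MTase", "TRD_nested"),
        tier=2,
        optional=("HTH",),
    ),
    ComponentRule(
        "BrxX",
        ("N_helical_bundle", "N6_MTase", "TRD_Cterm"),
        tier=2,
        optional=("wHTH", "coiledcoil_ext"),
    ),
    ComponentRule(
        "BrxL",
        ("SIGMA_HTH", "OB_fold", "MCM_ATPase"),
        tier=2,
        flag_domains=(("LonP", "BrxL:LonP"), ("HKD", "BrxL:HKD")),
    ),
    ComponentRule(
        "BrxHII",
        ("Swi2Snf2_helicase",),
        tier=3,
        forbidden=frozenset({"iSwi2Snf2", "PglZ_core"}),
        optional=("TUDOR", "iREase", "alphabeta_CTD"),
        flag_domains=(("HKD", "helicase:HKD_fused"), ("REase", "helicase:REase_fused")),
    ),
    ComponentRule(
        "PglZ",
        ("helical_linker", "PglZ_core"),
        tier=3,
        optional=("iSwi2Snf2", "HTH", "beta_sandwich", "wHTH"),
        flag_domains=(("iSTAND", "PglZ:iSTAND_fused"),),
    ),
    ComponentRule(
        "BrxP",
        ("PAPS_reductase",),
        tier=3,
        optional=("DUF1795", "ferredoxin_4Fe4S"),
        flag_domains=(("DUF4007_HTH", "BrxP:DUF4007_fused"),),
    ),
    ComponentRule(
        "DUF3780",
        ("DUF3780_core",),
        tier=3,
        flag_domains=(("ASCH_PUA", "DUF3780:ASCH_PUA"), ("RAMA", "DUF3780:RAMA")),
    ),
    ComponentRule(
        "ZnHTH",
        ("zinc_finger", "HTH"),
        tier=3,
    ),
    # PglZ without the helical linker: the reduced BRC-style architecture.
    ComponentRule(
        "PglZ",
        ("PglZ_core",),
        tier=4,
        forbidden=frozenset({"helical_linker"}),
        optional=("iSwi2Snf2",),
        fixed_flags=("PglZ:minimal",),
    ),
    ComponentRule("CysDesulf", ("cysteine_desulfurase",), tier=5, exact=True),
    ComponentRule("HerA_FtsK", ("HerA_FtsK_translocase",), tier=5, exact=True),
    ComponentRule("GNAT", ("GNAT_acetyltransferase",), tier=5, exact=True),
    ComponentRule("TGT", ("TGT_core",), tier=5, exact=True),
    ComponentRule("BrxE", ("BrxE_signature",), tier=5, exact=True),
    ComponentRule("BrxD", ("AAA_ATPase",), tier=5, exact=True),
    ComponentRule("STAND_active", ("STAND_walker",), tier=5, exact=True),
    ComponentRule("iSTAND", ("iSTAND",), tier=5, exact=True),
    ComponentRule("BrxA", ("BrxA_HTH",), tier=5, exact=True, min_repeat=2, max_repeat=3),
    ComponentRule("DUF4007", ("DUF4007_HTH",), tier=5, exact=True, min_repeat=2, max_repeat=3),
    # standalone effector proteins keep their domain name as the component
    *[
        ComponentRule(dom, (dom,), tier=6, exact=True)
        for dom in (
            "PDDExK_REase", "NERD", "Shedu_REase", "HNH", "ParB_HNH", "SRA_HNH",
            "HKD", "TOPRIM", "OLD_ABC", "HEPN", "MNT", "PIN", "Schlafen_kinase_wHTH",
        )
    ],
)

# Effector role ontology (fixed, not inferred): primary restriction nucleases
# per subtype, reinforcing DNases, and RNase/abortive fail-safe modules.
DNASE_EFFECTOR_DOMAINS = frozenset({
    "PDDExK_REase", "NERD", "Shedu_REase", "REase",
    "HNH", "ParB_HNH", "SRA_HNH", "HKD", "TOPRIM",
})
RNASE_BACKUP_DOMAINS = frozenset({"HEPN", "MNT", "PIN", "Schlafen_kinase_wHTH"})
EFFECTOR_DOMAINS = DNASE_EFFECTOR_DOMAINS | RNASE_BACKUP_DOMAINS | {"OLD_ABC"}
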