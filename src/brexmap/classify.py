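"""System taxonomy: subtype classification and effector cataloguing.

Classification is an ordered decision list over the component inventory of
a locus. The uniquely diagnostic anchors are tested first (HerA/FtsK for
BRC, DUF499 for the BR family) before the BREX subtypes, because PglZ and
BrxC-like ATPases are shared across systems. Types 5 and 6 collapse into
the Type-1 family group: their composition differs from Type-1 only by an
extra helicase (Type-5) or BrxE (Type-6).

Effector roles are a fixed ontology, not a computation: the primary
restriction nuclease per subtype (PglZ for every BREX subtype and Type-3
BR; the helicase-fused REase in Type-1 BR and helicase-fused HKD in
Type-2 BR), auxiliary DNases reinforcing restriction, and backup
RNase/abortive modules (HEPN+-MNT, PIN, Schlafen, OLD-ABC-paired dyads).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

from .model import Architecture, ComponentCall, EffectorRecord, Locus, SystemCall
from .registry import DNASE_EFFECTOR_DOMAINS, RNASE_BACKUP_DOMAINS

MTASE_COMPONENTS = frozenset({"BrxX", "BrxXI", "BR_MTase"})

# grammar-mandatory components per subtype (post-aliasing names)
MANDATORY: dict[str, frozenset[str]] = {
    "Type-1": frozenset({"BrxC", "BrxX", "PglZ", "BrxA", "BrxB", "BrxL"}),
    "Type-2": frozenset({"PglW", "BrxC", "BrxX", "PglZ", "BrxD", "BrxHI"}),
    "Type-3": frozenset({"BrxC", "BrxXI", "PglZ", "BrxF", "BrxHII"}),
    "Type-4": frozenset({"BrxC", "PglZ", "BrxP", "DUF4007", "BrxL", "CysDesulf"}),
    "Type-5": frozenset({"BrxC", "BrxX", "PglZ", "BrxA", "BrxB", "BrxL", "BrxHII"}),
    "Type-6": frozenset({"BrxC", "BrxX", "PglZ", "BrxA", "BrxB", "BrxL", "BrxE"}),
    "Type-1 BR": frozenset({"DUF499_ATPase", "BR_MTase", "BrxHII"}),
    "Type-2 BR": frozenset({"DUF499_ATPase", "BR_MTase", "BrxHII", "DUF3780"}),
    "Type-3 BR": frozenset({"DUF499_ATPase", "BR_MTase", "BrxHII", "PglZ", "iSTAND"}),
    "BRC": frozenset(
        {"PglZ", "BrxC", "STAND_active", "DUF4007", "HerA_FtsK", "GNAT", "TGT"}
    ),
}

SYSTEM_OF = {
    **{f"Type-{i}": "BREX" for i in range(1, 7)},
    **{f"Type-{i} BR": "BR" for i in range(1, 4)},
    "BRC": "BRC",
}

# subtype-contextual names of the standalone inactive STAND component
_ISTAND_ALIAS = {"Type-1": "BrxB", "Type-5": "BrxB", "Type-6": "BrxB", "Type-3": "BrxF"}


@dataclass(frozen=True)
class LocusComponents:
    """Component inventory of a locus, as consumed by the decision list."""

    components: frozenset[str]
    flags: frozenset[str]

    @classmethod
    def from_calls(cls, calls: dict[str, ComponentCall]) -> "LocusComponents":
        comps = {c.component for c in calls.values() if c.component != "unknown"}
        flags = {f for c in calls.values() for f in c.fusion_flags}
        return cls(frozenset(comps), frozenset(flags))


def _decide_subtype(c: frozenset[str], f: frozenset[str]) -> tuple[str, set[str]]:
    """The ordered decision list; returns (subtype, review flags)."""
    review: set[str] = set()
    if "HerA_FtsK" in c and "PglZ" in c and ({"BrxC", "DUF499_ATPase"} & c):
        return "BRC", review
    if "DUF499_ATPase" in c:
        if "PglZ" in c:
            return "Type-3 BR", review
        if "DUF3780" in c or "helicase:HKD_fused" in f:
            return "Type-2 BR", review
        return "Type-1 BR", review
    if "BrxP" in c and not (MTASE_COMPONENTS & c):
        return "Type-4", review
    if "PglW" in c or {"BrxD", "BrxHI"} <= c:
        return "Type-2", review
    if "BrxXI" in c or ({"iSTAND", "BrxHII"} <= c and "BrxX" not in c):
        return "Type-3", review
    if {"BrxC", "BrxX", "PglZ"} <= c:
        if "BrxE" in c:
            if "BrxHII" in c:
                review.add("type6_with_extra_helicase")
            return "Type-6", review
        if "BrxHII" in c:
            return "Type-5", review
        return "Type-1", review
    return "NA", review


def classify_locus(locus: Locus) -> SystemCall:
    """Classify one component-annotated locus.

    After subtype assignment the standalone iSTAND component is renamed to
    its subtype-contextual homolog (BrxB in the Type-1 family, BrxF in
    Type-3), and completeness is graded against the subtype's mandatory
    component set: complete when all are present, partial when at least 3
    components including the anchor are present, discarded otherwise.
    """
    inv = LocusComponents.from_calls(locus.component_calls)
    subtype, review = _decide_subtype(inv.components, inv.flags)
    components = set(inv.components)
    if subtype in _ISTAND_ALIAS and "iSTAND" in components:
        components.remove("iSTAND")
        components.add(_ISTAND_ALIAS[subtype])

    if subtype == "NA":
        system, family = "unassigned", "other"
        completeness = "discarded"
        missing: frozenset[str] = frozenset()
    else:
        system = SYSTEM_OF[subtype]
        family = "Type-1-family" if subtype in ("Type-1", "Type-5", "Type-6") else "other"
        mandatory = MANDATORY[subtype]
        missing = frozenset(mandatory - components)
        anchor_call = locus.component_calls.get(locus.anchor_gene_id)
        anchor_comp = anchor_call.component if anchor_call else "unknown"
        if anchor_comp == "iSTAND" and subtype in _ISTAND_ALIAS:
            anchor_comp = _ISTAND_ALIAS[subtype]
        if not missing:
            completeness = "complete"
        elif len(components & mandatory) >= 3 and anchor_comp in mandatory:
            completeness = "partial"
        else:
            completeness = "discarded"
    return SystemCall(
        locus_id=locus.locus_id,
        system=system,
        subtype=subtype if subtype != "NA" else "NA",
        family_group=family,
        completeness=completeness,
        components_present=frozenset(components),
        missing_core=missing,
        fusion_flags=inv.flags,
        review_flags=frozenset(review),
    )


def _primary_spec(call: SystemCall) -> tuple[str, str] | None:
    """(carrier component, effector domain) of the subtype's primary nuclease."""
    if call.system == "BREX" or call.subtype == "Type-3 BR":
        if "PglZ" in call.components_present:
            return ("PglZ", "PglZ_core")
        return None
    if call.subtype == "Type-1 BR" and "helicase:REase_fused" in call.fusion_flags:
        return ("BrxHII", "REase")
    if call.subtype == "Type-2 BR" and "helicase:HKD_fused" in call.fusion_flags:
        return ("BrxHII", "HKD")
    return None


def catalog_effectors(
    locus: Locus,
    call: SystemCall,
    architectures: dict[str, Architecture],
    flanking_genes: list[str] | None = None,
) -> list[EffectorRecord]:
    """Catalog primary/auxiliary/backup effectors of one classified locus.

    Provenance: an effector domain inside a multi-domain core component is
    a ``core_component_fusion``; a standalone effector gene in the anchor's
    operon block is ``standalone_in_locus``; genes in admitted neighboring
    blocks (or supplied as flanking) are ``flanking``. A nuclease gene
    adjacent to an OLD-ABC gene forms a backup dyad regardless of its
    domain class.
    """
    calls = locus.component_calls
    anchor_block = next(
        (b for b in locus.blocks if any(g.gene_id == locus.anchor_gene_id for g in b.genes)),
        None,
    )
    anchor_ids = {g.gene_id for g in anchor_block.genes} if anchor_block else set()
    member_order = [g.gene_id for g in locus.member_genes]
    flanking = set(flanking_genes or [])

    def provenance_of(gene_id: str, fused: bool) -> str:
        if fused:
            return "core_component_fusion"
        if gene_id in flanking or gene_id not in anchor_ids:
            return "flanking"
        return "standalone_in_locus"

    # genes adjacent to an OLD_ABC carrier form backup dyads
    old_abc_ids = {
        gid for gid, c in calls.items() if c.component == "OLD_ABC"
    }
    # a dyad is a co-transcribed pair: the partner must share the OLD_ABC
    # gene's operon block and be a standalone nuclease gene (a core
    # component with a fused nuclease domain keeps its own role)
    block_of = {g.gene_id: bi for bi, b in enumerate(locus.blocks) for g in b.genes}
    dyad_ids: set[str] = set()
    for gid in old_abc_ids:
        i = member_order.index(gid)
        for j in (i - 1, i + 1):
            if 0 <= j < len(member_order):
                neighbor = member_order[j]
                if block_of.get(neighbor) != block_of.get(gid):
                    continue
                comp = calls[neighbor].component if neighbor in calls else "unknown"
                if comp in DNASE_EFFECTOR_DOMAINS or comp in RNASE_BACKUP_DOMAINS:
                    dyad_ids.add(gid)
                    dyad_ids.add(neighbor)

    records: list[EffectorRecord] = []
    primary = _primary_spec(call)
    if primary is not None:
        carrier_comp, domain = primary
        carrier = next(
            (gid for gid, c in calls.items() if c.component == carrier_comp), None
        )
        if carrier is not None:
            records.append(
                EffectorRecord(locus.locus_id, domain, carrier, "primary", "core_component_fusion")
            )

    for gid in member_order:
        arch = architectures.get(gid)
        if arch is None:
            continue
        comp = calls[gid].component if gid in calls else "unknown"
        for dom in arch.domain_names:
            if primary is not None and comp == primary[0] and dom == primary[1]:
                continue  # the primary instance is not re-counted as auxiliary
            fused = comp not in (dom, "unknown") and len(arch.domains) > 1
            if gid in dyad_ids and (
                dom in DNASE_EFFECTOR_DOMAINS or dom in RNASE_BACKUP_DOMAINS or dom == "OLD_ABC"
            ):
                records.append(
                    EffectorRecord(locus.locus_id, dom, gid, "backup", provenance_of(gid, False))
                )
            elif dom in DNASE_EFFECTOR_DOMAINS:
                records.append(
                    EffectorRecord(
                        locus.locus_id, dom, gid, "auxiliary", provenance_of(gid, fused)
                    )
                )
            elif dom in RNASE_BACKUP_DOMAINS:
                records.append(
                    EffectorRecord(locus.locus_id, dom, gid, "backup", provenance_of(gid, fused))
                )
    return records


def summarize_cohort(
    calls: list[SystemCall], inventories: list[EffectorRecord]
) -> dict:
    """Cohort report: per-subtype counts, component retention, effector
    class totals and a reason-coded discarded-locus log."""
    subtype_counts = Counter(c.subtype for c in calls)
    completeness_counts = Counter(c.completeness for c in calls)
    component_counts: Counter = Counter()
    for c in calls:
        component_counts.update(c.components_present)
    role_counts = Counter(e.role for e in inventories)
    domain_counts = Counter(e.effector_domain for e in inventories)
    discarded = [
        {
            "locus_id": c.locus_id,
            "reason": (
                "unassigned" if c.system == "unassigned" else
                f"missing_core:{','.join(sorted(c.missing_core))}"
            ),
        }
        for c in calls
        if c.completeness == "discarded"
    ]
    return {
        "n_loci": len(calls),
        "subtype_counts": dict(sorted(subtype_counts.items())),
        "completeness_counts": dict(sorted(completeness_counts.items())),
        "component_counts": dict(sorted(component_counts.items())),
        "effector_role_counts": dict(sorted(role_counts.items())),
        "effector_domain_counts": dict(sorted(domain_counts.items())),
        "discarded": discarded,
    }
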