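"""Synthetic genome cohorts with planted defense operons and known truth.

Each subtype has an operon grammar listing its component slots in gene
order. A planted protein is a concatenation of the registry signature
blocks of its domains, separated by low-complexity linkers, so the
signature matcher can recover the architecture exactly in noiseless mode.
Decoy genes carry a periodic tryptophan lattice and therefore share no
signature k-mers with the registry (signatures avoid W by construction).

Planted loci are isolated from decoys by five times the locus gap
threshold, so truth loci are unambiguous for any configured threshold at
or below that margin. A single seeded RNG stream is sub-streamed per
genome, making output byte-identical for a fixed seed regardless of
generation order.
"""

from __future__ import annotations

import json
import zlib
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .entropy import chem8_map, identity20_map, reduce_alphabet, column_entropy
from .genbank_io import LINEAGE_RANKS, write_fasta, write_genbank
from .model import GeneRecord, GenomeRecord
from .registry import DomainRegistry, default_registry

LINKER_ALPHABET = "GSATNP"
LINKER_LEN = 15
DECOY_W_STRIDE = 8
ISOLATION_FACTOR = 5  # planted-locus isolation gap = factor * max_gap_nt
DEFAULT_MAX_GAP = 100

AA20 = "ACDEFGHIKLMNPQRSTVWY"


# --- grammar definitions ---------------------------------------------------

@dataclass(frozen=True)
class ProteinSpec:
    component: str
    domains: tuple[str, ...]
    flags: tuple[str, ...] = ()
    effectors: tuple[tuple[str, str, str], ...] = ()  # (domain, role, provenance)


@dataclass(frozen=True)
class SlotVariant:
    weight: float
    proteins: tuple[ProteinSpec, ...]


@dataclass(frozen=True)
class ComponentSlot:
    name: str
    variants: tuple[SlotVariant, ...]
    probability: float = 1.0
    placement: str = "core"  # "core" | "flank"
    core: bool = True  # grammar-mandatory component

    def __post_init__(self) -> None:
        if not (0.0 <= self.probability <= 1.0):
            raise ValueError(f"slot {self.name}: probability outside [0,1]")
        if self.core and self.probability < 1.0:
            raise ValueError(f"slot {self.name}: core slots must have probability 1")


@dataclass(frozen=True)
class OperonGrammar:
    system: str  # BREX | BR | BRC
    subtype: str
    slots: tuple[ComponentSlot, ...]
    strand_policy: str = "same"  # "same" | "blocks"
    gap_range: tuple[int, int] = (5, 80)
    flank_gap_range: tuple[int, int] = (20, 90)

    def __post_init__(self) -> None:
        if max(self.gap_range) > DEFAULT_MAX_GAP:
            raise ValueError("intra-operon gaps must stay at or below the gap threshold")


def _slot(component: str, domains: tuple[str, ...], *, flags: tuple[str, ...] = (),
          effectors: tuple[tuple[str, str, str], ...] = (), probability: float = 1.0,
          placement: str = "core", core: bool = True) -> ComponentSlot:
    return ComponentSlot(
        name=component,
        variants=(SlotVariant(1.0, (ProteinSpec(component, domains, flags, effectors),)),),
        probability=probability,
        placement=placement,
        core=core,
    )


_PGLZ_PRIMARY = (("PglZ_core", "primary", "core_component_fusion"),)

_BRXL_SLOT = ComponentSlot(
    name="BrxL",
    variants=(
        SlotVariant(0.75, (ProteinSpec("BrxL", ("SIGMA_HTH", "OB_fold", "MCM_ATPase", "LonP"),
                                       flags=("BrxL:LonP",)),)),
        SlotVariant(0.25, (ProteinSpec("BrxL", ("SIGMA_HTH", "OB_fold", "MCM_ATPase", "HKD"),
                                       flags=("BrxL:HKD",),
                                       effectors=(("HKD", "auxiliary", "core_component_fusion"),)),)),
    ),
)

_HNH_AUX_SLOT = _slot(
    "HNH", ("HNH",), effectors=(("HNH", "auxiliary", "standalone_in_locus"),),
    probability=0.2, core=False,
)

_OLD_TOPRIM_DYAD = ComponentSlot(
    name="OLD_ABC_TOPRIM_dyad",
    variants=(
        SlotVariant(1.0, (
            ProteinSpec("OLD_ABC", ("OLD_ABC",),
                        effectors=(("OLD_ABC", "backup", "flanking"),)),
            ProteinSpec("TOPRIM", ("TOPRIM",),
                        effectors=(("TOPRIM", "backup", "flanking"),)),
        )),
    ),
    probability=0.15,
    placement="flank",
    core=False,
)

_TYPE1_CORE = (
    _slot("BrxC", ("AAA_ATPase", "wHTH", "alphabeta_core", "wHTH", "coiledcoil")),
    _slot("BrxX", ("N_helical_bundle", "N6_MTase", "TRD_Cterm")),
    _slot("PglZ", ("iSwi2Snf2", "helical_linker", "PglZ_core", "beta_sandwich"),
          effectors=_PGLZ_PRIMARY),
    _slot("BrxA", ("BrxA_HTH", "BrxA_HTH")),
    _slot("BrxB", ("iSTAND",)),
    _BRXL_SLOT,
)

_BR_MTASE_SLOT = _slot("BR_MTase", ("DUF1156_helical", "N6_MTase", "TRD_nested", "HTH", "HTH", "HTH"))

_DUF499_SLOT = ComponentSlot(
    name="DUF499_ATPase",
    variants=(
        SlotVariant(0.5, (ProteinSpec(
            "DUF499_ATPase",
            ("AAA_ATPase", "wHTH", "alphabeta_core", "wHTH", "RRM", "FnIII", "FnIII")),)),
        SlotVariant(0.5, (ProteinSpec(
            "DUF499_ATPase",
            ("HEPN", "AAA_ATPase", "wHTH", "alphabeta_core", "wHTH", "RRM"),
            flags=("DUF499:HEPN_fused",),
            effectors=(("HEPN", "backup", "core_component_fusion"),)),)),
    ),
)

GRAMMARS: dict[str, OperonGrammar] = {
    "Type-1": OperonGrammar("BREX", "Type-1", (*_TYPE1_CORE, _HNH_AUX_SLOT, _OLD_TOPRIM_DYAD)),
    "Type-2": OperonGrammar("BREX", "Type-2", (
        _slot("PglW",
              ("NERD", "pseudokinase", "STY_kinase", "RNApolA_CTD", "wHTH", "wHTH", "wHTH", "iSTAND"),
              effectors=(("NERD", "auxiliary", "core_component_fusion"),)),
        _slot("BrxC", ("AAA_ATPase", "wHTH", "alphabeta_core", "wHTH", "terminal_subdomain")),
        _slot("BrxX", ("N_helical_bundle", "N6_MTase", "TRD_Cterm", "wHTH")),
        _slot("PglZ", ("helical_linker", "PglZ_core", "beta_sandwich"), effectors=_PGLZ_PRIMARY),
        _slot("BrxD", ("AAA_ATPase",)),
        _slot("BrxHI", ("Ski2_helicase", "wHTH", "HAS_barrel", "Lhr_CTD")),
        _slot("BrxA", ("BrxA_HTH", "BrxA_HTH", "BrxA_HTH"), probability=0.8, core=False),
    )),
    "Type-3": OperonGrammar("BREX", "Type-3", (
        _slot("BrxC", ("AAA_ATPase", "wHTH", "alphabeta_core", "wHTH", "coiledcoil")),
        _slot("BrxXI", ("N6_MTase", "TRD_nested", "HTH", "wHTH", "HTH")),
        _slot("PglZ", ("iSwi2Snf2", "helical_linker", "PglZ_core"), effectors=_PGLZ_PRIMARY),
        _slot("BrxF", ("iSTAND",)),
        _slot("BrxHII", ("TUDOR", "Swi2Snf2_helicase", "iREase", "alphabeta_CTD")),
        _slot("BrxA", ("BrxA_HTH", "BrxA_HTH"), probability=0.7, core=False),
    )),
    "Type-4": OperonGrammar("BREX", "Type-4", (
        _slot("BrxC", ("AAA_ATPase", "wHTH", "alphabeta_core", "wHTH")),
        _slot("PglZ", ("iSTAND", "helical_linker", "PglZ_core"),
              flags=("PglZ:iSTAND_fused",), effectors=_PGLZ_PRIMARY),
        ComponentSlot(
            name="BrxP",
            variants=(
                SlotVariant(0.6, (ProteinSpec(
                    "BrxP", ("PAPS_reductase", "DUF1795", "ferredoxin_4Fe4S")),)),
                SlotVariant(0.4, (ProteinSpec(
                    "BrxP", ("PAPS_reductase", "DUF1795", "ferredoxin_4Fe4S", "DUF4007_HTH"),
                    flags=("BrxP:DUF4007_fused",)),)),
            ),
        ),
        _slot("DUF4007", ("DUF4007_HTH", "DUF4007_HTH")),
        ComponentSlot(name="BrxL", variants=(
            SlotVariant(1.0, (ProteinSpec("BrxL", ("SIGMA_HTH", "OB_fold", "MCM_ATPase", "LonP"),
                                          flags=("BrxL:LonP",)),)),
        )),
        _slot("CysDesulf", ("cysteine_desulfurase",)),
        _slot("ZnHTH", ("zinc_finger", "HTH"), probability=0.6, core=False),
    )),
    "Type-5": OperonGrammar("BREX", "Type-5", (
        *_TYPE1_CORE,
        _slot("BrxHII", ("Swi2Snf2_helicase", "alphabeta_CTD")),
    )),
    "Type-6": OperonGrammar("BREX", "Type-6", (
        *_TYPE1_CORE,
        _slot("BrxE", ("BrxE_signature",)),
    )),
    "Type-1 BR": OperonGrammar("BR", "Type-1 BR", (
        _DUF499_SLOT,
        _BR_MTASE_SLOT,
        _slot("BrxHII", ("TUDOR", "Swi2Snf2_helicase", "REase"),
              flags=("helicase:REase_fused",),
              effectors=(("REase", "primary", "core_component_fusion"),)),
    )),
    "Type-2 BR": OperonGrammar("BR", "Type-2 BR", (
        ComponentSlot(name="DUF499_ATPase", variants=(
            SlotVariant(1.0, (ProteinSpec(
                "DUF499_ATPase",
                ("AAA_ATPase", "wHTH", "alphabeta_core", "wHTH", "RRM", "FnIII")),)),
        )),
        _BR_MTASE_SLOT,
        _slot("BrxHII", ("HKD", "Swi2Snf2_helicase", "alphabeta_CTD"),
              flags=("helicase:HKD_fused",),
              effectors=(("HKD", "primary", "core_component_fusion"),)),
        ComponentSlot(
            name="DUF3780",
            variants=(
                SlotVariant(0.7, (ProteinSpec("DUF3780", ("DUF3780_core",)),)),
                SlotVariant(0.3, (ProteinSpec("DUF3780", ("DUF3780_core", "ASCH_PUA"),
                                              flags=("DUF3780:ASCH_PUA",)),)),
            ),
        ),
    )),
    "Type-3 BR": OperonGrammar("BR", "Type-3 BR", (
        ComponentSlot(name="DUF499_ATPase", variants=(
            SlotVariant(1.0, (ProteinSpec(
                "DUF499_ATPase",
                ("AAA_ATPase", "wHTH", "alphabeta_core", "wHTH", "RRM")),)),
        )),
        _BR_MTASE_SLOT,
        _slot("BrxHII", ("Swi2Snf2_helicase", "alphabeta_CTD")),
        _slot("PglZ", ("helical_linker", "PglZ_core"), effectors=_PGLZ_PRIMARY),
        _slot("iSTAND", ("iSTAND",)),
    )),
    "BRC": OperonGrammar("BRC", "BRC", (
        _slot("PglZ", ("PglZ_core",), flags=("PglZ:minimal",)),
        _slot("BrxC", ("AAA_ATPase", "wHTH", "alphabeta_core", "wHTH")),
        _slot("STAND_active", ("STAND_walker",)),
        _slot("DUF4007", ("DUF4007_HTH", "DUF4007_HTH", "DUF4007_HTH")),
        _slot("HerA_FtsK", ("HerA_FtsK_translocase",)),
        _slot("GNAT", ("GNAT_acetyltransferase",)),
        _slot("TGT", ("TGT_core",)),
    )),
}


# --- cohort specification --------------------------------------------------

DEFAULT_PHYLA = ("Pseudomonadota", "Bacillota", "Actinomycetota", "Cyanobacteriota")


@dataclass(frozen=True)
class CohortSpec:
    subtype_mix: dict[str, int] = field(
        default_factory=lambda: {name: 20 for name in GRAMMARS}
    )
    assemblies_per_taxon: tuple[int, int] = (1, 2)
    phyla: tuple[str, ...] = DEFAULT_PHYLA
    decoy_genes_per_genome: tuple[int, int] = (6, 12)
    noise_rate: float = 0.0
    dropout_rate: float = 0.0
    linker_drift: float = 0.1  # per-taxon substitution rate on linker residues
    max_gap_nt: int = DEFAULT_MAX_GAP
    seed: int = 0

    def __post_init__(self) -> None:
        unknown = set(self.subtype_mix) - set(GRAMMARS)
        if unknown:
            raise ValueError(
                f"unknown subtypes {sorted(unknown)}; valid: {sorted(GRAMMARS)}"
            )
        if any(n < 0 for n in self.subtype_mix.values()):
            raise ValueError("subtype counts must be non-negative")


# --- protein / operon / genome construction --------------------------------

def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    chars = list(seq)
    hits = np.nonzero(rng.random(len(chars)) < rate)[0]
    for i in hits:
        chars[i] = AA20[rng.integers(0, 20)]
    return "".join(chars)


def _base_linker(key: str, length: int = LINKER_LEN) -> str:
    # deterministic per architecture position (crc32-seeded), so homologous
    # proteins across taxa share linkers up to the configured drift and
    # greedy clustering pools them as CD-HIT would pool near-identical seqs
    rng = np.random.default_rng(zlib.crc32(key.encode()))
    return "".join(LINKER_ALPHABET[i] for i in rng.integers(0, len(LINKER_ALPHABET), length))


def build_protein(
    domains: tuple[str, ...],
    rng: np.random.Generator,
    registry: DomainRegistry | None = None,
    linker_drift: float = 0.0,
) -> str:
    """Concatenate domain signature blocks separated by low-complexity linkers."""
    registry = registry or default_registry()
    arch_key = "+".join(domains)
    parts = [_base_linker(f"{arch_key}:0")]
    for i, dom in enumerate(domains):
        parts.append(registry[dom].signature)
        parts.append(_base_linker(f"{arch_key}:{i + 1}"))
    seq = "".join(parts)
    if linker_drift > 0:
        # drift only the linker residues; signatures stay exact
        sig_mask = np.zeros(len(seq), dtype=bool)
        pos = LINKER_LEN
        for dom in domains:
            sig_len = len(registry[dom].signature)
            sig_mask[pos : pos + sig_len] = True
            pos += sig_len + LINKER_LEN
        chars = list(seq)
        hits = np.nonzero((rng.random(len(chars)) < linker_drift) & ~sig_mask)[0]
        for i in hits:
            chars[i] = LINKER_ALPHABET[rng.integers(0, len(LINKER_ALPHABET))]
        seq = "".join(chars)
    return seq


def decoy_protein(rng: np.random.Generator, min_len: int = 80, max_len: int = 160) -> str:
    """Random protein with a periodic W lattice (shares no signature k-mers
    with the registry, whose signatures avoid W)."""
    n = int(rng.integers(min_len, max_len + 1))
    chars = [AA20[i] for i in rng.integers(0, 20, n)]
    for i in range(0, n, DECOY_W_STRIDE):
        chars[i] = "W"
    return "".join(chars)


def sample_operon(
    grammar: OperonGrammar,
    rng: np.random.Generator,
    registry: DomainRegistry | None = None,
    noise_rate: float = 0.0,
    dropout_rate: float = 0.0,
    linker_drift: float = 0.0,
    gene_prefix: str = "op",
) -> tuple[list[GeneRecord], dict]:
    """Realize one operon: genes laid left-to-right from position 0, with the
    core block on the plus strand and flank slots on the minus strand.

    Returns (genes, truth) where truth lists the planted components with
    fusion flags and the planted effector inventory.
    """
    registry = registry or default_registry()
    core_entries: list[tuple[ProteinSpec, str]] = []  # (spec, strand)
    flank_entries: list[tuple[ProteinSpec, str]] = []
    for slot in grammar.slots:
        if rng.random() >= slot.probability:
            continue
        if dropout_rate > 0 and rng.random() < dropout_rate:
            continue
        weights = np.array([v.weight for v in slot.variants], dtype=float)
        variant = slot.variants[rng.choice(len(slot.variants), p=weights / weights.sum())]
        target = core_entries if slot.placement == "core" else flank_entries
        for spec in variant.proteins:
            target.append((spec, "+" if slot.placement == "core" else "-"))

    genes: list[GeneRecord] = []
    truth_components: list[dict] = []
    truth_effectors: list[dict] = []
    cursor = 0
    for i, (spec, strand) in enumerate(core_entries + flank_entries):
        flank = i >= len(core_entries)
        if genes:
            lo, hi = grammar.flank_gap_range if flank and i == len(core_entries) else grammar.gap_range
            cursor = genes[-1].end + int(rng.integers(lo, hi + 1))
        protein = build_protein(spec.domains, rng, registry, linker_drift)
        protein = _mutate(protein, noise_rate, rng)
        gene_id = f"{gene_prefix}_{i:02d}"
        gene = GeneRecord(
            gene_id=gene_id,
            start=cursor,
            end=cursor + 3 * (len(protein) + 1),
            strand=strand,
            translation=protein,
            product=spec.component,
        )
        genes.append(gene)
        truth_components.append(
            {"gene_id": gene_id, "component": spec.component, "flags": sorted(spec.flags)}
        )
        for dom, role, provenance in spec.effectors:
            truth_effectors.append(
                {"gene_id": gene_id, "domain": dom, "role": role, "provenance": provenance}
            )
    truth = {
        "system": grammar.system,
        "subtype": grammar.subtype,
        "components": truth_components,
        "effectors": truth_effectors,
    }
    return genes, truth


def synth_genome(
    genome_id: str,
    assembly_id: str,
    taxid: int,
    lineage: list[tuple[str, str]],
    grammar: OperonGrammar,
    rng: np.random.Generator,
    n_decoys: int = 8,
    registry: DomainRegistry | None = None,
    noise_rate: float = 0.0,
    dropout_rate: float = 0.0,
    linker_drift: float = 0.0,
    max_gap_nt: int = DEFAULT_MAX_GAP,
) -> tuple[GenomeRecord, dict]:
    """Plant one operon among decoys, isolated by 5x the gap threshold."""
    registry = registry or default_registry()
    iso = ISOLATION_FACTOR * max_gap_nt
    operon_genes, operon_truth = sample_operon(
        grammar, rng, registry, noise_rate, dropout_rate, linker_drift,
        gene_prefix=f"{genome_id}_op",
    )
    n_left = int(rng.integers(0, n_decoys + 1))
    genes: list[GeneRecord] = []
    cursor = int(rng.integers(50, 200))

    def add_decoy(k: int) -> None:
        nonlocal cursor
        protein = decoy_protein(rng)
        genes.append(
            GeneRecord(
                gene_id=f"{genome_id}_d{k:02d}",
                start=cursor,
                end=cursor + 3 * (len(protein) + 1),
                strand="+" if rng.random() < 0.5 else "-",
                translation=protein,
                product="hypothetical protein",
            )
        )
        cursor = genes[-1].end + int(rng.integers(max_gap_nt + 50, max_gap_nt + 400))

    for k in range(n_left):
        add_decoy(k)
    if genes:
        cursor = genes[-1].end + iso + int(rng.integers(0, 200))
    offset = cursor
    for g in operon_genes:
        genes.append(
            GeneRecord(
                gene_id=g.gene_id,
                start=g.start + offset,
                end=g.end + offset,
                strand=g.strand,
                translation=g.translation,
                product=g.product,
                genome_id=genome_id,
            )
        )
    cursor = genes[-1].end + iso + int(rng.integers(0, 200))
    for k in range(n_left, n_decoys):
        add_decoy(k)
    length = (genes[-1].end if genes else 1000) + int(rng.integers(100, 400))
    genes = [
        GeneRecord(g.gene_id, g.start, g.end, g.strand, g.translation, g.product, genome_id)
        for g in genes
    ]
    genome = GenomeRecord(
        genome_id=genome_id,
        assembly_id=assembly_id,
        taxid=taxid,
        length=length,
        genes=genes,
        lineage=lineage,
    )
    span_genes = [g for g in genome.genes if g.gene_id.startswith(f"{genome_id}_op")]
    truth = {
        "genome_id": genome_id,
        "assembly_id": assembly_id,
        "taxid": taxid,
        "span": [min(g.start for g in span_genes), max(g.end for g in span_genes)],
        "gene_ids": [g.gene_id for g in span_genes],
        **operon_truth,
    }
    return genome, truth


def _lineage_for(phylum: str, taxid: int) -> list[tuple[str, str]]:
    names = (
        "Bacteria", phylum, f"{phylum[:4]}ia", f"{phylum[:4]}ales",
        f"{phylum[:4]}aceae", f"Genus{taxid}", f"Genus{taxid} sp{taxid}",
    )
    return list(zip(LINEAGE_RANKS, names))


def synth_cohort(
    spec: CohortSpec,
    out_dir: str | Path | None = None,
    registry: DomainRegistry | None = None,
    grammars: dict[str, OperonGrammar] | None = None,
) -> tuple[list[GenomeRecord], dict]:
    """Generate a cohort of genomes realizing the subtype mix exactly.

    Taxa of each subtype are spread round-robin over the cohort spec's phyla (so
    every subtype with >= 2 taxa occurs in >= 2 phyla when >= 2 phyla are
    given); each taxon may contribute several assemblies carrying the same
    planted locus. When ``out_dir`` is given, GenBank files, the taxonomy
    TSV and the truth JSON are written there.
    """
    registry = registry or default_registry()
    ss = np.random.SeedSequence(spec.seed)
    genomes: list[GenomeRecord] = []
    truth: dict = {
        "spec": {**asdict(spec), "subtype_mix": dict(spec.subtype_mix)},
        "genomes": {},
        "loci": [],
        "warnings": [],
    }
    if len(spec.phyla) < 2:
        truth["warnings"].append(
            "fewer than 2 phyla: cross-phyla support cannot be exercised"
        )
    taxon_plan: list[tuple[str, str, int]] = []  # (subtype, phylum, taxid)
    taxid = 1000
    for subtype in sorted(spec.subtype_mix):
        for j in range(spec.subtype_mix[subtype]):
            taxon_plan.append((subtype, spec.phyla[j % len(spec.phyla)], taxid))
            taxid += 1
    children = ss.spawn(len(taxon_plan))
    taxonomy_rows = []
    for (subtype, phylum, taxid), child in zip(taxon_plan, children):
        rng = np.random.default_rng(child)
        lineage = _lineage_for(phylum, taxid)
        lo, hi = spec.assemblies_per_taxon
        n_asm = int(rng.integers(lo, hi + 1))
        # one realization per taxon; assemblies are copies under new ids,
        # emulating redundant assemblies of the same organism
        base_id = f"G{taxid}"
        genome, locus_truth = synth_genome(
            genome_id=f"{base_id}A1",
            assembly_id=f"ASM{taxid}.1",
            taxid=taxid,
            lineage=lineage,
            grammar=(grammars or GRAMMARS)[subtype],
            rng=rng,
            n_decoys=int(
                rng.integers(spec.decoy_genes_per_genome[0], spec.decoy_genes_per_genome[1] + 1)
            ),
            registry=registry,
            noise_rate=spec.noise_rate,
            dropout_rate=spec.dropout_rate,
            linker_drift=spec.linker_drift,
            max_gap_nt=spec.max_gap_nt,
        )
        copies = [genome]
        loci_truths = [locus_truth]
        for a in range(2, n_asm + 1):
            gid = f"{base_id}A{a}"
            dup = GenomeRecord(
                genome_id=gid,
                assembly_id=f"ASM{taxid}.{a}",
                taxid=taxid,
                length=genome.length,
                genes=[
                    GeneRecord(
                        g.gene_id.replace(f"{base_id}A1", gid), g.start, g.end,
                        g.strand, g.translation, g.product, gid,
                    )
                    for g in genome.genes
                ],
                lineage=lineage,
            )
            dup_truth = json.loads(json.dumps(locus_truth))
            dup_truth["genome_id"] = gid
            dup_truth["assembly_id"] = dup.assembly_id
            dup_truth["gene_ids"] = [i.replace(f"{base_id}A1", gid) for i in dup_truth["gene_ids"]]
            for comp in dup_truth["components"]:
                comp["gene_id"] = comp["gene_id"].replace(f"{base_id}A1", gid)
            for eff in dup_truth["effectors"]:
                eff["gene_id"] = eff["gene_id"].replace(f"{base_id}A1", gid)
            copies.append(dup)
            loci_truths.append(dup_truth)
        for gm, lt in zip(copies, loci_truths):
            genomes.append(gm)
            truth["loci"].append(lt)
            truth["genomes"][gm.genome_id] = {
                "assembly_id": gm.assembly_id,
                "taxid": gm.taxid,
                "phylum": phylum,
                "subtype": subtype,
                "n_genes": len(gm.genes),
            }
            taxonomy_rows.append(
                {"assembly_id": gm.assembly_id, "taxid": gm.taxid,
                 **{rank: name for rank, name in gm.lineage}}
            )

    counts: dict[str, set[int]] = {}
    phylum_counts: dict[str, dict[str, set[int]]] = {}
    for lt in truth["loci"]:
        subtype = lt["subtype"]
        counts.setdefault(subtype, set()).add(lt["taxid"])
        ph = truth["genomes"][lt["genome_id"]]["phylum"]
        phylum_counts.setdefault(ph, {}).setdefault(subtype, set()).add(lt["taxid"])
    truth["taxid_counts"] = {s: len(t) for s, t in sorted(counts.items())}
    truth["phylum_subtype_counts"] = {
        ph: {s: len(t) for s, t in sorted(d.items())} for ph, d in sorted(phylum_counts.items())
    }

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        import pandas as pd

        for gm in genomes:
            write_genbank([gm], out_dir / f"{gm.genome_id}.gbk")
        pd.DataFrame(taxonomy_rows, columns=["assembly_id", "taxid", *LINEAGE_RANKS]).to_csv(
            out_dir / "taxonomy.tsv", sep="\t", index=False
        )
        with open(out_dir / "truth.json", "w") as fh:
            json.dump(truth, fh, indent=1, sort_keys=True)
            fh.write("\n")
    return genomes, truth


# --- alignment generator ---------------------------------------------------

def synth_msa(
    n_rows: int,
    column_spec: list[dict[str, float]],
    rng: np.random.Generator,
    out_path: str | Path | None = None,
) -> tuple[list[tuple[str, str]], list[dict]]:
    """Sample an alignment with prescribed per-column residue distributions.

    Each column spec is a distribution over the 20 residues plus the gap
    character "-". Truth records, per column, the expected entropy of the
    generating distribution and the plug-in entropies of the realized
    column under both shipped alphabets (computed by direct closed-form
    evaluation).
    """
    if n_rows < 2:
        raise ValueError("n_rows must be >= 2")
    cols: list[list[str]] = []
    truth: list[dict] = []
    map20, map8 = identity20_map(), chem8_map()
    for j, dist in enumerate(column_spec):
        total = sum(dist.values())
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ValueError(f"column {j}: distribution sums to {total}, not 1")
        symbols = sorted(dist)
        probs = np.array([dist[s] for s in symbols])
        draw = [symbols[i] for i in rng.choice(len(symbols), size=n_rows, p=probs)]
        cols.append(draw)
        residue_probs = [p for s, p in dist.items() if s != "-" and p > 0]
        res_total = sum(residue_probs)
        expected = (
            -sum((p / res_total) * math.log2(p / res_total) for p in residue_probs)
            if res_total > 0
            else math.nan
        )
        truth.append(
            {
                "column_index": j,
                "expected_H20": expected,
                "plugin_H20": column_entropy(reduce_alphabet(draw, map20)),
                "plugin_H8": column_entropy(reduce_alphabet(draw, map8)),
                "gap_fraction": draw.count("-") / n_rows,
            }
        )
    records = [
        (f"r{i + 1}", "".join(cols[j][i] for j in range(len(cols))))
        for i in range(n_rows)
    ]
    if out_path is not None:
        write_fasta(records, out_path)
    return records, truth
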