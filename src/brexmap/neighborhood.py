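"""Candidate-locus reconstruction around anchor genes.

Three contextual filters define a locus: genomic proximity (intergenic gap
at or below ~100 nt), conservation of gene orientation (same-strand operon
blocks, with divergently oriented neighboring blocks admitted at the locus
level), and cross-phyla occurrence of the assembled neighborhood archetype.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .model import GeneRecord, GenomeRecord, Locus, OperonBlock


@dataclass(frozen=True)
class NeighborhoodParams:
    max_gap_nt: int = 100
    window_genes: int = 10
    strand_mode: str = "same_strand_blocks"  # or "any"
    min_phyla: int = 2

    def __post_init__(self) -> None:
        if self.max_gap_nt < 0:
            raise ValueError("max_gap_nt must be >= 0")
        if self.window_genes < 1:
            raise ValueError("window_genes must be >= 1")
        if self.strand_mode not in ("same_strand_blocks", "any"):
            raise ValueError(f"bad strand_mode {self.strand_mode!r}")


def intergenic_gap(g1: GeneRecord, g2: GeneRecord) -> int:
    """Number of bases strictly between two genes (negative when overlapping).

    Genes must come from the same genome with g1 starting no later than g2.
    """
    if g1.genome_id != g2.genome_id:
        raise ValueError(f"genes {g1.gene_id}/{g2.gene_id} are on different genomes")
    if g1.start > g2.start:
        raise ValueError("g1 must start at or before g2")
    return g2.start - g1.end


def build_operon_blocks(
    genome: GenomeRecord, params: NeighborhoodParams = NeighborhoodParams()
) -> list[OperonBlock]:
    """Partition the gene list into maximal proximity/orientation runs.

    Consecutive genes co-block when their gap is <= max_gap_nt (overlapping
    genes always co-block) and, under same_strand_blocks, share a strand.
    """
    blocks: list[OperonBlock] = []
    cur: list[GeneRecord] = []
    for g in genome.genes:
        if not cur:
            cur = [g]
            continue
        gap = g.start - cur[-1].end
        same_strand = params.strand_mode == "any" or g.strand == cur[-1].strand
        if gap <= params.max_gap_nt and same_strand:
            cur.append(g)
        else:
            blocks.append(OperonBlock(genes=cur, strand=cur[0].strand))
            cur = [g]
    if cur:
        blocks.append(OperonBlock(genes=cur, strand=cur[0].strand))
    return blocks


def extract_locus(
    genome: GenomeRecord,
    anchor_gene_id: str,
    params: NeighborhoodParams = NeighborhoodParams(),
) -> Locus:
    """Assemble the candidate locus around one anchor gene.

    Within a window of ``window_genes`` genes on each side of the anchor,
    the anchor's operon block is kept together with every neighboring block
    whose nearest edge lies within max_gap_nt of the growing locus span.
    This admits divergently transcribed adjacent blocks while still bounding
    the locus by the proximity rule.
    """
    anchor = genome.gene(anchor_gene_id)
    idx = genome.genes.index(anchor)
    lo = max(0, idx - params.window_genes)
    hi = min(len(genome.genes), idx + params.window_genes + 1)
    window = GenomeRecord(
        genome_id=genome.genome_id,
        assembly_id=genome.assembly_id,
        taxid=genome.taxid,
        length=genome.length,
        genes=list(genome.genes[lo:hi]),
        lineage=genome.lineage,
    )
    blocks = build_operon_blocks(window, params)
    anchor_idx = next(i for i, b in enumerate(blocks) if anchor in b.genes)

    kept = [anchor_idx]
    span = list(blocks[anchor_idx].span)
    left, right = anchor_idx - 1, anchor_idx + 1
    grew = True
    while grew:
        grew = False
        if left >= 0 and span[0] - blocks[left].span[1] <= params.max_gap_nt:
            kept.insert(0, left)
            span[0] = blocks[left].span[0]
            left -= 1
            grew = True
        if right < len(blocks) and blocks[right].span[0] - span[1] <= params.max_gap_nt:
            kept.append(right)
            span[1] = blocks[right].span[1]
            right += 1
            grew = True
    return Locus(
        locus_id=f"{genome.genome_id}:{anchor_gene_id}",
        genome_id=genome.genome_id,
        anchor_gene_id=anchor_gene_id,
        blocks=[blocks[i] for i in kept],
    )


def archetype_key(locus: Locus) -> tuple[str, ...]:
    """Sorted multiset of component names; loci with equal keys form one
    neighborhood archetype for the cross-phyla support test."""
    comps = sorted(
        c.component for c in locus.component_calls.values() if c.component != "unknown"
    )
    return tuple(comps)


def cross_phyla_filter(
    loci: list[Locus],
    taxonomy: pd.DataFrame,
    genome_to_assembly: dict[str, str],
    params: NeighborhoodParams = NeighborhoodParams(),
) -> tuple[list[Locus], list[Locus]]:
    """Flag neighborhood archetypes not observed in >= min_phyla phyla.

    Loci are never deleted: unsupported ones gain a ``phyla_support`` flag
    and loci from genomes missing in the taxonomy gain ``no_taxonomy`` and
    are excluded from the group test. Returns (kept, flagged).
    """
    phylum_by_assembly = dict(zip(taxonomy["assembly_id"], taxonomy.get("phylum", "")))
    key_phyla: dict[tuple[str, ...], set[str]] = {}
    locus_phylum: dict[str, str | None] = {}
    for loc in loci:
        asm = genome_to_assembly.get(loc.genome_id)
        phylum = phylum_by_assembly.get(asm) if asm is not None else None
        locus_phylum[loc.locus_id] = phylum
        if phylum is None:
            continue
        key_phyla.setdefault(archetype_key(loc), set()).add(phylum)
    kept, flagged = [], []
    for loc in loci:
        if locus_phylum[loc.locus_id] is None:
            loc.flags.add("no_taxonomy")
            flagged.append(loc)
        elif len(key_phyla.get(archetype_key(loc), set())) >= params.min_phyla:
            kept.append(loc)
        else:
            loc.flags.add("phyla_support")
            flagged.append(loc)
    return kept, flagged
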