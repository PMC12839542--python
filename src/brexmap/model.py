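"""Core data model shared by every pipeline stage.

All coordinates are 0-based half-open on the genome forward strand; the
GenBank 1-based inclusive convention is converted at the I/O boundary only.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class GeneRecord:
    """One protein-coding gene on a replicon.

    ``start``/``end`` are genome-forward 0-based half-open; ``strand`` is
    stored separately so intergenic arithmetic is strand-free.
    """

    gene_id: str
    start: int
    end: int
    strand: str  # "+" or "-"
    translation: str
    product: str = ""
    genome_id: str = ""

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"gene {self.gene_id}: start {self.start} >= end {self.end}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: bad strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class GenomeRecord:
    """One annotated replicon with assembly and taxonomy metadata.

    ``lineage`` is an ordered list of (rank, name) pairs from superkingdom
    downwards; it may be empty when taxonomy comes from a side table.
    """

    genome_id: str
    assembly_id: str
    taxid: int
    length: int
    genes: list[GeneRecord] = field(default_factory=list)
    lineage: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.genes = sorted(self.genes, key=lambda g: (g.start, g.end))
        ids = [g.gene_id for g in self.genes]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"{self.genome_id}: duplicate gene ids {dup}")
        for g in self.genes:
            if g.start < 0 or g.end > self.length:
                raise ValueError(
                    f"{self.genome_id}: gene {g.gene_id} [{g.start},{g.end}) "
                    f"outside [0,{self.length})"
                )

    def gene(self, gene_id: str) -> GeneRecord:
        for g in self.genes:
            if g.gene_id == gene_id:
                return g
        raise KeyError(f"{self.genome_id}: no gene {gene_id!r}")


@dataclass(frozen=True)
class DomainHitRow:
    """One domain hit on a protein (amino-acid coordinates, 0-based half-open)."""

    protein_id: str
    domain_name: str
    aa_start: int
    aa_end: int
    score: float = 0.0

    def __post_init__(self) -> None:
        if self.aa_start >= self.aa_end:
            raise ValueError(
                f"{self.protein_id}/{self.domain_name}: aa_start >= aa_end"
            )


@dataclass
class Architecture:
    """Ordered, overlap-resolved domain architecture of one protein."""

    protein_id: str
    domains: list[DomainHitRow] = field(default_factory=list)
    source: str = "signature"  # "signature" | "imported"

    @property
    def domain_names(self) -> list[str]:
        return [d.domain_name for d in self.domains]


@dataclass
class ComponentCall:
    """Canonical component assignment for one protein."""

    protein_id: str
    component: str  # canonical name or "unknown"
    fusion_flags: frozenset[str] = frozenset()
    confidence: str = "exact"  # "exact" | "partial"


@dataclass
class OperonBlock:
    """Maximal run of same-strand genes with intergenic gaps at or below the
    proximity threshold."""

    genes: list[GeneRecord]
    strand: str

    @property
    def span(self) -> tuple[int, int]:
        return (self.genes[0].start, self.genes[-1].end)


@dataclass
class Locus:
    """A reconstructed candidate defense neighborhood."""

    locus_id: str
    genome_id: str
    anchor_gene_id: str
    blocks: list[OperonBlock]
    flags: set[str] = field(default_factory=set)
    component_calls: dict[str, ComponentCall] = field(default_factory=dict)

    @property
    def member_genes(self) -> list[GeneRecord]:
        out: list[GeneRecord] = []
        for b in self.blocks:
            out.extend(b.genes)
        return sorted(out, key=lambda g: g.start)

    @property
    def span(self) -> tuple[int, int]:
        genes = self.member_genes
        return (genes[0].start, genes[-1].end)


@dataclass
class SystemCall:
    """Classification outcome for one locus."""

    locus_id: str
    system: str  # BREX | BR | BRC | unassigned
    subtype: str  # Type-1 .. Type-6, Type-1 BR .. Type-3 BR, BRC, NA
    family_group: str  # Type-1-family | other
    completeness: str  # complete | partial | discarded
    components_present: frozenset[str] = frozenset()
    missing_core: frozenset[str] = frozenset()
    fusion_flags: frozenset[str] = frozenset()
    review_flags: frozenset[str] = frozenset()


@dataclass(frozen=True)
class EffectorRecord:
    """One effector domain occurrence attached to a locus."""

    locus_id: str
    effector_domain: str
    carrier_protein: str
    role: str  # primary | auxiliary | backup
    provenance: str  # core_component_fusion | standalone_in_locus | flanking
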