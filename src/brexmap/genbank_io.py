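"""I/O boundary: GenBank, FASTA and the pipeline's TSV/JSON tables.

All coordinate conversion between the GenBank 1-based inclusive convention
and the internal 0-based half-open convention happens here and nowhere else.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord

from .model import DomainHitRow, EffectorRecord, GeneRecord, GenomeRecord, Locus, SystemCall

LINEAGE_RANKS = ("superkingdom", "phylum", "class", "order", "family", "genus", "species")


class GenBankParseError(ValueError):
    pass


def read_genbank(path: str | Path) -> list[GenomeRecord]:
    """Parse a GenBank flat file into GenomeRecords (one per LOCUS entry).

    CDS coordinates become 0-based half-open; compound (join) locations are
    collapsed to their outer span with a warning; CDS features without a
    translation are skipped with a warning when the record carries no usable
    sequence.
    """
    path = Path(path)
    genomes: list[GenomeRecord] = []
    try:
        records = list(SeqIO.parse(str(path), "genbank"))
    except Exception as exc:  # pragma: no cover - biopython error text varies
        raise GenBankParseError(f"{path}: malformed GenBank file: {exc}") from exc
    for rec in records:
        try:
            genomes.append(_record_to_genome(rec))
        except Exception as exc:
            raise GenBankParseError(f"{path}: LOCUS {rec.name}: {exc}") from exc
    return genomes


def _record_to_genome(rec: SeqRecord) -> GenomeRecord:
    genome_id = rec.name or rec.id
    taxid = 0
    lineage: list[tuple[str, str]] = []
    assembly_id = genome_id
    for feat in rec.features:
        if feat.type != "source":
            continue
        for xref in feat.qualifiers.get("db_xref", []):
            if xref.startswith("taxon:"):
                taxid = int(xref.split(":", 1)[1])
        for note in feat.qualifiers.get("note", []):
            if note.startswith("assembly:"):
                assembly_id = note.split(":", 1)[1]
    taxonomy = rec.annotations.get("taxonomy", [])
    organism = rec.annotations.get("organism", "")
    names = list(taxonomy) + ([organism] if organism else [])
    lineage = list(zip(LINEAGE_RANKS, names))

    genes: list[GeneRecord] = []
    n_skipped = 0
    try:  # records may carry a declared length but undefined sequence content
        has_seq = len(rec.seq) > 0 and set(str(rec.seq[:50])) != {"N"}
    except Exception:
        has_seq = False
    for feat in rec.features:
        if feat.type != "CDS":
            continue
        loc = feat.location
        if len(loc.parts) > 1:
            warnings.warn(
                f"{genome_id}: compound location collapsed to outer span "
                f"for CDS at {loc}",
                stacklevel=2,
            )
        start, end = int(loc.start), int(loc.end)
        strand = "-" if loc.strand == -1 else "+"
        translation = feat.qualifiers.get("translation", [""])[0]
        if not translation:
            if has_seq:
                translation = str(feat.extract(rec.seq).translate(to_stop=True))
            if not translation:
                n_skipped += 1
                warnings.warn(
                    f"{genome_id}: CDS [{start},{end}) lacks a translation; skipped",
                    stacklevel=2,
                )
                continue
        gene_id = (
            feat.qualifiers.get("locus_tag", [None])[0]
            or feat.qualifiers.get("protein_id", [None])[0]
            or f"{genome_id}_{start}"
        )
        genes.append(
            GeneRecord(
                gene_id=gene_id,
                start=start,
                end=end,
                strand=strand,
                translation=translation.upper(),
                product=feat.qualifiers.get("product", [""])[0],
                genome_id=genome_id,
            )
        )
    genome = GenomeRecord(
        genome_id=genome_id,
        assembly_id=assembly_id,
        taxid=taxid,
        length=len(rec.seq) if len(rec.seq) else max((g.end for g in genes), default=0),
        genes=genes,
        lineage=lineage,
    )
    genome.n_skipped_cds = n_skipped  # type: ignore[attr-defined]
    return genome


def write_genbank(genomes: Iterable[GenomeRecord], path: str | Path) -> None:
    """Write GenomeRecords as a (deterministic) multi-LOCUS GenBank file."""
    records = []
    for gm in genomes:
        seq = Seq(_filler_sequence(gm.length))
        rec = SeqRecord(seq, id=gm.genome_id, name=gm.genome_id, description="synthetic replicon")
        rec.annotations["molecule_type"] = "DNA"
        rec.annotations["topology"] = "linear"
        rec.annotations["date"] = "01-JAN-1980"  # fixed: byte-identical output
        rec.annotations["organism"] = gm.lineage[-1][1] if gm.lineage else "unknown"
        rec.annotations["taxonomy"] = [name for _, name in gm.lineage[:-1]]
        src = SeqFeature(FeatureLocation(0, gm.length), type="source")
        src.qualifiers["db_xref"] = [f"taxon:{gm.taxid}"]
        src.qualifiers["note"] = [f"assembly:{gm.assembly_id}"]
        rec.features.append(src)
        for g in gm.genes:
            feat = SeqFeature(
                FeatureLocation(g.start, g.end, strand=1 if g.strand == "+" else -1),
                type="CDS",
            )
            feat.qualifiers["locus_tag"] = [g.gene_id]
            feat.qualifiers["product"] = [g.product or "hypothetical protein"]
            feat.qualifiers["translation"] = [g.translation]
            rec.features.append(feat)
        records.append(rec)
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "genbank")


def _filler_sequence(length: int) -> str:
    return ("ACGT" * (length // 4 + 1))[:length]


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read FASTA into (id, upper-cased sequence) pairs; duplicate ids error."""
    records = [(r.id, str(r.seq).upper()) for r in SeqIO.parse(str(path), "fasta")]
    ids = [rid for rid, _ in records]
    dups = sorted({i for i in ids if ids.count(i) > 1})
    if dups:
        raise ValueError(f"{path}: duplicate FASTA ids {dups}")
    return records


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


DOMAIN_TABLE_COLUMNS = ("protein_id", "domain_name", "aa_start", "aa_end", "score")


def read_domain_table(path: str | Path, known_domains: set[str] | None = None) -> list[DomainHitRow]:
    """Read an externally produced per-protein domain-hit TSV.

    Input coordinates are 1-based inclusive amino-acid positions; unknown
    domain names are retained as ``other:<name>``; rows with aa_start >=
    aa_end are rejected with their line number.
    """
    if known_domains is None:
        from .registry import default_registry

        known_domains = set(default_registry().entries)
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in DOMAIN_TABLE_COLUMNS[:4] if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    rows: list[DomainHitRow] = []
    for idx, row in df.iterrows():
        aa_start = int(row["aa_start"]) - 1  # to 0-based half-open
        aa_end = int(row["aa_end"])
        if aa_start >= aa_end:
            raise ValueError(f"{path}: line {idx + 2}: aa_start >= aa_end")
        name = str(row["domain_name"])
        if name not in known_domains:
            name = f"other:{name}"
        rows.append(
            DomainHitRow(
                protein_id=str(row["protein_id"]),
                domain_name=name,
                aa_start=aa_start,
                aa_end=aa_end,
                score=float(row["score"]) if "score" in df.columns and pd.notna(row.get("score")) else 0.0,
            )
        )
    return rows


def read_taxonomy(path: str | Path) -> pd.DataFrame:
    """Read the assembly -> TaxID -> lineage table (TSV)."""
    df = pd.read_csv(path, sep="\t", dtype={"assembly_id": str})
    required = {"assembly_id", "taxid"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required columns {sorted(missing)}")
    df["taxid"] = df["taxid"].astype(int)
    return df


# --- tabular export --------------------------------------------------------

def loci_frame(loci: Sequence[Locus]) -> pd.DataFrame:
    rows = []
    for loc in loci:
        s, e = loc.span
        rows.append(
            {
                "locus_id": loc.locus_id,
                "genome_id": loc.genome_id,
                "anchor_gene_id": loc.anchor_gene_id,
                "start": s,
                "end": e,
                "n_genes": len(loc.member_genes),
                "n_blocks": len(loc.blocks),
                "member_gene_ids": ",".join(g.gene_id for g in loc.member_genes),
                "block_structure": ";".join(
                    f"{b.strand}:" + ",".join(g.gene_id for g in b.genes) for b in loc.blocks
                ),
                "flags": ",".join(sorted(loc.flags)),
            }
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "locus_id", "genome_id", "anchor_gene_id", "start", "end",
            "n_genes", "n_blocks", "member_gene_ids", "block_structure", "flags",
        ],
    )
    return df.sort_values(["genome_id", "start", "locus_id"]).reset_index(drop=True)


def calls_frame(calls: Sequence[SystemCall]) -> pd.DataFrame:
    rows = [
        {
            "locus_id": c.locus_id,
            "system": c.system,
            "subtype": c.subtype,
            "family_group": c.family_group,
            "completeness": c.completeness,
            "components_present": ",".join(sorted(c.components_present)),
            "missing_core": ",".join(sorted(c.missing_core)),
            "fusion_flags": ",".join(sorted(c.fusion_flags)),
            "review_flags": ",".join(sorted(c.review_flags)),
        }
        for c in calls
    ]
    df = pd.DataFrame(
        rows,
        columns=[
            "locus_id", "system", "subtype", "family_group", "completeness",
            "components_present", "missing_core", "fusion_flags", "review_flags",
        ],
    )
    return df.sort_values("locus_id").reset_index(drop=True)


def effectors_frame(effectors: Sequence[EffectorRecord]) -> pd.DataFrame:
    rows = [
        {
            "locus_id": e.locus_id,
            "effector_domain": e.effector_domain,
            "carrier_protein": e.carrier_protein,
            "role": e.role,
            "provenance": e.provenance,
        }
        for e in effectors
    ]
    df = pd.DataFrame(
        rows, columns=["locus_id", "effector_domain", "carrier_protein", "role", "provenance"]
    )
    return df.sort_values(["locus_id", "carrier_protein", "effector_domain"]).reset_index(drop=True)


SCHEMAS = {
    "loci": loci_frame,
    "system_calls": calls_frame,
    "effectors": effectors_frame,
}


def write_tables(objects, path: str | Path, schema: str) -> pd.DataFrame:
    """Write objects of one declared schema as TSV plus a JSON sidecar.

    Row and column order are deterministic (sorted by stable keys), so
    repeated runs produce byte-identical files. Returns the frame written.
    """
    path = Path(path)
    if isinstance(objects, pd.DataFrame):
        df = objects
    elif schema in SCHEMAS:
        df = SCHEMAS[schema](objects)
    else:
        raise ValueError(f"unknown schema {schema!r}")
    write_frame(df, path)
    return df


def write_frame(df: pd.DataFrame, path: str | Path) -> pd.DataFrame:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path.with_suffix(".tsv"), sep="\t", index=False)
    with open(path.with_suffix(".json"), "w") as fh:
        json.dump(df.to_dict(orient="records"), fh, indent=1, default=str)
        fh.write("\n")
    return df
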