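"""End-to-end orchestration of the scan.

Stages run in a fixed order: read genomes -> find anchor genes -> extract
loci -> cluster neighborhood proteins -> annotate -> call components ->
classify -> catalog effectors -> cross-phyla flag -> phyletic matrices.
A run manifest records parameters, the seed and per-stage record counts;
reruns with identical inputs and config are byte-identical.
"""

from __future__ import annotations

import json
import logging
from collections import defaultdict
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .annotate import call_component, call_domains, compose_architecture
from .classify import catalog_effectors, classify_locus, summarize_cohort
from .cluster import ClusterParams, greedy_dedupe
from .genbank_io import (
    calls_frame,
    effectors_frame,
    loci_frame,
    read_domain_table,
    read_genbank,
    read_taxonomy,
    write_frame,
)
from .model import Architecture, GenomeRecord, Locus
from .neighborhood import NeighborhoodParams, cross_phyla_filter, extract_locus
from .phyletics import dedupe_taxa, matrix_long, presence_matrix
from .registry import DomainRegistry, default_registry

log = logging.getLogger("brexmap")

ANCHOR_DOMAINS = ("AAA_ATPase", "PglZ_core")  # BrxC/DUF499 and PglZ anchors


@dataclass
class RunConfig:
    genomes_dir: str
    out_dir: str
    taxonomy: str | None = None
    domain_tables: list[str] = field(default_factory=list)
    neighborhood: NeighborhoodParams = field(default_factory=NeighborhoodParams)
    cluster: ClusterParams = field(default_factory=lambda: ClusterParams(mode="greedy_incremental"))
    max_mismatch_fraction: float = 0.1
    annotate_members: str = "all"  # "all" | "representative"
    seed: int = 0
    plots: bool = False
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        nb = NeighborhoodParams(**raw.pop("neighborhood", {}))
        cl = ClusterParams(**{"mode": "greedy_incremental", **raw.pop("cluster", {})})
        return cls(neighborhood=nb, cluster=cl, **raw)

    def validate(self) -> None:
        if not Path(self.genomes_dir).is_dir():
            raise FileNotFoundError(f"genomes_dir {self.genomes_dir} does not exist")
        if self.taxonomy and not Path(self.taxonomy).is_file():
            raise FileNotFoundError(f"taxonomy table {self.taxonomy} does not exist")
        if self.annotate_members not in ("all", "representative"):
            raise ValueError("annotate_members must be 'all' or 'representative'")


def _find_anchor_genes(
    genome: GenomeRecord, registry: DomainRegistry, max_mismatch_fraction: float
) -> list[str]:
    anchor_registry = DomainRegistry(
        {d: registry[d] for d in ANCHOR_DOMAINS}, version=registry.version
    )
    anchors = []
    for g in genome.genes:
        if call_domains(g.translation, anchor_registry, max_mismatch_fraction):
            anchors.append(g.gene_id)
    return anchors


def _dedupe_loci(loci: list[Locus]) -> list[Locus]:
    """Merge loci sharing any member gene; keep the leftmost anchor."""
    by_key: dict[tuple[str, frozenset[str]], Locus] = {}
    for loc in loci:
        key = (loc.genome_id, frozenset(g.gene_id for g in loc.member_genes))
        prev = by_key.get(key)
        if prev is None or loc.member_genes[0].gene_id == loc.anchor_gene_id:
            anchor_start = min(
                (g.start for g in loc.member_genes if g.gene_id == loc.anchor_gene_id)
            )
            prev_start = (
                min(g.start for g in prev.member_genes if g.gene_id == prev.anchor_gene_id)
                if prev
                else None
            )
            if prev is None or anchor_start < prev_start:
                by_key[key] = loc
    return sorted(by_key.values(), key=lambda l: (l.genome_id, l.span[0]))


def run_scan(config: RunConfig, registry: DomainRegistry | None = None) -> dict:
    """Execute all stages; write the output bundle; return it in memory."""
    config.validate()
    registry = registry or default_registry()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=config.log_level)
    manifest: dict = {
        "tool": "brexmap",
        "version": __version__,
        "registry_version": registry.version,
        "seed": config.seed,
        "params": {
            "neighborhood": asdict(config.neighborhood),
            "cluster": asdict(config.cluster),
            "max_mismatch_fraction": config.max_mismatch_fraction,
            "annotate_members": config.annotate_members,
        },
        "stages": {},
    }

    # stage: read
    paths = sorted(
        p for ext in ("*.gb", "*.gbk", "*.gbff") for p in Path(config.genomes_dir).glob(ext)
    )
    genomes: list[GenomeRecord] = []
    for p in paths:
        genomes.extend(read_genbank(p))
    if not genomes:
        raise FileNotFoundError(f"no GenBank files found under {config.genomes_dir}")
    manifest["stages"]["read"] = {
        "files": len(paths),
        "genomes": len(genomes),
        "genes": sum(len(g.genes) for g in genomes),
    }
    log.info("read %d genomes (%d genes)", len(genomes), manifest["stages"]["read"]["genes"])

    # stage: anchors + loci
    loci: list[Locus] = []
    for gm in genomes:
        anchors = _find_anchor_genes(gm, registry, config.max_mismatch_fraction)
        loci.extend(extract_locus(gm, a, config.neighborhood) for a in anchors)
    loci = _dedupe_loci(loci)
    manifest["stages"]["loci"] = {"anchored_loci": len(loci)}
    log.info("extracted %d candidate loci", len(loci))

    # gene ids are unique per cohort (the generator prefixes them by genome)
    gene_seq = {g.gene_id: g.translation for loc in loci for g in loc.member_genes}

    # stage: cluster
    clusters = greedy_dedupe(gene_seq, config.cluster) if gene_seq else None
    if clusters is not None:
        cluster_rows = [
            {"cluster_id": f"C{i:05d}", "representative_id": rep, "member_id": m}
            for i, (rep, members) in enumerate(clusters.clusters)
            for m in members
        ]
        write_frame(
            pd.DataFrame(cluster_rows, columns=["cluster_id", "representative_id", "member_id"]),
            out / "clusters",
        )
        manifest["stages"]["cluster"] = {
            "proteins": len(gene_seq),
            "clusters": len(clusters.clusters),
        }

    # stage: annotate + component calls
    imported_hits: dict[str, list] = defaultdict(list)
    for table in config.domain_tables:
        for row in read_domain_table(table, set(registry.entries)):
            imported_hits[row.protein_id].append(row)
    if imported_hits:
        comp_calls = {}
        for pid, hits in imported_hits.items():
            arch = compose_architecture(pid, hits, source="imported")
            comp_calls[pid] = call_component(arch)
        architectures = {
            pid: compose_architecture(pid, hits, source="imported")
            for pid, hits in imported_hits.items()
        }
    elif config.annotate_members == "representative" and clusters is not None:
        rep_seqs = {rep: gene_seq[rep] for rep in clusters.representative_ids}
        rep_arch = {
            rep: compose_architecture(rep, call_domains(seq, registry, config.max_mismatch_fraction))
            for rep, seq in rep_seqs.items()
        }
        membership = clusters.membership()
        architectures = {
            gid: Architecture(gid, rep_arch[membership[gid]].domains) for gid in gene_seq
        }
        comp_calls = {gid: call_component(arch) for gid, arch in architectures.items()}
    else:
        architectures = {}
        comp_calls = {}
        seq_cache: dict[str, Architecture] = {}
        for gid, seq in gene_seq.items():
            if seq not in seq_cache:
                seq_cache[seq] = compose_architecture(
                    "", call_domains(seq, registry, config.max_mismatch_fraction)
                )
            architectures[gid] = Architecture(gid, seq_cache[seq].domains)
            comp_calls[gid] = call_component(architectures[gid])
    manifest["stages"]["annotate"] = {
        "proteins": len(gene_seq),
        "called": sum(1 for c in comp_calls.values() if c.component != "unknown"),
    }

    for loc in loci:
        loc.component_calls = {
            g.gene_id: comp_calls[g.gene_id] for g in loc.member_genes if g.gene_id in comp_calls
        }

    # stage: classify + effectors
    system_calls = [classify_locus(loc) for loc in loci]
    effectors = []
    for loc, call in zip(loci, system_calls):
        effectors.extend(catalog_effectors(loc, call, architectures))
    manifest["stages"]["classify"] = {
        "calls": len(system_calls),
        "discarded": sum(1 for c in system_calls if c.completeness == "discarded"),
    }

    # stage: cross-phyla flag + phyletics
    taxonomy = None
    genome_to_assembly = {g.genome_id: g.assembly_id for g in genomes}
    genome_taxid = {g.genome_id: g.taxid for g in genomes}
    matrices: dict[str, pd.DataFrame] = {}
    if config.taxonomy:
        taxonomy = read_taxonomy(config.taxonomy)
        kept, flagged = cross_phyla_filter(
            loci, taxonomy, genome_to_assembly, config.neighborhood
        )
        manifest["stages"]["cross_phyla"] = {"kept": len(kept), "flagged": len(flagged)}
        tax_by_assembly = dict(zip(taxonomy["assembly_id"], taxonomy["taxid"]))
        genome_taxid = {
            gid: tax_by_assembly.get(asm, genome_taxid.get(gid))
            for gid, asm in genome_to_assembly.items()
        }
        summary = dedupe_taxa(
            system_calls,
            {g: t for g, t in genome_taxid.items() if t is not None},
            genome_of_locus={loc.locus_id: loc.genome_id for loc in loci},
        )
        for by in ("subtype", "component"):
            matrices[by] = presence_matrix(summary, taxonomy, rank="phylum", by=by)
            write_frame(matrices[by].reset_index(), out / f"phyletic_matrix_{by}")
            write_frame(matrix_long(matrices[by]), out / f"phyletic_matrix_{by}_long")
        write_frame(summary, out / "taxid_summary")
        manifest["stages"]["phyletics"] = {
            "unique_taxids": int(summary["taxid"].nunique()) if len(summary) else 0,
        }
        if config.plots:
            from .phyletics import plot_heatmap

            plot_heatmap(matrices["subtype"], str(out / "phyletic_matrix_subtype.png"))
    else:
        log.info("no taxonomy table supplied: cross-phyla and phyletics stages skipped")
        manifest["stages"]["phyletics"] = "skipped (no taxonomy)"

    # outputs
    write_frame(loci_frame(loci), out / "loci")
    write_frame(calls_frame(system_calls), out / "system_calls")
    write_frame(effectors_frame(effectors), out / "effectors")
    report = summarize_cohort(system_calls, effectors)
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
        fh.write("\n")
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return {
        "manifest": manifest,
        "loci": loci,
        "system_calls": system_calls,
        "effectors": effectors,
        "report": report,
        "matrices": matrices,
    }


def run_report(out_dir: str | Path) -> str:
    """Human-readable summary of a scan bundle (idempotent)."""
    out = Path(out_dir)
    lines = ["brexmap scan report", "===================", ""]
    report_path = out / "report.json"
    if not report_path.is_file():
        lines.append("no report.json found: run scan first")
    else:
        with open(report_path) as fh:
            report = json.load(fh)
        lines.append(f"loci classified: {report['n_loci']}")
        lines.append("")
        lines.append("subtype counts:")
        for subtype, n in report["subtype_counts"].items():
            lines.append(f"  {subtype:<12} {n}")
        lines.append("")
        lines.append("completeness:")
        for k, n in report["completeness_counts"].items():
            lines.append(f"  {k:<12} {n}")
        lines.append("")
        lines.append("effector roles:")
        for k, n in report["effector_role_counts"].items():
            lines.append(f"  {k:<12} {n}")
        if report["discarded"]:
            lines.append("")
            lines.append(f"discarded loci ({len(report['discarded'])}):")
            for d in report["discarded"][:20]:
                lines.append(f"  {d['locus_id']}: {d['reason']}")
    for name in ("phyletic_matrix_subtype.tsv",):
        p = out / name
        if p.is_file():
            lines.append("")
            lines.append(f"phyletic matrix ({name}):")
            lines.append(p.read_text().rstrip())
        else:
            lines.append("")
            lines.append(f"{name}: absent")
    text = "\n".join(lines) + "\n"
    (out / "report.txt").write_text(text)
    return text
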