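import pytest

from brexmap.model import ComponentCall, GeneRecord, Locus, OperonBlock
from brexmap.pipeline import RunConfig, run_scan
from brexmap.synthdata import CohortSpec, GRAMMARS, synth_cohort


@pytest.fixture(scope="session")
def small_cohort(tmp_path_factory):
    """Noiseless cohort with 2 taxa per subtype, written to disk with truth."""
    out = tmp_path_factory.mktemp("cohort")
    spec = CohortSpec(subtype_mix={s: 2 for s in GRAMMARS}, seed=101)
    genomes, truth = synth_cohort(spec, out_dir=out)
    return {"dir": out, "genomes": genomes, "truth": truth, "spec": spec}


@pytest.fixture(scope="session")
def small_bundle(small_cohort, tmp_path_factory):
    """Full scan of the small noiseless cohort."""
    out = tmp_path_factory.mktemp("scan")
    config = RunConfig(
        genomes_dir=str(small_cohort["dir"]),
        taxonomy=str(small_cohort["dir"] / "taxonomy.tsv"),
        out_dir=str(out),
        log_level="WARNING",
    )
    bundle = run_scan(config)
    bundle["out_dir"] = out
    return bundle


def make_locus(components, anchor_index=0, genome_id="G1", flags_by_index=None):
    """Build a one-block locus whose genes carry the given component calls."""
    flags_by_index = flags_by_index or {}
    genes = []
    calls = {}
    pos = 0
    for i, comp in enumerate(components):
        gid = f"g{i}"
        genes.append(
            GeneRecord(gid, pos, pos + 300, "+", "M" * 99, genome_id=genome_id)
        )
        calls[gid] = ComponentCall(
            protein_id=gid,
            component=comp,
            fusion_flags=frozenset(flags_by_index.get(i, ())),
        )
        pos += 350
    locus = Locus(
        locus_id=f"{genome_id}:g{anchor_index}",
        genome_id=genome_id,
        anchor_gene_id=f"g{anchor_index}",
        blocks=[OperonBlock(genes=genes, strand="+")],
    )
    locus.component_calls = calls
    return locus
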