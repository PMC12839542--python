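import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from brexmap.model import ComponentCall, GeneRecord, GenomeRecord
from brexmap.neighborhood import (
    NeighborhoodParams,
    archetype_key,
    build_operon_blocks,
    cross_phyla_filter,
    extract_locus,
    intergenic_gap,
)
from conftest import make_locus


def _gene(gid, start, end, strand="+", genome="G"):
    return GeneRecord(gid, start, end, strand, "M" * 60, genome_id=genome)


def _genome(genes, length=100_000):
    return GenomeRecord("G", "ASM", 1, length, genes=list(genes))


class TestIntergenicGap:
    def test_hand_traced_convention(self):
        assert intergenic_gap(_gene("a", 100, 400), _gene("b", 449, 900)) == 49

    def test_abutting_genes_have_zero_gap(self):
        assert intergenic_gap(_gene("a", 100, 400), _gene("b", 400, 600)) == 0

    def test_overlap_is_negative(self):
        assert intergenic_gap(_gene("a", 100, 400), _gene("b", 390, 600)) == -10

    def test_cross_genome_comparison_rejected(self):
        with pytest.raises(ValueError, match="different genomes"):
            intergenic_gap(_gene("a", 0, 10, genome="G1"), _gene("b", 20, 30, genome="G2"))


class TestOperonBlocks:
    def test_hand_traced_split_at_threshold(self):
        genome = _genome([
            _gene("g1", 100, 400), _gene("g2", 449, 900), _gene("g3", 1100, 1500),
        ])
        blocks = build_operon_blocks(genome, NeighborhoodParams(max_gap_nt=100))
        assert [[g.gene_id for g in b.genes] for b in blocks] == [["g1", "g2"], ["g3"]]

    def test_strand_change_splits_block(self):
        genome = _genome([
            _gene("g1", 0, 100), _gene("g2", 110, 200), _gene("g3", 210, 300, strand="-"),
        ])
        blocks = build_operon_blocks(genome)
        assert len(blocks) == 2
        blocks_any = build_operon_blocks(genome, NeighborhoodParams(strand_mode="any"))
        assert len(blocks_any) == 1

    def test_single_gene_is_singleton_block(self):
        blocks = build_operon_blocks(_genome([_gene("g1", 5, 50)]))
        assert len(blocks) == 1 and len(blocks[0].genes) == 1

    def test_overlapping_genes_always_coblock(self):
        genome = _genome([_gene("g1", 0, 500), _gene("g2", 450, 900)])
        blocks = build_operon_blocks(genome, NeighborhoodParams(max_gap_nt=0))
        assert len(blocks) == 1

    @given(st.data())
    @settings(max_examples=150, deadline=None)
    def test_partition_matches_brute_force(self, data):
        n = data.draw(st.integers(1, 15))
        gaps = data.draw(st.lists(st.integers(-50, 300), min_size=n - 1, max_size=n - 1))
        strands = data.draw(st.lists(st.sampled_from("+-"), min_size=n, max_size=n))
        genes, pos = [], 0
        for i in range(n):
            genes.append(_gene(f"g{i}", pos, pos + 200, strands[i]))
            pos += 200 + (gaps[i] if i < n - 1 else 0)
            pos = max(pos, genes[-1].start + 1)
        genes = sorted(genes, key=lambda g: g.start)
        params = NeighborhoodParams(max_gap_nt=100)
        blocks = build_operon_blocks(_genome(genes, length=10**9), params)
        # partition property: concatenating blocks restores the gene order
        flat = [g.gene_id for b in blocks for g in b.genes]
        assert flat == [g.gene_id for g in genes]
        # brute-force reference: split wherever gap or strand breaks the run
        expected, cur = [], [genes[0]]
        for prev, g in zip(genes, genes[1:]):
            if g.start - prev.end <= 100 and g.strand == prev.strand:
                cur.append(g)
            else:
                expected.append(cur)
                cur = [g]
        expected.append(cur)
        assert [[g.gene_id for g in b.genes] for b in blocks] == [
            [g.gene_id for g in b] for b in expected
        ]
        # monotonicity: a larger threshold never splits more
        wider = build_operon_blocks(_genome(genes, length=10**9),
                                    NeighborhoodParams(max_gap_nt=250))
        assert len(wider) <= len(blocks)


class TestExtractLocus:
    def test_anchor_block_only(self):
        genome = _genome([
            _gene("g1", 100, 400), _gene("g2", 449, 900), _gene("g3", 1100, 1500),
        ])
        locus = extract_locus(genome, "g2")
        assert [g.gene_id for g in locus.member_genes] == ["g1", "g2"]

    def test_divergent_adjacent_block_admitted(self):
        genome = _genome([
            _gene("g1", 0, 500), _gene("g2", 540, 900), _gene("g3", 980, 1400, strand="-"),
        ])
        locus = extract_locus(genome, "g1")
        assert [g.gene_id for g in locus.member_genes] == ["g1", "g2", "g3"]
        assert len(locus.blocks) == 2

    def test_singleton_anchor(self):
        genome = _genome([_gene("g1", 5, 50)])
        locus = extract_locus(genome, "g1")
        assert [g.gene_id for g in locus.member_genes] == ["g1"]

    def test_unknown_anchor_rejected(self):
        with pytest.raises(KeyError):
            extract_locus(_genome([_gene("g1", 5, 50)]), "nope")

    def test_planted_operon_recovered_exactly(self, small_cohort):
        truth = small_cohort["truth"]
        lt = next(t for t in truth["loci"] if t["subtype"] == "Type-4")
        genome = next(
            g for g in small_cohort["genomes"] if g.genome_id == lt["genome_id"]
        )
        locus = extract_locus(genome, lt["gene_ids"][0])
        assert sorted(g.gene_id for g in locus.member_genes) == sorted(lt["gene_ids"])
        assert list(locus.span) == lt["span"]


class TestCrossPhylaFilter:
    @staticmethod
    def _setup():
        taxonomy = pd.DataFrame(
            {"assembly_id": ["A1", "A2", "A3"], "taxid": [1, 2, 3],
             "phylum": ["PhyA", "PhyB", "PhyA"]}
        )
        g2a = {"G1": "A1", "G2": "A2", "G3": "A3", "G4": "missing"}
        return taxonomy, g2a

    def test_two_phyla_archetype_kept(self):
        taxonomy, g2a = self._setup()
        loci = [
            make_locus(["BrxC", "BrxX"], genome_id="G1"),
            make_locus(["BrxC", "BrxX"], genome_id="G2"),
        ]
        kept, flagged = cross_phyla_filter(loci, taxonomy, g2a)
        assert len(kept) == 2 and not flagged

    def test_single_phylum_archetype_flagged_not_deleted(self):
        taxonomy, g2a = self._setup()
        loci = [
            make_locus(["BrxC", "BrxX"], genome_id="G1"),
            make_locus(["BrxC", "BrxX"], genome_id="G3"),  # same phylum PhyA
            make_locus(["PglZ", "HerA_FtsK"], genome_id="G1"),
            make_locus(["PglZ", "HerA_FtsK"], genome_id="G2"),
        ]
        kept, flagged = cross_phyla_filter(loci, taxonomy, g2a)
        assert len(kept) == 2 and len(flagged) == 2
        assert all("phyla_support" in l.flags for l in flagged)
        assert {archetype_key(l) for l in flagged} == {("BrxC", "BrxX")}

    def test_missing_taxonomy_flagged_separately(self):
        taxonomy, g2a = self._setup()
        loci = [make_locus(["BrxC"], genome_id="G4")]
        kept, flagged = cross_phyla_filter(loci, taxonomy, g2a)
        assert not kept and "no_taxonomy" in flagged[0].flags


def test_locus_gene_count_monotone_in_gap_threshold(small_cohort):
    lt = small_cohort["truth"]["loci"][0]
    genome = next(
        g for g in small_cohort["genomes"] if g.genome_id == lt["genome_id"]
    )
    anchor = lt["gene_ids"][0]
    sizes = []
    for gap in (0, 50, 100, 300, 600):
        locus = extract_locus(genome, anchor, NeighborhoodParams(max_gap_nt=gap))
        sizes.append(len(locus.member_genes))
    assert sizes == sorted(sizes)
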