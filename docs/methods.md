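# Methods

## Scope and model

`brexmap` treats a defense system as a *gene-neighborhood archetype*: a
multiset of canonical components realized as an operon. The analysis is a
deterministic pipeline — no statistical model is fitted — whose scientific
content lies in four places: the neighborhood-reconstruction filters, the
architecture→component rule table, the subtype decision list, and the
TaxID-deduplicated counting scheme. Each is described below together with
the numerical and design choices that were genuinely open.

## Coordinates and formats

Internally every interval is 0-based half-open on the genome forward
strand; the GenBank 1-based inclusive convention is converted only at the
I/O boundary. Intergenic gap is therefore `g2.start − g1.end` — the number
of bases strictly between two genes, negative when they overlap — with no
sign corrections anywhere else. Compound (join) CDS locations are
collapsed to their outer span: the gap logic needs a single interval per
gene, and the defense operons modelled here are single-exon. Genes on
either strand keep genome-forward coordinates with the strand stored
separately, because the proximity filter is defined on genomic positions,
not transcripts. Multiple replicons of one assembly are independent
`GenomeRecord`s sharing `assembly_id`/`taxid`; loci never span replicons.

## Locus reconstruction

Three contextual filters define a candidate locus around an anchor gene
(the BrxC/DUF499-class ATPase or PglZ — the two components conserved
across all subtypes):

1. **Proximity.** Maximal runs of consecutive genes with intergenic gap
   ≤ `max_gap_nt` form operon blocks. The threshold defaults to 100 nt;
   the quantity is inherently fuzzy ("roughly 100"), so it is a parameter
   with that default. Overlapping genes (negative gap) always co-block.
2. **Orientation.** Blocks are same-strand by default. A strictly
   same-strand *locus* would, however, contradict the mixed-orientation
   neighborhoods drawn for real systems, so the locus admits divergently
   oriented *neighboring blocks* whose nearest edge lies within
   `max_gap_nt` of the growing locus span, inside a window of
   `window_genes` (default 10) genes on each side of the anchor. Ten
   covers the largest described system (seven-component BRC) with margin.
3. **Cross-phyla support.** Loci are grouped by archetype key (the sorted
   multiset of component names); archetypes observed in fewer than
   `min_phyla` (default 2) distinct phyla are *flagged*, not deleted —
   the filter is a curation confidence signal, and near-misses stay
   available downstream.

## Component calling

Two annotation channels feed one rule engine. On generated cohorts,
domains are found by scanning proteins for registry *signature blocks*
(60-aa sequences unique per domain) with a sliding window tolerating a
mismatch fraction of at most 0.1; overlapping candidate hits are resolved
greedily, highest score first (ties: longer hit, then smaller start). For
real proteins the only supported channel is an imported domain-hit table
(hmmscan-domtblout-like TSV) — the signature matcher makes no claim on
real sequences, and remote-homology detection is explicitly out of scope.
Distinguishing catalytically intact STAND NTPases from eroded iSTANDs is
a registry property (`walker_intact`), not a sequence test: imported
tables must carry that distinction.

The rule table maps ordered architectures to components. Mandatory
domains must appear as an ordered subsequence — extra uncalled segments
are tolerated because lineage-specific insertions are ubiquitous — while
`exact` rules (single-domain components such as BrxD, BrxE, standalone
effectors) require the architecture to contain nothing else. Rules are
ordered most-specific-first in tiers; within a tier evaluation order is
immaterial (tested). When no rule matches fully, the *best-supported*
rule — highest fraction of its mandatory domains present in order, with
at least half present — yields a `partial` call. Selecting by support
fraction rather than rule order matters: a BrxC that lost one domain
shares three domains with the more specific DUF499 rule, and first-match
semantics would misroute whole loci into the BR family. Partial calls
exist because truncated genes at contig edges are common, and incomplete
neighborhoods should be discarded at the classification stage, not here.

BrxA and DUF4007 are architecture-identical at the family level (2–3
consecutive HTH units and nothing else) but are distinct protein
families, so the registry gives them distinct HTH signatures. The
standalone iSTAND component is called generically and renamed to its
subtype-contextual homolog (BrxB in the Type-1 family, BrxF in Type-3)
after subtype assignment.

## Subtype decision list

First match wins, with the uniquely diagnostic anchors tested before the
shared ones (PglZ and BrxC occur across systems; HerA/FtsK and DUF499 do
not):

1. HerA/FtsK + PglZ + BrxC-like ATPase → **BRC**;
2. DUF499 → BR family: PglZ in locus → **Type-3 BR**; DUF3780 or an
   HKD-fused helicase → **Type-2 BR**; else **Type-1 BR**;
3. BrxP with no methyltransferase component → **Type-4**;
4. PglW, or BrxD + BrxHI → **Type-2**;
5. BrxXI, or standalone iSTAND + BrxHII without BrxX → **Type-3**;
6. BrxC + BrxX + PglZ → Type-1 family: BrxE → **Type-6**; extra
   BrxHII-class helicase → **Type-5**; else **Type-1**;
7. else unassigned.

Types 5 and 6 always carry `family_group = Type-1-family`: their
composition differs from Type-1 only by an extra helicase or BrxE. A
locus containing both BrxE and an extra helicase resolves Type-6-first
and is flagged `type6_with_extra_helicase` for review. Completeness is
graded against the subtype's mandatory component set: `complete` when all
are present, `partial` when ≥ 3 components including the anchor are
present (three spans the minimal tripartite core of every described
system; no published count exists), otherwise `discarded` with a reason.

Effector roles are a fixed ontology (see README), applied over the called
architectures: the primary nuclease is never re-counted as auxiliary, an
effector domain inside a multi-domain core component has provenance
`core_component_fusion`, a standalone effector gene in the anchor block
`standalone_in_locus`, genes in admitted neighboring blocks `flanking`,
and any nuclease gene adjacent to an OLD-ABC gene forms a backup dyad.

## Clustering semantics

`single_linkage_cluster` mirrors BLASTCLUST: an edge joins two sequences
when alignment coverage on both is ≥ L (default 0.5, meaningful range
0.2–0.5) and the score density is ≥ S (default 50, range 20–50); clusters
are connected components, order-independent by construction. S is
interpreted as bits per alignment column — the documented meaning of the
BLASTCLUST threshold when it exceeds 3, and the only reading consistent
with a 20–50 range. `greedy_dedupe` mirrors CD-HIT: longest-first greedy
assignment (ties by id, making the representative choice reproducible) to
the first representative with identity ≥ c (default 0.9, range 0.4–0.9),
with a word-length-n k-mer count prefilter. The prefilter is provably
conservative for substitution-type divergence: a pair at identity ≥ c
must share at least `n_k − k·m` words of the shorter sequence (m = maximal
mismatch count); when that bound is not positive the filter abstains, so
it never skips a qualifying pair. The native scorer is an end-gap-free
global alignment under BLOSUM62 with gap open 11 / extend 1 (BLAST
defaults); identity and score density are computed over alignment columns
excluding terminal gaps — end-gap-free semantics is what both emulated
tools approximate, and the denominator is stated here because neither
defines it precisely. Both reference tools tuned their thresholds per
family in the original analyses; the defaults here are mid-range choices,
and bit-for-bit reproduction of either tool is a non-goal.

## Entropy

Per column, `H = −Σᵢ pᵢ log₂ pᵢ` over the residue types present. The
minus sign and the base are fixed by the stated range: 0 for complete
conservation up to 4.32 = log₂ 20 when all twenty residues are equally
represented. Gaps are excluded from the frequencies (a 21-symbol support
would allow H > log₂ 20) and nonstandard residues (B, Z, X, U, O) are
excluded and tallied separately. The reduced alphabet is a Murphy-style
8-class chemical partition {LVIMC}{AG}{ST}{P}{FWY}{EDNQ}{KR}{H} — the
source analyses name only "an 8-residue alphabet based on chemical
properties", so a widely used partition with exactly eight classes ships
as the default and is user-overridable. Because the 8-class map is a
coarsening of the identity map, H8 ≤ H20 holds column-wise (data-
processing inequality); this, the bounds, and merge-monotonicity are
enforced as property tests. Sequence weighting and gappy-column removal
are off by default and exposed as options; columns with gap fraction
above 0.5 are flagged, not dropped. The export signs the 20-alphabet
track positive and the 8-alphabet track negative to mirror the standard
above/below-zero bar layout.

## Phyletic counting

All phyletic statistics count unique species-level TaxIDs: a TaxID counts
once per subtype (or per component) regardless of assemblies and loci,
and may count for several subtypes. Matrices are grouped strictly by a
single chosen rank (default phylum), with TaxIDs missing that rank
bucketed under `unclassified`; mixed-rank rollups are left to a
user-supplied grouping. Retention of a component is reported relative to
an anchor: taxa carrying the component divided by taxa carrying the
component that defines membership (e.g. BrxC for the Type-1 family).

## Synthetic cohorts

The generator is first-class, tested code, and its defaults are the study
conditions for every end-to-end guarantee:

- Each of the ten subtype grammars lists component slots in gene order;
  grammar-core slots have probability 1 (the six-gene Type-1 core, the
  tripartite BR cores, the seven BRC components), optional slots model
  documented variation (BrxL carries LonP in 75% / HKD-endoDNase in 25%
  of draws; DUF499 carries an N-terminal HEPN in half of Type-1 BR draws;
  a standalone HNH occurs in 20% and a flanking OLD-ABC+TOPRIM dyad in
  15% of Type-1 loci; DUF3780 gains an ASCH/PUA extension in 30%).
- Planted proteins are concatenations of 60-aa signature blocks joined by
  15-aa low-complexity linkers. Signature-block construction (instead of
  sampling from real sequence profiles) is deliberate: profile searches
  are out of scope, and exact truth enables sharp recovery tests. The
  block length is a robustness choice: at the matcher's 10% mismatch
  tolerance, the chance that 5% i.i.d. residue noise destroys a 60-aa
  block is ≈ 3%, against ≈ 5% for 40-aa blocks (binomial concentration).
- Signatures avoid tryptophan entirely and are pairwise 12-mer-disjoint;
  decoy proteins carry a periodic W lattice, so no decoy window can reach
  90% identity to any signature — decoys share no signature k-mers by
  construction.
- Intra-operon gaps are drawn from 5–80 nt (below the 100-nt threshold);
  flanking blocks sit 20–90 nt from the core on the opposite strand,
  exercising the divergent-block admission rule; planted loci are
  isolated from decoys by five times the gap threshold, so truth loci are
  unambiguous for any configured threshold at or below that margin.
- Default cohort: 20 taxa per subtype across four phyla (round-robin, so
  every subtype spans ≥ 2 phyla), 1–2 assemblies per taxon duplicating
  the same planted locus (exercising TaxID dedup), 6–12 decoy genes per
  genome, linkers drifting at 10% between taxa (signatures exact in
  noiseless mode). The noise model is i.i.d. residue substitution at rate
  ε plus optional component dropout — the simplest controls for
  robustness experiments.
- One RNG stream per cohort, sub-streamed per taxon via `SeedSequence`
  spawning; output is byte-identical for a fixed seed (the GenBank writer
  pins the LOCUS date for this reason).

What the generator does **not** emulate — realistic domain sequence
variation, sequence evolution, codon structure, real phage or genome
backgrounds, contig fragmentation — bounds what passing tests show:
recovery rates on these cohorts validate the *logic* of the pipeline
(reconstruction, rules, counting), not the sensitivity of any homology
search on real data. Real-data use requires externally computed domain
tables.

## Problem sizes and numerical notes

End-to-end guarantees are measured on the default 200-taxon cohort (ten
grammars × 20 loci) and a 500-taxon single-subtype cohort for retention
calibration (planted BrxL probability 0.74, recovered within its binomial
99% CI); clustering equivalence against brute-force references uses 200
seeded family instances of up to 40 sequences; entropy invariants use
10,000 random columns. Plug-in entropies agree with the generator's
closed-form truth to 1e-12 (floating-point summation only). Ties are
broken deterministically throughout: cluster representatives are the
longest member then lexicographically smallest id; domain hits by score,
length, then position; rule matches by tier order. Degenerate inputs are
defined rather than special-cased: empty cohorts yield zeroed reports,
all-gap columns yield NaN entropy, zero anchored taxa yield NA retention.

## Known limitations

- The signature matcher is not a homology detector; real-mode operation
  is import-only.
- BrxX/BrxXI/BR-MTase discrimination in imported data depends on the
  external annotator's vocabulary; the registry mapping is a user-editable
  JSON resource for that reason.
- Replicons are treated as linear; circular-origin wraparound is not
  modelled.
- The greedy clustering mode inherits CD-HIT's order-dependence by
  design; only the single-linkage mode is order-invariant. A consequence
  is that raising the identity threshold guarantees a non-decreasing
  cluster count but not exact nesting of partitions: a member that no
  longer reaches its old representative may join a cluster seeded by a
  different member.
- Genome-scale taxa counts from live databases are version-dependent and
  intentionally out of scope.
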