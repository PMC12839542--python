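# brexmap

Comparative-genomics tooling for mapping **BREX** (BacteRiophage EXclusion)
anti-phage defense systems and their relatives — the DUF499-ATPase-centred
**BR** (BREX-related) systems and the seven-component hybrid **BRC**
(BREX-related capture) system — in annotated prokaryotic genomes.

BREX systems methylate self-DNA and exclude phage DNA without classical
restriction digestion. Their loci are multi-gene operons built around a
small set of recurring components: a large ORC/Cdc6-clade AAA+ ATPase
scaffold (BrxC, or DUF499 in BR systems), an N6-adenine DNA
methyltransferase with a target-recognition domain (BrxX/BrxXI/BR-MTase),
the alkaline-phosphatase-superfamily nicking nuclease PglZ, inactivated
STAND NTPase sensors (BrxB/BrxF-type iSTANDs), HTH proteins
(BrxA, DUF4007), and subtype-specific enzymes (BrxL, PglW, BrxP, HerA/FtsK
translocases, GNAT/TGT modification enzymes). `brexmap` implements the full
desk analysis over such loci:

- **locus reconstruction** around anchor genes using three contextual
  filters: intergenic gaps at or below ~100 nt, conservation of gene
  orientation (same-strand operon blocks, with divergently oriented
  neighboring blocks admitted at the locus level), and cross-phyla
  occurrence of the assembled neighborhood archetype;
- **component calling** from ordered domain architectures (signature
  matching on generated cohorts; imported hmmscan-style domain tables for
  real proteins) through a rule table covering all described components;
- **rule-based subtype classification** into Type-1 … Type-6 BREX
  (Types 5/6 collapse into the Type-1 family group), Type-1/2/3 BR and
  BRC, with completeness grading and a reason-coded discard log;
- **effector cataloguing** with the fixed role ontology: the subtype's
  primary restriction nuclease (PglZ for every BREX subtype and Type-3 BR;
  the helicase-fused REase / HKD-endoDNase in Type-1 / Type-2 BR),
  auxiliary DNases (PD-(D/E)xK, NERD, Shedu, HNH-clade, HKD on BrxL,
  TOPRIM) and backup RNase/abortive modules (HEPN±MNT, PIN, Schlafen,
  OLD-ABC-paired dyads);
- **phyletic profiling** deduplicated by species-level NCBI TaxID: a TaxID
  counts once per subtype regardless of how many assemblies carry it;
- **alignment conservation profiles** via position-wise Shannon entropy
  `H = −Σᵢ pᵢ log₂ pᵢ` under the 20-letter alphabet (0 ≤ H ≤ log₂20 = 4.32
  bits) and a reduced 8-class chemical alphabet
  ({LVIMC}{AG}{ST}{P}{FWY}{EDNQ}{KR}{H}), exported in the above/below-zero
  dual-track layout;
- protein clustering with **BLASTCLUST-like single-linkage** (coverage L,
  bit-score density S) and **CD-HIT-like greedy-incremental** (identity c,
  word length n) semantics, backed by an end-gap-free BLOSUM62 global
  aligner;
- a **synthetic-cohort generator** that plants operons obeying each
  subtype's component grammar among decoy genes, with taxonomy labels
  spanning several phyla and machine-readable truth tables, so the whole
  pipeline is testable without any download.

## Worked example

```bash
brexmap simulate --out-dir cohort --seed 4 --subtype Type-1=2 --subtype BRC=1
brexmap scan --genomes-dir cohort --taxonomy cohort/taxonomy.tsv --out-dir scan_out
brexmap report scan_out
```

The simulator prints `wrote 4 genomes and truth tables to cohort` (three
taxa; one Type-1 taxon contributes two redundant assemblies), and the
report prints:

```
brexmap scan report
===================

loci classified: 4

subtype counts:
  BRC          1
  Type-1       3

completeness:
  complete     4

effector roles:
  primary      3

phyletic matrix (phyletic_matrix_subtype.tsv):
phylum  BRC     Type-1
Bacillota       0       1
Pseudomonadota  1       1
```

All four planted loci come back classified: the Type-1 loci are complete
six-gene cores (BrxC–BrxX–PglZ–BrxA–BrxB–BrxL) whose PglZ is the primary
effector; the BRC locus shows the seven-component architecture with a
minimal PglZ and no primary nuclease. Note the TaxID deduplication: three
Type-1 *loci* (one taxon twice, via its duplicate assembly) count as two
unique TaxIDs in the phylum × subtype matrix. `scan_out/` also holds the
loci/effectors tables, cluster table, per-locus system calls, the
discarded-locus log inside `report.json`, and a `manifest.json` with
parameters and per-stage record counts; reruns are byte-identical.

Entropy profiles for an aligned FASTA:

```bash
brexmap entropy alignment.afa --out profile
```

writes a plot-ready table with the 20-alphabet track signed positive and
the 8-alphabet track signed negative.

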