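"""Protein clustering with BLASTCLUST-like and CD-HIT-like semantics.

``single_linkage_cluster`` mirrors BLASTCLUST: an edge joins two sequences
when alignment coverage on BOTH is at least L and the score density (bits
per alignment column, BLASTCLUST's meaning of S above 3) is at least S;
clusters are connected components. ``greedy_dedupe`` mirrors CD-HIT:
longest-first greedy assignment to the first representative at identity
>= c, with a word-length k-mer count prefilter.

The native scorer is an end-gap-free global alignment under BLOSUM62 with
gap open 11 / extend 1 (BLAST defaults). Identity and score density are
computed over alignment columns excluding terminal gaps.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple

from Bio import Align
from Bio.Align import substitution_matrices


@dataclass(frozen=True)
class ClusterParams:
    mode: str = "single_linkage"  # or "greedy_incremental"
    min_coverage: float = 0.5  # BLASTCLUST -L analog (0.2-0.5) / CD-HIT short-seq coverage
    min_score_density: float = 50.0  # BLASTCLUST -S analog (20-50), bits/column
    min_identity: float = 0.9  # CD-HIT -c analog (0.4-0.9)
    word_length: int = 5  # CD-HIT -n analog (2-5)
    use_prefilter: bool = True

    def __post_init__(self) -> None:
        if self.mode not in ("single_linkage", "greedy_incremental"):
            raise ValueError(f"bad mode {self.mode!r}")
        if not (0.0 < self.min_coverage <= 1.0):
            raise ValueError("min_coverage must be in (0,1]")
        if not (0.0 < self.min_identity <= 1.0):
            raise ValueError("min_identity must be in (0,1]")
        if self.word_length < 1:
            raise ValueError("word_length must be >= 1")


@dataclass
class ClusterSet:
    clusters: list[tuple[str, list[str]]]
    params: ClusterParams = field(default_factory=ClusterParams)

    @property
    def representative_ids(self) -> list[str]:
        return [rep for rep, _ in self.clusters]

    def membership(self) -> dict[str, str]:
        return {m: rep for rep, members in self.clusters for m in members}


class PairwiseStats(NamedTuple):
    identity: float
    coverage_a: float
    coverage_b: float
    score_density: float


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    # end-gap-free global alignment
    try:
        aligner.end_insertion_score = 0.0
        aligner.end_deletion_score = 0.0
    except AttributeError:  # older Biopython
        aligner.target_end_gap_score = 0.0
        aligner.query_end_gap_score = 0.0
    aligner.mode = "global"
    return aligner


_ALIGNER = _make_aligner()


def pairwise_identity(a: str, b: str) -> PairwiseStats:
    """End-gap-free global alignment statistics for two protein sequences.

    identity = matches / alignment columns excluding terminal gaps;
    coverage_x = aligned span on x / len(x); score_density = BLOSUM62 score
    / alignment columns excluding terminal gaps.
    """
    if not a or not b:
        raise ValueError("empty sequence")
    a, b = a.upper(), b.upper()
    aln = _ALIGNER.align(a, b)[0]
    row_a, row_b = str(aln[0]), str(aln[1])
    both = [i for i in range(len(row_a)) if row_a[i] != "-" and row_b[i] != "-"]
    if not both:
        return PairwiseStats(0.0, 0.0, 0.0, 0.0)
    first, last = both[0], both[-1]
    cols = last - first + 1
    matches = sum(
        1 for i in range(first, last + 1) if row_a[i] == row_b[i] and row_a[i] != "-"
    )
    span_a = sum(1 for i in range(first, last + 1) if row_a[i] != "-")
    span_b = sum(1 for i in range(first, last + 1) if row_b[i] != "-")
    return PairwiseStats(
        identity=matches / cols,
        coverage_a=span_a / len(a),
        coverage_b=span_b / len(b),
        score_density=aln.score / cols,
    )


def _representative(members: list[str], seqs: dict[str, str]) -> str:
    return max(members, key=lambda m: (len(seqs[m]), _neg_lex(m)))


def _neg_lex(s: str):
    # max() helper: prefer lexicographically smallest id on length ties
    return tuple(-ord(c) for c in s)


def single_linkage_cluster(seqs: dict[str, str], params: ClusterParams | None = None) -> ClusterSet:
    """BLASTCLUST-style clustering: qualifying pairs are edges, clusters are
    connected components (order-independent by construction)."""
    params = params or ClusterParams(mode="single_linkage")
    ids = sorted(seqs)
    parent = {i: i for i in ids}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            st = pairwise_identity(seqs[a], seqs[b])
            if (
                st.coverage_a >= params.min_coverage
                and st.coverage_b >= params.min_coverage
                and st.score_density >= params.min_score_density
            ):
                parent[find(a)] = find(b)
    groups: dict[str, list[str]] = {}
    for i in ids:
        groups.setdefault(find(i), []).append(i)
    clusters = sorted(
        ((_representative(m, seqs), sorted(m)) for m in groups.values()),
        key=lambda c: c[0],
    )
    return ClusterSet(clusters=clusters, params=params)


def _kmers(seq: str, k: int) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def _kmer_prefilter_passes(
    short: str, long: str, c: float, k: int,
    short_kmers: set[str] | None = None, long_kmers: set[str] | None = None,
) -> bool:
    """Conservative CD-HIT-style word filter.

    A pair at identity >= c (substitution-type divergence) must share at
    least n_k - k*m k-mers of the shorter sequence, where m is the maximum
    mismatch count. When that bound is not positive the filter abstains, so
    it can only skip pairs whose true identity is below the threshold.
    """
    n = len(short)
    if n < k:
        return True
    m = math.ceil((1.0 - c) * n)
    min_shared = (n - k + 1) - k * m
    if min_shared < 1:
        return True
    if long_kmers is None:
        long_kmers = _kmers(long, k)
    if short_kmers is None:
        short_kmers = _kmers(short, k)
    if not (short_kmers & long_kmers):
        return False
    shared = sum(1 for i in range(n - k + 1) if short[i : i + k] in long_kmers)
    return shared >= min_shared


def greedy_dedupe(seqs: dict[str, str], params: ClusterParams | None = None) -> ClusterSet:
    """CD-HIT-style greedy-incremental clustering.

    Sequences are processed longest-first (ties: id order); each joins the
    first existing representative with identity >= min_identity and coverage
    of the shorter sequence >= min_coverage, else founds a new cluster.
    """
    params = params or ClusterParams(mode="greedy_incremental")
    order = sorted(seqs, key=lambda i: (-len(seqs[i]), i))
    reps: list[str] = []
    members: dict[str, list[str]] = {}
    kmer_cache: dict[str, set[str]] = {}

    def kmers_of(sid: str) -> set[str]:
        if sid not in kmer_cache:
            kmer_cache[sid] = _kmers(seqs[sid], params.word_length)
        return kmer_cache[sid]

    for sid in order:
        s = seqs[sid]
        placed = False
        for rep in reps:
            r = seqs[rep]
            short, long = (s, r) if len(s) <= len(r) else (r, s)
            short_id, long_id = (sid, rep) if len(s) <= len(r) else (rep, sid)
            if params.use_prefilter and not _kmer_prefilter_passes(
                short, long, params.min_identity, params.word_length,
                kmers_of(short_id), kmers_of(long_id),
            ):
                continue
            st = pairwise_identity(s, r)
            cov_short = st.coverage_a if len(s) <= len(r) else st.coverage_b
            if st.identity >= params.min_identity and cov_short >= params.min_coverage:
                members[rep].append(sid)
                placed = True
                break
        if not placed:
            reps.append(sid)
            members[sid] = [sid]
    clusters = [(rep, sorted(members[rep])) for rep in sorted(reps)]
    return ClusterSet(clusters=clusters, params=params)
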