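"""Domain calling and component assignment.

Two annotation channels exist: signature matching against the shipped
registry (for generated cohorts, where each protein is a concatenation of
signature blocks) and imported domain-hit tables produced by an external
annotator (the only supported channel for real proteins). Both feed the
same architecture -> component rule engine.
"""

from __future__ import annotations

import math
from collections import defaultdict

import numpy as np

from .model import Architecture, ComponentCall, DomainHitRow
from .registry import COMPONENT_RULES, ComponentRule, DomainRegistry, default_registry

DEFAULT_MAX_MISMATCH_FRACTION = 0.1


def call_domains(
    protein: str,
    registry: DomainRegistry | None = None,
    max_mismatch_fraction: float = DEFAULT_MAX_MISMATCH_FRACTION,
) -> list[DomainHitRow]:
    """Scan a protein for registry signature blocks.

    Every window within ``max_mismatch_fraction`` mismatches of a signature
    is a candidate hit scored by its match count; overlapping candidates are
    resolved greedily highest-score-first (ties: longer hit, then smaller
    start). Returns hits sorted by start position.
    """
    registry = registry or default_registry()
    protein = protein.upper()
    if not protein:
        return []
    arr = np.frombuffer(protein.encode("ascii"), dtype=np.uint8)

    by_len: dict[int, list] = defaultdict(list)
    for entry in registry:
        by_len[len(entry.signature)].append(entry)

    candidates: list[DomainHitRow] = []
    for sig_len, entries in by_len.items():
        if sig_len > len(arr) or sig_len == 0:
            continue
        max_mm = math.floor(max_mismatch_fraction * sig_len)
        sigs = np.array(
            [np.frombuffer(e.signature.encode("ascii"), dtype=np.uint8) for e in entries]
        )
        windows = np.lib.stride_tricks.sliding_window_view(arr, sig_len)
        # mismatches[w, s] = Hamming distance of window w to signature s
        mism = (windows[:, None, :] != sigs[None, :, :]).sum(axis=2)
        wpos, sidx = np.nonzero(mism <= max_mm)
        for w, s in zip(wpos.tolist(), sidx.tolist()):
            candidates.append(
                DomainHitRow(
                    protein_id="",
                    domain_name=entries[s].name,
                    aa_start=w,
                    aa_end=w + sig_len,
                    score=float(sig_len - mism[w, s]),
                )
            )

    return _greedy_nonoverlap(candidates)


def _greedy_nonoverlap(hits: list[DomainHitRow]) -> list[DomainHitRow]:
    """Keep best-scoring non-overlapping hits (score desc, longer, smaller start)."""
    ranked = sorted(
        hits, key=lambda h: (-h.score, -(h.aa_end - h.aa_start), h.aa_start, h.domain_name)
    )
    kept: list[DomainHitRow] = []
    for h in ranked:
        if all(h.aa_end <= k.aa_start or h.aa_start >= k.aa_end for k in kept):
            kept.append(h)
    return sorted(kept, key=lambda h: h.aa_start)


def compose_architecture(
    protein_id: str, hits: list[DomainHitRow], source: str = "signature"
) -> Architecture:
    """Sort and overlap-resolve hits for one protein into an Architecture."""
    resolved = _greedy_nonoverlap(
        [
            DomainHitRow(protein_id, h.domain_name, h.aa_start, h.aa_end, h.score)
            for h in hits
        ]
    )
    return Architecture(protein_id=protein_id, domains=resolved, source=source)


def _is_subsequence(needle: tuple[str, ...], haystack: list[str]) -> bool:
    it = iter(haystack)
    return all(any(x == h for h in it) for x in needle)


def _lcs_length(a: tuple[str, ...], b: list[str]) -> int:
    # small inputs; plain DP
    m, n = len(a), len(b)
    prev = [0] * (n + 1)
    for i in range(1, m + 1):
        cur = [0] * (n + 1)
        for j in range(1, n + 1):
            cur[j] = prev[j - 1] + 1 if a[i - 1] == b[j - 1] else max(prev[j], cur[j - 1])
        prev = cur
    return prev[n]


def _rule_matches(rule: ComponentRule, names: list[str]) -> bool:
    if rule.forbidden & set(names):
        return False
    if rule.exact:
        if len(rule.mandatory) == 1:
            dom = rule.mandatory[0]
            return (
                rule.min_repeat <= len(names) <= rule.max_repeat
                and all(n == dom for n in names)
            )
        return names == list(rule.mandatory)
    return _is_subsequence(rule.mandatory, names)


def _rule_flags(rule: ComponentRule, names: list[str]) -> frozenset[str]:
    flags = set(rule.fixed_flags)
    for dom, flag in rule.flag_domains:
        if dom in names:
            flags.add(flag)
    return frozenset(flags)


def call_component(
    arch: Architecture, rules: tuple[ComponentRule, ...] = COMPONENT_RULES
) -> ComponentCall:
    """Map an architecture to a canonical component.

    First fully matching rule wins (rules are ordered most-specific-first);
    if none matches fully, the first rule with at least half of its
    mandatory domains present in order yields a partial-confidence call;
    otherwise the component is "unknown".
    """
    names = arch.domain_names
    if names:
        for rule in rules:
            if _rule_matches(rule, names):
                return ComponentCall(
                    protein_id=arch.protein_id,
                    component=rule.component,
                    fusion_flags=_rule_flags(rule, names),
                    confidence="exact",
                )
        # partial fallback: the best-supported rule (highest fraction of its
        # mandatory domains present in order) wins, not the first in order —
        # otherwise a degraded architecture would be claimed by whichever
        # more-specific rule happens to share half its domains
        best: tuple[float, int, int] | None = None  # (frac, lcs, -rule_index)
        best_rule = None
        for idx, rule in enumerate(rules):
            if rule.exact or (rule.forbidden & set(names)):
                continue
            need = len(rule.mandatory)
            if need < 2:
                continue
            lcs = _lcs_length(rule.mandatory, names)
            if lcs < math.ceil(need / 2):
                continue
            key = (lcs / need, lcs, -idx)
            if best is None or key > best:
                best, best_rule = key, rule
        if best_rule is not None:
            return ComponentCall(
                protein_id=arch.protein_id,
                component=best_rule.component,
                fusion_flags=_rule_flags(best_rule, names),
                confidence="partial",
            )
    return ComponentCall(protein_id=arch.protein_id, component="unknown")


def annotate_proteins(
    proteins: dict[str, str],
    registry: DomainRegistry | None = None,
    max_mismatch_fraction: float = DEFAULT_MAX_MISMATCH_FRACTION,
) -> dict[str, ComponentCall]:
    """Signature-annotate a set of proteins and call components.

    Identical sequences are scanned once and the result mapped back to every
    carrier, mirroring the cluster-then-annotate-then-map-back loop.
    """
    registry = registry or default_registry()
    by_seq: dict[str, list[str]] = defaultdict(list)
    for pid, seq in proteins.items():
        by_seq[seq.upper()].append(pid)
    calls: dict[str, ComponentCall] = {}
    for seq, pids in by_seq.items():
        hits = call_domains(seq, registry, max_mismatch_fraction)
        for pid in pids:
            arch = compose_architecture(pid, hits)
            calls[pid] = call_component(arch)
    return calls
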