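"""Position-wise Shannon entropy of protein alignments under two alphabets.

H = -sum_i p_i log2 p_i over the residue types present in a column, giving
0 bits for a fully conserved column and log2(20) = 4.32 bits when all 20
residues are equally represented. A second track recomputes H after mapping
residues onto 8 chemical-property classes (Murphy-style partition
{LVIMC}{AG}{ST}{P}{FWY}{EDNQ}{KR}{H}), which emphasises conservation of
residue character over identity. Gaps are excluded from the frequencies;
nonstandard residues (B, Z, X, U, O) are excluded and tallied separately.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

STANDARD_RESIDUES = "ACDEFGHIKLMNPQRSTVWY"
NONSTANDARD_RESIDUES = set("BZXUO")
GAP_CHARS = set("-.")

MURPHY8_CLASSES = {
    "LVIMC": "hydrophobic",
    "AG": "small",
    "ST": "hydroxyl",
    "P": "proline",
    "FWY": "aromatic",
    "EDNQ": "acidic_amide",
    "KR": "basic",
    "H": "histidine",
}


@dataclass(frozen=True)
class AlphabetMap:
    name: str
    mapping: dict[str, str]

    def __post_init__(self) -> None:
        missing = set(STANDARD_RESIDUES) - set(self.mapping)
        if missing:
            raise ValueError(f"alphabet map {self.name!r} misses residues {sorted(missing)}")

    @property
    def class_count(self) -> int:
        return len(set(self.mapping.values()))


def identity20_map() -> AlphabetMap:
    return AlphabetMap("identity20", {r: r for r in STANDARD_RESIDUES})


def chem8_map() -> AlphabetMap:
    mapping = {r: label for group, label in MURPHY8_CLASSES.items() for r in group}
    return AlphabetMap("chem8", mapping)


def reduce_alphabet(column: list[str] | str, amap: AlphabetMap) -> Counter:
    """Map a column's residues onto alphabet classes, excluding gaps and
    nonstandard residues."""
    counts: Counter = Counter()
    for ch in column:
        c = ch.upper()
        if c in GAP_CHARS or c in NONSTANDARD_RESIDUES:
            continue
        counts[amap.mapping[c]] += 1
    return counts


def column_entropy(counts: Counter | dict[str, int]) -> float:
    """Shannon entropy (bits) of a class-count vector; NaN for empty counts."""
    total = sum(counts.values())
    if total == 0:
        return math.nan
    # summation in sorted class order: the result is then invariant to the
    # order rows were seen in (row-permutation invariance holds exactly)
    return 0.0 + -sum(
        (n / total) * math.log2(n / total)
        for _, n in sorted(counts.items())
        if n > 0
    )


@dataclass
class EntropyProfile:
    columns: pd.DataFrame  # column_index, H20, H8, gap_fraction, n_effective, flagged
    maps: tuple[str, str] = ("identity20", "chem8")
    nonstandard_tally: dict[str, int] = field(default_factory=dict)

    def to_frame(self, signed: bool = True) -> pd.DataFrame:
        """Plot-ready table: the 20-alphabet track signed positive and the
        8-alphabet track signed negative (above/below-zero bar layout)."""
        df = self.columns.copy()
        if signed:
            df["H8_signed"] = -df["H8"]
            return df[["column_index", "H20", "H8_signed", "gap_fraction", "flagged"]]
        return df


def msa_profile(
    alignment: list[tuple[str, str]],
    maps: tuple[AlphabetMap, AlphabetMap] | None = None,
    max_gap_fraction: float = 0.5,
) -> EntropyProfile:
    """Per-column entropy of an aligned FASTA under both alphabets.

    Columns whose gap fraction exceeds ``max_gap_fraction`` are flagged (not
    removed). Raises on ragged alignments, naming the offending rows.
    """
    if len(alignment) < 2:
        raise ValueError("alignment needs at least 2 rows")
    maps = maps or (identity20_map(), chem8_map())
    width = len(alignment[0][1])
    ragged = [rid for rid, seq in alignment if len(seq) != width]
    if ragged:
        raise ValueError(f"ragged alignment: rows {ragged} differ in length")
    rows = np.array([list(seq.upper()) for _, seq in alignment])
    records = []
    nonstandard: Counter = Counter()
    for j in range(width):
        col = rows[:, j]
        gaps = sum(1 for c in col if c in GAP_CHARS)
        for c in col:
            if c in NONSTANDARD_RESIDUES:
                nonstandard[c] += 1
        c20 = reduce_alphabet(col.tolist(), maps[0])
        c8 = reduce_alphabet(col.tolist(), maps[1])
        n_eff = sum(c20.values())
        records.append(
            {
                "column_index": j,
                "H20": column_entropy(c20),
                "H8": column_entropy(c8),
                "gap_fraction": gaps / len(col),
                "n_effective": n_eff,
                "flagged": gaps / len(col) > max_gap_fraction,
            }
        )
    return EntropyProfile(columns=pd.DataFrame(records), nonstandard_tally=dict(nonstandard))
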