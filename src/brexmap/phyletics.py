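"""TaxID-deduplicated phyletic profiling.

Multiple assemblies of the same organism would inflate presence counts, so
every phyletic statistic counts unique species-level TaxIDs: a TaxID
counts once per subtype (or component) no matter how many assemblies or
loci carry it, but may count for several distinct subtypes.
"""

from __future__ import annotations

import warnings

import pandas as pd

from .model import SystemCall


def dedupe_taxa(
    calls: list[SystemCall],
    genome_taxid: dict[str, int],
    genome_of_locus: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Collapse system calls to unique (taxid, subtype) and (taxid, component)
    records.

    ``genome_taxid`` maps genome_id -> taxid; locus genome ids are taken
    from ``genome_of_locus`` or parsed as the prefix of ``locus_id`` before
    ":". Loci from unmapped genomes are excluded with a warning.
    """
    rows = []
    n_unmapped = 0
    for call in calls:
        gid = (
            genome_of_locus[call.locus_id]
            if genome_of_locus is not None
            else call.locus_id.split(":", 1)[0]
        )
        taxid = genome_taxid.get(gid)
        if taxid is None:
            n_unmapped += 1
            continue
        for comp in call.components_present:
            rows.append(
                {"taxid": taxid, "subtype": call.subtype, "system": call.system,
                 "component": comp}
            )
        if not call.components_present:
            rows.append(
                {"taxid": taxid, "subtype": call.subtype, "system": call.system,
                 "component": ""}
            )
    if n_unmapped:
        warnings.warn(f"{n_unmapped} loci from genomes missing a taxid mapping; excluded")
    df = pd.DataFrame(rows, columns=["taxid", "subtype", "system", "component"])
    return df.drop_duplicates().sort_values(["taxid", "subtype", "component"]).reset_index(drop=True)


def presence_matrix(
    summary: pd.DataFrame,
    taxonomy: pd.DataFrame,
    rank: str = "phylum",
    by: str = "subtype",
) -> pd.DataFrame:
    """Count unique TaxIDs per taxonomic group x subtype (or x component).

    TaxIDs whose taxonomy row lacks the rank are bucketed under
    "unclassified". Returns a wide frame (groups as rows, sorted axes).
    """
    if by not in ("subtype", "component"):
        raise ValueError("by must be 'subtype' or 'component'")
    tax = taxonomy.drop_duplicates("taxid").set_index("taxid")
    group_of = {}
    for taxid in summary["taxid"].unique():
        if taxid in tax.index and rank in tax.columns and pd.notna(tax.at[taxid, rank]):
            group_of[taxid] = str(tax.at[taxid, rank])
        else:
            group_of[taxid] = "unclassified"
    df = summary.copy()
    df = df[df[by] != ""]
    df["group"] = df["taxid"].map(group_of)
    cells = (
        df.drop_duplicates(["taxid", by])
        .groupby(["group", by], sort=True)["taxid"]
        .nunique()
    )
    matrix = cells.unstack(fill_value=0)
    matrix = matrix.reindex(sorted(matrix.index), axis=0)
    matrix = matrix.reindex(sorted(matrix.columns), axis=1)
    matrix.index.name = rank
    matrix.columns.name = by
    return matrix


def matrix_long(matrix: pd.DataFrame) -> pd.DataFrame:
    long = matrix.stack().rename("n_taxids").reset_index()
    return long.sort_values(list(long.columns[:2])).reset_index(drop=True)


def retention_fraction(
    component: str,
    anchor: str,
    summary: pd.DataFrame,
    subtype: str | None = None,
    ndigits: int | None = 4,
) -> tuple[int, float]:
    """Fraction of anchored taxa that retain a component.

    ``anchor`` is the component whose presence defines membership (e.g. the
    BrxC ATPase for the Type-1 family); restricting to a subtype first is
    optional. Returns (count, fraction); fraction is NaN when no taxon
    carries the anchor.
    """
    df = summary
    if subtype is not None:
        df = df[df["subtype"] == subtype]
    anchored = set(df.loc[df["component"] == anchor, "taxid"])
    if not anchored:
        return 0, float("nan")
    carrying = set(df.loc[df["component"] == component, "taxid"]) & anchored
    frac = len(carrying) / len(anchored)
    if ndigits is not None:
        frac = round(frac, ndigits)
    return len(carrying), frac


def plot_heatmap(matrix: pd.DataFrame, path: str) -> None:
    """Render the group x subtype count matrix as a heatmap image."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import seaborn as sns

    fig, ax = plt.subplots(
        figsize=(1.2 * max(4, len(matrix.columns)), 0.6 * max(4, len(matrix.index)))
    )
    sns.heatmap(matrix, annot=True, fmt="d", cmap="YlOrRd", ax=ax)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
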