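"""Genotype-frequency, expression-status and geographic-diversity summaries.

These are the population-arithmetic stages of the analysis: how common each
multilocus genotype is, how many intact (active) genes each accession
carries - in particular whether all three i-type genes are active, the
expression dose thought to matter for dough quality - and how genes,
variants and genotypes distribute over the collection regions, which is
what identifies a putative center of diversity.

A genotype table is a pandas DataFrame with one row per accession and
columns ``accession_id``, ``region``, ``genotype``, ``variants`` (tuple of
variant names) and ``active_variants`` (tuple, a subset of ``variants``).
Percentages are rounded half-up to two decimals, matching the style of
printed population tables.
"""

from __future__ import annotations

import pandas as pd

from .errors import ConsistencyError, InputError
from .util import percent

REQUIRED_COLUMNS = ("accession_id", "region", "genotype", "variants")


def validate_genotype_table(
    table: pd.DataFrame, regions: tuple[str, ...] | None = None
) -> None:
    """Check table invariants: columns, unique accessions, active subsets."""
    for col in REQUIRED_COLUMNS:
        if col not in table.columns:
            raise InputError(f"genotype table lacks column {col!r}")
    if table.empty:
        raise InputError("genotype table is empty")
    if table["accession_id"].duplicated().any():
        dup = table.loc[table["accession_id"].duplicated(), "accession_id"]
        raise ConsistencyError(f"duplicate accession {dup.iloc[0]!r}")
    if regions is not None:
        unknown = sorted(set(table["region"]) - set(regions))
        if unknown:
            raise InputError(f"unknown region label(s): {', '.join(unknown)}")
    if "active_variants" in table.columns:
        for row in table.itertuples(index=False):
            if not set(row.active_variants) <= set(row.variants):
                raise ConsistencyError(
                    f"{row.accession_id}: active variants not a subset of "
                    "the variant multiset"
                )


def genotype_summary(table: pd.DataFrame) -> pd.DataFrame:
    """Accession counts and percentage shares per genotype, largest first."""
    validate_genotype_table(table)
    total = len(table)
    counts = table.groupby("genotype")["accession_id"].count()
    df = (
        counts.rename("n_accessions")
        .reset_index()
        .sort_values(["n_accessions", "genotype"], ascending=[False, True])
        .reset_index(drop=True)
    )
    df["share_pct"] = [percent(n, total) for n in df["n_accessions"]]
    return df


def active_gene_census(
    table: pd.DataFrame,
    variant_types: dict[str, str],
    active_variants: set[str] | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Per-accession count of active genes by subunit type.

    ``variant_types`` maps variant name -> i/m/s.  Active status is read
    from the table's ``active_variants`` column unless an explicit
    ``active_variants`` set is given (e.g. ORF calls from annotation).
    Returns the per-accession table and a summary with the share of
    accessions carrying three active i-type genes.
    """
    validate_genotype_table(table)
    missing = sorted(
        {v for row in table["variants"] for v in row} - set(variant_types)
    )
    if missing:
        raise ConsistencyError(
            f"variant(s) without annotation: {', '.join(missing)}"
        )
    rows = []
    for row in table.itertuples(index=False):
        if active_variants is not None:
            active = [v for v in row.variants if v in active_variants]
        else:
            active = list(row.active_variants)
        by_type = {"i": 0, "m": 0, "s": 0}
        for v in active:
            by_type[variant_types[v]] += 1
        rows.append(
            {
                "accession_id": row.accession_id,
                "genotype": row.genotype,
                "n_active": len(active),
                "n_active_i": by_type["i"],
                "n_active_m": by_type["m"],
                "n_active_s": by_type["s"],
                "three_active_i": by_type["i"] == 3,
            }
        )
    census = pd.DataFrame(rows)
    summary = {
        "n_accessions": len(census),
        "n_three_active_i": int(census["three_active_i"].sum()),
        "pct_three_active_i": percent(
            int(census["three_active_i"].sum()), len(census)
        ),
    }
    return census, summary


def regional_summary(
    table: pd.DataFrame,
    variant_to_gene: dict[str, str],
    regions: tuple[str, ...] | None = None,
) -> pd.DataFrame:
    """Richness and uniqueness of genes/variants/genotypes per region.

    Uniqueness means present in exactly one region (checked against all
    other regions).  Regions are ranked by variant richness, then genotype
    richness; the table is returned in rank order.
    """
    validate_genotype_table(table, regions)
    missing = sorted(
        {v for row in table["variants"] for v in row} - set(variant_to_gene)
    )
    if missing:
        raise ConsistencyError(
            f"variant(s) not in the catalog: {', '.join(missing)}"
        )
    per_region: dict[str, dict[str, set]] = {}
    for row in table.itertuples(index=False):
        slot = per_region.setdefault(
            row.region,
            {"accessions": set(), "genes": set(), "variants": set(),
             "genotypes": set()},
        )
        slot["accessions"].add(row.accession_id)
        slot["genotypes"].add(row.genotype)
        for v in row.variants:
            slot["variants"].add(v)
            slot["genes"].add(variant_to_gene[v])
    rows = []
    for region, slot in per_region.items():
        others_variants = set().union(
            *(s["variants"] for r, s in per_region.items() if r != region)
        ) if len(per_region) > 1 else set()
        others_genotypes = set().union(
            *(s["genotypes"] for r, s in per_region.items() if r != region)
        ) if len(per_region) > 1 else set()
        unique_variants = slot["variants"] - others_variants
        unique_genotypes = slot["genotypes"] - others_genotypes
        rows.append(
            {
                "region": region,
                "n_accessions": len(slot["accessions"]),
                "n_genes": len(slot["genes"]),
                "n_variants": len(slot["variants"]),
                "n_genotypes": len(slot["genotypes"]),
                "n_unique_variants": len(unique_variants),
                "n_unique_genotypes": len(unique_genotypes),
                "unique_variants": ";".join(sorted(unique_variants)),
                "unique_genotypes": ";".join(sorted(unique_genotypes)),
            }
        )
    return (
        pd.DataFrame(rows)
        .sort_values(
            ["n_variants", "n_genotypes", "region"],
            ascending=[False, False, True],
        )
        .reset_index(drop=True)
    )
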