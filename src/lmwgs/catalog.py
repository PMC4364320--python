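"""Clustering of cloned sequences into genes and named allelic variants.

Members of the LMW-GS family are assigned to genes by overall sequence
identity: copies that are highly similar but differ in the length of the
repetitive domain are the same gene, while distinct sequences inside one
gene (conserved SNPs and/or repeat-length indels) are its allelic variants.
Clustering is single-linkage on global nucleotide identity so that ladders
of repeat-length variants chain into one gene; the membership threshold
``t_gene`` (default 0.95) sits between observed within-gene identities
(>0.99) and cross-gene homologies (<=0.90-0.94).

Naming follows the marker-system convention: a gene is represented by its
most frequent variant and named ``<prefix><LMWGS1 size of representative>``;
variants are named ``<prefix><size>``, with letters a, b, c ... appended in
descending accession-frequency order when several variants share a fragment
size.  Ties are broken by smaller fragment size, then lexicographic
sequence id, so names are a pure function of the input.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd
from Bio.Align import PairwiseAligner

from .errors import ConsistencyError, InputError
from .util import percent

#: Default global-alignment scoring: match +2, mismatch -3, and affine gap
#: cost 7 + k for a gap of length k (favours single long motif-multiple
#: indels over scattered gaps).
DEFAULT_SCORING = {"match": 2, "mismatch": -3, "gap_open": -7, "gap_extend": -1}

#: Default gene-membership identity threshold.
T_GENE = 0.95


def make_aligner(
    match: int = 2,
    mismatch: int = -3,
    gap_open: int = -7,
    gap_extend: int = -1,
) -> PairwiseAligner:
    """End-to-end global aligner with affine gaps.

    ``gap_open`` is the gap-opening surcharge: a gap of length k costs
    ``-(gap_open + k * gap_extend)`` in total.
    """
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap_open + gap_extend
    aligner.extend_gap_score = gap_extend
    return aligner


def _alignment_counts(alignment) -> tuple[int, int]:
    """(matches, columns) of a pairwise alignment, gap columns included."""
    a, b = alignment.sequences
    matches = 0
    compared = 0
    for (a0, a1), (b0, b1) in zip(*alignment.aligned):
        seg_a, seg_b = a[a0:a1], b[b0:b1]
        matches += sum(x == y for x, y in zip(seg_a, seg_b))
        compared += a1 - a0
    return matches, alignment.length


def global_identity(
    seq_a: str, seq_b: str, aligner: PairwiseAligner | None = None
):
    """Global (end-to-end) alignment and identity fraction of two sequences.

    Identity is matches / alignment columns with gap columns counted in the
    denominator, hence symmetric and length-aware.  Returns
    ``(alignment, identity)``.
    """
    if not seq_a or not seq_b:
        raise InputError("cannot align an empty sequence")
    if aligner is None:
        aligner = make_aligner()
    alignment = aligner.align(seq_a.upper(), seq_b.upper())[0]
    matches, columns = _alignment_counts(alignment)
    return alignment, matches / columns


# --------------------------------------------------------------------------
# catalog model


@dataclass
class Variant:
    name: str
    sequence_ids: tuple[str, ...]
    dna: str
    lmwgs1_size: int
    accession_count: int


@dataclass
class Gene:
    name: str
    representative: str                   # variant name
    variants: list[Variant] = field(default_factory=list)


@dataclass
class VariantCatalog:
    genes: list[Gene] = field(default_factory=list)
    naming_prefix: str = "TuA3-"

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_variants(self) -> int:
        return sum(len(g.variants) for g in self.genes)

    def variant_to_gene(self) -> dict[str, str]:
        return {v.name: g.name for g in self.genes for v in g.variants}

    def variant_names(self) -> list[str]:
        return [v.name for g in self.genes for v in g.variants]

    def variants(self) -> list[Variant]:
        return [v for g in self.genes for v in g.variants]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for gene in self.genes:
            for v in gene.variants:
                rows.append(
                    {
                        "gene": gene.name,
                        "variant": v.name,
                        "representative": v.name == gene.representative,
                        "lmwgs1_size": v.lmwgs1_size,
                        "accession_count": v.accession_count,
                        "sequence_ids": ";".join(v.sequence_ids),
                    }
                )
        return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# clustering


@dataclass(frozen=True)
class SequenceEntry:
    """One input sequence for clustering: id, DNA, accession support, size."""

    sequence_id: str
    dna: str
    accession_count: int
    lmwgs1_size: int


def _single_linkage(n: int, edges: list[tuple[int, int]]) -> list[list[int]]:
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, j in edges:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[max(ri, rj)] = min(ri, rj)
    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    return [groups[k] for k in sorted(groups)]


def cluster_variants(
    entries: list[SequenceEntry],
    t_gene: float = T_GENE,
    prefix: str = "TuA3-",
    aligner: PairwiseAligner | None = None,
) -> VariantCatalog:
    """Cluster sequences into genes and named allelic variants.

    Exact-duplicate sequences are merged (support summed) before
    single-linkage clustering at identity >= ``t_gene``.  The result is
    deterministic and invariant to input order.
    """
    if not entries:
        raise InputError("no sequences to cluster")
    if aligner is None:
        aligner = make_aligner()
    # merge identical sequences into candidate variants
    by_dna: dict[str, list[SequenceEntry]] = {}
    for e in entries:
        by_dna.setdefault(e.dna.upper(), []).append(e)
    variants: list[dict] = []
    for dna in sorted(by_dna):
        group = by_dna[dna]
        sizes = {e.lmwgs1_size for e in group}
        if len(sizes) > 1:
            raise ConsistencyError(
                "identical sequences reported with different LMWGS1 sizes"
            )
        variants.append(
            {
                "dna": dna,
                "sequence_ids": tuple(sorted(e.sequence_id for e in group)),
                "count": sum(e.accession_count for e in group),
                "size": group[0].lmwgs1_size,
            }
        )
    variants.sort(key=lambda v: v["sequence_ids"][0])
    n = len(variants)
    edges = []
    for i in range(n):
        for j in range(i + 1, n):
            _, ident = global_identity(
                variants[i]["dna"], variants[j]["dna"], aligner
            )
            if ident >= t_gene:
                edges.append((i, j))
    clusters = _single_linkage(n, edges)

    genes: list[Gene] = []
    for members in clusters:
        cluster = [variants[i] for i in members]
        rep = min(
            cluster,
            key=lambda v: (-v["count"], v["size"], v["sequence_ids"][0]),
        )
        gene_name = f"{prefix}{rep['size']}"
        # letter suffixes within each shared fragment size
        by_size: dict[int, list[dict]] = {}
        for v in cluster:
            by_size.setdefault(v["size"], []).append(v)
        named: list[Variant] = []
        rep_name = None
        for size in sorted(by_size):
            group = sorted(
                by_size[size],
                key=lambda v: (-v["count"], v["sequence_ids"][0]),
            )
            for k, v in enumerate(group):
                suffix = chr(ord("a") + k) if len(group) > 1 else ""
                name = f"{prefix}{size}{suffix}"
                named.append(
                    Variant(
                        name=name,
                        sequence_ids=v["sequence_ids"],
                        dna=v["dna"],
                        lmwgs1_size=v["size"],
                        accession_count=v["count"],
                    )
                )
                if v is rep:
                    rep_name = name
        named.sort(key=lambda v: (v.lmwgs1_size, v.name))
        genes.append(Gene(name=gene_name, representative=rep_name, variants=named))
    genes.sort(key=lambda g: (int(g.name[len(prefix):] or 0), g.name))
    # disambiguate rare cross-cluster name collisions deterministically
    seen: dict[str, int] = {}
    for gene in genes:
        if gene.name in seen:
            seen[gene.name] += 1
            gene.name = f"{gene.name}.{seen[gene.name]}"
        else:
            seen[gene.name] = 1
    return VariantCatalog(genes=genes, naming_prefix=prefix)


# --------------------------------------------------------------------------
# population-level summaries over a genotype table


def _variant_support(genotype_table: pd.DataFrame) -> dict[str, set[str]]:
    """variant id -> set of accession ids carrying it."""
    support: dict[str, set[str]] = {}
    for row in genotype_table.itertuples(index=False):
        for vid in row.variants:
            support.setdefault(vid, set()).add(row.accession_id)
    return support


def variant_frequencies(
    catalog: VariantCatalog, genotype_table: pd.DataFrame
) -> pd.DataFrame:
    """Accession counts and percentages for every catalog variant.

    ``genotype_table`` needs columns ``accession_id`` and ``variants``
    (iterable of variant names).  A genotype referencing a variant absent
    from the catalog is a consistency error.
    """
    known = set(catalog.variant_names())
    support = _variant_support(genotype_table)
    orphans = sorted(set(support) - known)
    if orphans:
        raise ConsistencyError(
            f"genotype table references variants missing from the catalog: "
            f"{', '.join(orphans)}"
        )
    total = genotype_table["accession_id"].nunique()
    v2g = catalog.variant_to_gene()
    rows = [
        {
            "variant": name,
            "gene": v2g[name],
            "accession_count": len(support.get(name, ())),
            "accession_pct": percent(len(support.get(name, ())), total),
        }
        for name in sorted(known)
    ]
    return (
        pd.DataFrame(rows)
        .sort_values(["gene", "variant"])
        .reset_index(drop=True)
    )


def haplotype_cosegregation(genotype_table: pd.DataFrame) -> pd.DataFrame:
    """Groups of variants supported by exactly the same accessions.

    Variants whose supporting accession sets are identical co-segregate and
    may form a haplotype; groups of two or more are reported with their
    support count, largest first.
    """
    support = _variant_support(genotype_table)
    by_support: dict[frozenset, list[str]] = {}
    for vid, accs in support.items():
        by_support.setdefault(frozenset(accs), []).append(vid)
    rows = [
        {
            "variants": ";".join(sorted(vids)),
            "n_variants": len(vids),
            "support": len(accs),
        }
        for accs, vids in by_support.items()
        if len(vids) >= 2
    ]
    return (
        pd.DataFrame(rows, columns=["variants", "n_variants", "support"])
        .sort_values(["support", "variants"], ascending=[False, True])
        .reset_index(drop=True)
    )
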