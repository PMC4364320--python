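"""Packaged reference panel: the published Glu-A3 LMW-GS inventory.

A published survey of the LMW-GS gene family at the Glu-A3 locus of a
157-accession *Triticum urartu* panel from the Fertile Crescent found eight
genes (four m-type, one s-type, three i-type) carrying 39 allelic variants,
organised into 15 multilocus genotypes (U1-U15) distributed over six
collection regions.  This module encodes that inventory as data - genotype
definitions (variant multisets), per-region accession counts, active/pseudo
flags with the domain of each premature stop, and nominal LMWGS1 fragment
sizes - and pairs it with synthetic gene templates so the whole panel can
be materialised as concrete sequences and pushed through every downstream
stage.

The synthetic sequences emulate the family's architecture (conserved primer
anchors, a 24-bp repeat-unit ladder for fragment-length polymorphism,
silent tag substitutions distinguishing same-size variants, premature stops
in the documented domains).  Fragment sizes of the emitted sequences are
exact theoretical sizes of the synthetic amplicons; the published sizes are
carried as nominal labels (capillary-electrophoresis estimates differing by
1-2 bp cannot be expressed as in-frame coding indels).  All published
population-level arithmetic - genotype counts, variant frequencies, the
active-gene census, regional richness - is reproduced exactly because it
depends only on the combinatorial structure, which is preserved.
"""

from __future__ import annotations

from dataclasses import replace
from functools import lru_cache

import numpy as np
import pandas as pd

from . import annotate as _ann
from .catalog import Gene, Variant, VariantCatalog
from .errors import ValidationError
from .marker import PrimerSet
from .simulate import (
    CODON,
    SYNONYMOUS_ALT,
    GeneTemplate,
    MutationSpec,
    Population,
    PopulationConfig,
    gene_truth,
    make_population,
    measure_amplicons,
    primer_sets_from_sites,
    refresh_orf_truth,
    standard_primer_sites,
)

NAMING_PREFIX = "TuA3-"

#: The six collection regions of the panel (fixed vocabulary).
REGIONS = (
    "Iraq",
    "Iran",
    "Armenia",
    "Northeastern Lebanon",
    "Syria",
    "Southeastern Turkey",
)

#: The eight genes, in marker-table column order, with subunit types.
GENE_TYPES = {
    "TuA3-385": "m",
    "TuA3-391": "m",
    "TuA3-397": "m",
    "TuA3-400": "m",
    "TuA3-460": "s",
    "TuA3-502": "i",
    "TuA3-576": "i",
    "TuA3-538": "i",
}
GENE_ORDER = tuple(GENE_TYPES)

#: Allelic variants of each gene, in published-name order; letters rank
#: same-size variants by descending accession frequency.
GENE_VARIANTS = {
    "TuA3-385": ("TuA3-385a", "TuA3-385b"),
    "TuA3-391": ("TuA3-373", "TuA3-391", "TuA3-392"),
    "TuA3-397": ("TuA3-397a", "TuA3-397b"),
    "TuA3-400": ("TuA3-400", "TuA3-402"),
    "TuA3-460": ("TuA3-460", "TuA3-463", "TuA3-474"),
    "TuA3-502": (
        "TuA3-495", "TuA3-498", "TuA3-502a", "TuA3-502b", "TuA3-502c",
        "TuA3-502d", "TuA3-520", "TuA3-590", "TuA3-593",
    ),
    "TuA3-576": (
        "TuA3-406", "TuA3-555", "TuA3-576a", "TuA3-576b", "TuA3-576c",
        "TuA3-576d", "TuA3-576e", "TuA3-579a", "TuA3-579b", "TuA3-597",
        "TuA3-669",
    ),
    "TuA3-538": (
        "TuA3-535", "TuA3-538a", "TuA3-538b", "TuA3-538c", "TuA3-538d",
        "TuA3-538e", "TuA3-657",
    ),
}

VARIANT_GENE = {
    vid: gene for gene, vids in GENE_VARIANTS.items() for vid in vids
}

#: Nominal LMWGS1 fragment size (bp) each variant is named after.
NOMINAL_SIZE = {
    vid: int("".join(c for c in vid[len(NAMING_PREFIX):] if c.isdigit()))
    for vid in VARIANT_GENE
}

#: Variants with intact ORFs whose protein products were detected; the
#: remaining 18 variants are pseudo-genes.
ACTIVE_VARIANTS = frozenset(
    {
        "TuA3-397b", "TuA3-400",
        "TuA3-498", "TuA3-502a", "TuA3-502c", "TuA3-520",
        "TuA3-555", "TuA3-576a", "TuA3-576b", "TuA3-576c", "TuA3-576e",
        "TuA3-579a", "TuA3-579b", "TuA3-597", "TuA3-669",
        "TuA3-535", "TuA3-538a", "TuA3-538b", "TuA3-538c", "TuA3-538e",
        "TuA3-657",
    }
)

#: Premature-stop placement for each pseudo-gene variant, as a list of
#: (domain, residue offset within the domain); the s-type gene's variants
#: carry stops in both the repetitive and C-terminal I domains.
_STOP_REP = (_ann.DOMAIN_REPETITIVE, 10)
_STOP_C1 = (_ann.DOMAIN_CTERM1, 20)
_STOP_C2 = (_ann.DOMAIN_CTERM2, 20)
STOP_SPECS = {
    "TuA3-385a": (_STOP_REP,),
    "TuA3-385b": (_STOP_REP,),
    "TuA3-373": (_STOP_REP,),
    "TuA3-391": (_STOP_C1,),
    "TuA3-392": (_STOP_REP,),
    "TuA3-397a": (_STOP_REP,),
    "TuA3-402": (_STOP_C2,),
    "TuA3-460": (_STOP_REP, _STOP_C1),
    "TuA3-463": (_STOP_REP, _STOP_C1),
    "TuA3-474": (_STOP_REP, _STOP_C1),
    "TuA3-495": (_STOP_REP,),
    "TuA3-502b": (_STOP_REP,),
    "TuA3-502d": (_STOP_REP,),
    "TuA3-590": (_STOP_REP,),
    "TuA3-593": (_STOP_REP,),
    "TuA3-406": (_STOP_REP,),
    "TuA3-576d": (_STOP_C2,),
    "TuA3-538d": (_STOP_REP,),
}

#: Repeat-unit count of each variant's repetitive domain (the 24-bp
#: ladder); same-size variants share a rung and differ by silent tags.
VARIANT_REPEATS = {
    "TuA3-385a": 11, "TuA3-385b": 11,
    "TuA3-373": 7, "TuA3-391": 8, "TuA3-392": 9,
    "TuA3-397a": 12, "TuA3-397b": 12,
    "TuA3-400": 14, "TuA3-402": 15,
    "TuA3-460": 18, "TuA3-463": 19, "TuA3-474": 20,
    "TuA3-495": 16, "TuA3-498": 17,
    "TuA3-502a": 18, "TuA3-502b": 18, "TuA3-502c": 18, "TuA3-502d": 18,
    "TuA3-520": 19, "TuA3-590": 20, "TuA3-593": 21,
    "TuA3-406": 26, "TuA3-555": 27,
    "TuA3-576a": 28, "TuA3-576b": 28, "TuA3-576c": 28, "TuA3-576d": 28,
    "TuA3-576e": 28,
    "TuA3-579a": 29, "TuA3-579b": 29, "TuA3-597": 30, "TuA3-669": 31,
    "TuA3-535": 23,
    "TuA3-538a": 24, "TuA3-538b": 24, "TuA3-538c": 24, "TuA3-538d": 24,
    "TuA3-538e": 24,
    "TuA3-657": 25,
}

#: The 15 multilocus genotypes as variant multisets, in gene-column order.
GENOTYPE_DEFS = {
    "U1": ("TuA3-385a", "TuA3-373", "TuA3-397a",
           "TuA3-502c", "TuA3-576d", "TuA3-538a"),
    "U2": ("TuA3-385b", "TuA3-391", "TuA3-397a",
           "TuA3-502b", "TuA3-406", "TuA3-538c"),
    "U3": ("TuA3-385a", "TuA3-391", "TuA3-397a",
           "TuA3-498", "TuA3-597", "TuA3-535"),
    "U4": ("TuA3-385b", "TuA3-392", "TuA3-397a",
           "TuA3-520", "TuA3-576c", "TuA3-538d"),
    "U5": ("TuA3-385a", "TuA3-392", "TuA3-397a",
           "TuA3-502c", "TuA3-576b", "TuA3-538b"),
    "U6": ("TuA3-385a", "TuA3-392", "TuA3-397a",
           "TuA3-502a", "TuA3-576a", "TuA3-538a"),
    "U7": ("TuA3-385a", "TuA3-392", "TuA3-397a",
           "TuA3-502d", "TuA3-555", "TuA3-538a"),
    "U8": ("TuA3-385a", "TuA3-392", "TuA3-397b",
           "TuA3-502a", "TuA3-579b", "TuA3-538b"),
    "U9": ("TuA3-385a", "TuA3-392", "TuA3-397a",
           "TuA3-593", "TuA3-576b", "TuA3-538e"),
    "U10": ("TuA3-385a", "TuA3-373", "TuA3-397a", "TuA3-460",
            "TuA3-502a", "TuA3-579a", "TuA3-538b"),
    "U11": ("TuA3-385a", "TuA3-373", "TuA3-397a", "TuA3-463",
            "TuA3-520", "TuA3-576c", "TuA3-538a"),
    "U12": ("TuA3-385b", "TuA3-373", "TuA3-397a", "TuA3-463",
            "TuA3-495", "TuA3-669", "TuA3-657"),
    "U13": ("TuA3-385a", "TuA3-392", "TuA3-397a", "TuA3-474",
            "TuA3-502c", "TuA3-576d", "TuA3-538d"),
    "U14": ("TuA3-385a", "TuA3-392", "TuA3-397a", "TuA3-402",
            "TuA3-520", "TuA3-576c", "TuA3-538a"),
    "U15": ("TuA3-392", "TuA3-397b", "TuA3-400",
            "TuA3-590", "TuA3-576e", "TuA3-538a"),
}

#: Accessions collected per genotype and region (sums to 157).
REGION_COUNTS = {
    "U1": {"Southeastern Turkey": 1},
    "U2": {"Iraq": 1, "Iran": 1, "Northeastern Lebanon": 9,
           "Syria": 1, "Southeastern Turkey": 23},
    "U3": {"Southeastern Turkey": 5},
    "U4": {"Southeastern Turkey": 7},
    "U5": {"Southeastern Turkey": 9},
    "U6": {"Northeastern Lebanon": 36, "Syria": 2, "Southeastern Turkey": 1},
    "U7": {"Northeastern Lebanon": 1, "Southeastern Turkey": 1},
    "U8": {"Northeastern Lebanon": 15, "Syria": 1},
    "U9": {"Northeastern Lebanon": 1, "Syria": 1, "Southeastern Turkey": 4},
    "U10": {"Armenia": 1, "Northeastern Lebanon": 19, "Southeastern Turkey": 1},
    "U11": {"Southeastern Turkey": 2},
    "U12": {"Southeastern Turkey": 1},
    "U13": {"Northeastern Lebanon": 1, "Southeastern Turkey": 3},
    "U14": {"Southeastern Turkey": 5},
    "U15": {"Armenia": 4},
}

#: Accessions of the panel referred to by name.
NAMED_ACCESSIONS = {
    "PI428198": ("U14", "Southeastern Turkey"),
    "PI428202": ("U2", "Northeastern Lebanon"),
    "PI428255": ("U9", "Southeastern Turkey"),
    "PI428270": ("U10", "Northeastern Lebanon"),
    "PI428335": ("U8", "Northeastern Lebanon"),
}

POPULATION_SIZE = 157

# --------------------------------------------------------------------------
# synthetic gene templates
#
# One 20-residue signal peptide shared by all genes (its first and last
# codons carry the conserved forward primer anchors), per-gene N-terminal
# domains and repeat units, and per-gene C-terminal domains derived from a
# common archetype by seeded substitution so that within-type paralogs sit
# around 85-90% nucleotide identity and types are further apart - below the
# 0.95 gene-membership threshold, above what would scramble the i vs m/s
# phylogenetic split.

SIGNAL_PEPTIDE = "MKTFLVFALLAVAATSAIAQ"

_N_TERMINAL = {
    "TuA3-385": "METSHIPGLERPS",
    "TuA3-391": "METSRIPGLQRPS",
    "TuA3-397": "METSHIPSLEKPS",
    "TuA3-400": "METSHIPSLEKPA",
    "TuA3-460": "MENSHIPGLEKPS",  # s-type diagnostic N-terminus
    "TuA3-502": "",
    "TuA3-576": "",
    "TuA3-538": "",
}

#: i-type repetitive-domain heads (mature protein starts with Ile).
_REPEAT_HEAD = {
    "TuA3-502": "ISQQQQ",
    "TuA3-576": "ISQPQQ",
    "TuA3-538": "ISQTQQ",
}

#: 8-residue (24-bp) repeat units; all start QQPP so the repetitive domain
#: is recognisable, suffixes diverge between genes.  The s-type unit
#: carries the type-specific TLSH peptide.
_REPEAT_UNIT = {
    "TuA3-385": "QQPPFPQQ",
    "TuA3-391": "QQPPSFSQ",
    "TuA3-397": "QQPPLSFQ",
    "TuA3-400": "QQPPLVSQ",
    "TuA3-460": "QQPPTLSH",
    "TuA3-502": "QQPPFSQQ",
    "TuA3-576": "QQPPILQH",
    "TuA3-538": "QQPPVLQQ",
}

# C-terminal archetypes: 72 residues with cysteines at 0/14/28/40/52/71,
# 45 residues with the cysteine last, 38 residues with the cysteine at 10.
_CT1_BASE = (
    "C" "QQLQQSSQQLAQQ"
    "C" "QAIHSVVHSIIMQ"
    "C" "QQLAQIPQQLQ"
    "C" "AAIHSVAHSIA"
    "C" "SQVSQQQLGQQPQHLSVP"
    "C"
)
_CT2_BASE = "VLQQSTY" "EQQVLQPQQQVFGTPMLSVHQQLFQQQPVVSGQAQLA" "C"
_CT3_BASE = "TSVPFGVGTG" "C" "GVSTVHGLLGSHQPAQ" "SGQGYLPHESI"

#: Positions never touched by divergence: cysteines and primer anchors
#: (cterm1 tail = LMWGS3 reverse, cterm2 head = LMWGS1 reverse, cterm3
#: tail = LMWGS2 reverse).
_CT1_PROTECTED = {i for i, c in enumerate(_CT1_BASE) if c == "C"} | set(
    range(len(_CT1_BASE) - 7, len(_CT1_BASE))
)
_CT2_PROTECTED = set(range(7)) | {len(_CT2_BASE) - 1}
_CT3_PROTECTED = {10} | set(range(len(_CT3_BASE) - 7, len(_CT3_BASE)))

_SUBSTITUTION_ALPHABET = "QSLVIPFATGHE"

_TYPE_SEEDS = {"i": 11, "m": 12, "s": 13}
_GENE_SEEDS = {gene: 101 + k for k, gene in enumerate(GENE_ORDER)}


def _diverge(seq: str, protected: set[int], rate: float, seed: int) -> str:
    rng = np.random.default_rng(seed)
    out = list(seq)
    for i in range(len(out)):
        if i in protected:
            continue
        if rng.random() < rate:
            choices = [c for c in _SUBSTITUTION_ALPHABET if c != out[i]]
            out[i] = choices[int(rng.integers(len(choices)))]
    return "".join(out)


def _cterms_for(gene: str) -> tuple[str, str, str]:
    subunit_type = GENE_TYPES[gene]
    parts = []
    for base, protected in (
        (_CT1_BASE, _CT1_PROTECTED),
        (_CT2_BASE, _CT2_PROTECTED),
        (_CT3_BASE, _CT3_PROTECTED),
    ):
        if subunit_type == "s":  # s-types derive from the m-type base
            type_base = _diverge(base, protected, 0.18, _TYPE_SEEDS["m"])
            type_base = _diverge(type_base, protected, 0.06, _TYPE_SEEDS["s"])
        else:
            type_base = _diverge(base, protected, 0.18, _TYPE_SEEDS[subunit_type])
        parts.append(_diverge(type_base, protected, 0.10, _GENE_SEEDS[gene]))
    return tuple(parts)


@lru_cache(maxsize=1)
def reference_templates() -> dict[str, GeneTemplate]:
    """The eight gene templates of the reference panel."""
    templates = {}
    for gene in GENE_ORDER:
        subunit_type = GENE_TYPES[gene]
        ct1, ct2, ct3 = _cterms_for(gene)
        if subunit_type == "i":
            motifs = (_REPEAT_HEAD[gene], _REPEAT_UNIT[gene])
        else:
            motifs = (_REPEAT_UNIT[gene],)
        template = GeneTemplate(
            gene_id=gene,
            subunit_type=subunit_type,
            signal_peptide=SIGNAL_PEPTIDE,
            n_terminal=_N_TERMINAL[gene],
            repeat_motifs=motifs,
            repeat_count=min(
                VARIANT_REPEATS[v] for v in GENE_VARIANTS[gene]
            ),
            cterm1=ct1,
            cterm2=ct2,
            cterm3=ct3,
        )
        template = replace(
            template, primer_sites=standard_primer_sites(template)
        )
        template.validate()
        templates[gene] = template
    return templates


@lru_cache(maxsize=1)
def reference_primer_sets() -> list[PrimerSet]:
    """The three conserved primer sets (anchors shared by all templates)."""
    template = reference_templates()[GENE_ORDER[0]]
    return primer_sets_from_sites(template.primer_sites)


# --------------------------------------------------------------------------
# variant sequences

#: cterm1 codon offsets usable for silent variant tags (no cysteines, no
#: anchor tail, no archetype methionine at 26).
_TAG_OFFSETS = (
    2, 4, 6, 8, 10, 12, 16, 18, 20, 22, 24, 30, 32, 34, 36, 38,
    42, 44, 46, 48, 50, 54, 56,
)


def _apply_codon_edit(dna: str, codon_index: int, new_codon: str) -> str:
    i = 3 * codon_index
    return dna[:i] + new_codon + dna[i + 3 :]


def _protein_spans(template: GeneTemplate) -> dict[str, tuple[int, int]]:
    """Domain spans in precursor-protein (codon) coordinates."""
    mature = template.domain_map()
    off = template.mature_start
    return {name: (lo + off, hi + off) for name, (lo, hi) in mature.items()}


@lru_cache(maxsize=1)
def reference_variants() -> dict[str, tuple[str, "object"]]:
    """DNA and truth row for each of the 39 variants.

    Same-size variants differ by silent third-position tags in the
    C-terminal I domain; pseudo-gene variants carry TAA stops at the
    documented domains.  Theoretical amplicon sizes are recomputed from the
    final sequences and checked to be collision-free across the panel.
    """
    templates = reference_templates()
    primer_sets = reference_primer_sets()
    out = {}
    for gene in GENE_ORDER:
        template = templates[gene]
        for j, vid in enumerate(GENE_VARIANTS[gene]):
            t_v = replace(template, repeat_count=VARIANT_REPEATS[vid])
            dna = t_v.encode()
            spans = _protein_spans(t_v)
            # silent tags: two synonymous substitutions unique per variant
            if j > 0:
                ct1_start = spans[_ann.DOMAIN_CTERM1][0]
                for off in _TAG_OFFSETS[2 * (j - 1) : 2 * (j - 1) + 2]:
                    aa = t_v.cterm1[off]
                    dna = _apply_codon_edit(
                        dna, ct1_start + off, SYNONYMOUS_ALT[aa]
                    )
            for domain, off in STOP_SPECS.get(vid, ()):
                lo, hi = spans[domain]
                if lo + off >= hi:
                    raise ValidationError(
                        f"{vid}: stop offset outside {domain}"
                    )
                dna = _apply_codon_edit(dna, lo + off, "TAA")
            truth = gene_truth(
                t_v, sequence_id=vid, variant_id=vid
            )
            refresh_orf_truth(dna, truth)
            truth.amplicons = measure_amplicons(dna, primer_sets)
            expected = "pseudo" if vid in STOP_SPECS else "active"
            if truth.orf_status != expected:
                raise ValidationError(f"{vid}: ORF status {truth.orf_status}")
            out[vid] = (dna, truth)
    _check_size_ladder(out)
    return out


def _check_size_ladder(variants) -> None:
    """Theoretical sizes must separate exactly the nominal size classes."""
    for set_name in ("LMWGS1", "LMWGS2", "LMWGS3"):
        by_nominal: dict[int, set] = {}
        for vid, (_, truth) in variants.items():
            size = truth.amplicons[set_name]
            if not isinstance(size, int):
                raise ValidationError(f"{vid}: {set_name} failed to amplify")
            by_nominal.setdefault(NOMINAL_SIZE[vid], set()).add(size)
        sizes = []
        for nominal, got in by_nominal.items():
            if len(got) != 1:
                raise ValidationError(
                    f"nominal size {nominal} maps to several {set_name} sizes"
                )
            sizes.append(got.pop())
        if len(sizes) != len(set(sizes)):
            raise ValidationError(f"{set_name} size collision across variants")


def variant_sequences() -> dict[str, str]:
    """Variant id -> DNA for the 39 reference variants."""
    return {vid: dna for vid, (dna, _) in reference_variants().items()}


# --------------------------------------------------------------------------
# whole-panel assembly


def reference_population_config() -> PopulationConfig:
    variants = reference_variants()
    return PopulationConfig(
        genotype_defs=dict(GENOTYPE_DEFS),
        region_counts={g: dict(c) for g, c in REGION_COUNTS.items()},
        variant_dna={vid: dna for vid, (dna, _) in variants.items()},
        variant_truth={vid: truth for vid, (_, truth) in variants.items()},
        primer_sets=reference_primer_sets(),
        named_accessions=dict(NAMED_ACCESSIONS),
        accession_prefix="TU",
        region_order=REGIONS,
    )


@lru_cache(maxsize=4)
def reference_population(seed: int = 0) -> Population:
    """Materialise the 157-accession panel (zero mutation: exact truth)."""
    return make_population(
        reference_population_config(), MutationSpec(seed=seed)
    )


def _accession_layout() -> list[tuple[str, str, str]]:
    """(accession_id, region, genotype) in deterministic panel order."""
    rows = []
    named: dict[tuple[str, str], list[str]] = {}
    for acc, slot in sorted(NAMED_ACCESSIONS.items()):
        named.setdefault(slot, []).append(acc)
    serial = 0
    for genotype in sorted(GENOTYPE_DEFS, key=lambda g: int(g[1:])):
        for region in REGIONS:
            pending = list(named.get((genotype, region), []))
            for _ in range(REGION_COUNTS[genotype].get(region, 0)):
                if pending:
                    acc = pending.pop(0)
                else:
                    serial += 1
                    acc = f"TU{serial:04d}"
                rows.append((acc, region, genotype))
    return rows


def reference_genotype_table() -> pd.DataFrame:
    """The published genotype table: one row per accession.

    Columns: accession_id, region, genotype, variants (tuple of variant
    names), active_variants (tuple).  This is the packaged inventory; the
    pipeline recomputes its own version of it from sequences.
    """
    rows = []
    for acc, region, genotype in _accession_layout():
        variants = GENOTYPE_DEFS[genotype]
        rows.append(
            {
                "accession_id": acc,
                "region": region,
                "genotype": genotype,
                "variants": variants,
                "active_variants": tuple(
                    v for v in variants if v in ACTIVE_VARIANTS
                ),
            }
        )
    return pd.DataFrame(rows)


def reference_catalog_skeleton() -> VariantCatalog:
    """Catalog of the 39 published variants (published names and flags)."""
    table = reference_genotype_table()
    support: dict[str, int] = {vid: 0 for vid in VARIANT_GENE}
    for row in table.itertuples(index=False):
        for vid in row.variants:
            support[vid] += 1
    genes = []
    for gene in GENE_ORDER:
        variants = [
            Variant(
                name=vid,
                sequence_ids=(vid,),
                dna="",
                lmwgs1_size=NOMINAL_SIZE[vid],
                accession_count=support[vid],
            )
            for vid in GENE_VARIANTS[gene]
        ]
        rep = max(variants, key=lambda v: (v.accession_count, -v.lmwgs1_size))
        genes.append(
            Gene(name=gene, representative=rep.name, variants=variants)
        )
    return VariantCatalog(genes=genes, naming_prefix=NAMING_PREFIX)


def reference_fixture():
    """(catalog skeleton, genotype table, per-genotype region counts)."""
    return (
        reference_catalog_skeleton(),
        reference_genotype_table(),
        {g: dict(c) for g, c in REGION_COUNTS.items()},
    )
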