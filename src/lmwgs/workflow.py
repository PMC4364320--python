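"""Configuration, I/O and the end-to-end pipeline runner.

The pipeline chains the analysis stages in the order the method runs:

    simulate -> annotate -> genotype (marker) -> cluster (catalog)
             -> diversity -> phylo -> report

Everything is driven by one structured YAML config (seed, mutation rates,
clustering threshold, primer definitions, output paths) so a run is fully
reproducible; with a fixed seed the emitted tables are byte-identical
between runs.  Outputs are plain text: wrapped FASTA per accession,
UTF-8 TSV tables with headers, Newick for trees, JSON for the summary
report.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import reference
from .annotate import annotate_gene, localize_stop
from .catalog import (
    SequenceEntry,
    cluster_variants,
    haplotype_cosegregation,
    variant_frequencies,
)
from .diversity import active_gene_census, genotype_summary, regional_summary
from .errors import ConfigError, InputError
from .marker import (
    PrimerSet,
    build_profile,
    call_genotypes,
    profiles_to_frame,
    triplets_to_frame,
    virtual_amplicon,
)
from .phylo import check_monophyly, neighbor_joining, pdistance_matrix
from .simulate import MutationSpec, Population, PopulationConfig, make_population

log = logging.getLogger("lmwgs")

_FASTA_ALPHABET = set("ACGTRYSWKMBDHVN")


# --------------------------------------------------------------------------
# readers / writers


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file (wrapped or not, IUPAC codes) into id -> sequence.

    Malformed records are rejected with the offending line number.
    """
    records: dict[str, list[str]] = {}
    current: str | None = None
    with open(path, encoding="utf-8") as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                current = line[1:].split()[0]
                if not current:
                    raise InputError(f"{path}:{lineno}: empty FASTA header")
                if current in records:
                    raise InputError(
                        f"{path}:{lineno}: duplicate record {current!r}"
                    )
                records[current] = []
            else:
                if current is None:
                    raise InputError(
                        f"{path}:{lineno}: sequence data before first header"
                    )
                bad = set(line.upper()) - _FASTA_ALPHABET
                if bad:
                    raise InputError(
                        f"{path}:{lineno}: illegal character(s) "
                        f"{''.join(sorted(bad))!r}"
                    )
                records[current].append(line.upper())
    if not records:
        raise InputError(f"{path}: no FASTA records found")
    return {name: "".join(parts) for name, parts in records.items()}


def write_fasta(records: dict[str, str], path: str | Path, wrap: int = 60) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        for name in records:
            handle.write(f">{name}\n")
            seq = records[name]
            for i in range(0, len(seq), wrap):
                handle.write(seq[i : i + wrap] + "\n")


def write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, encoding="utf-8")


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", encoding="utf-8")


def genotype_table_to_frame(table: pd.DataFrame) -> pd.DataFrame:
    """Serialisable copy of a genotype table (tuples -> ';'-joined)."""
    out = table.copy()
    for col in ("variants", "active_variants"):
        if col in out.columns:
            out[col] = out[col].map(lambda v: ";".join(v))
    return out


def frame_to_genotype_table(df: pd.DataFrame) -> pd.DataFrame:
    out = df.copy()
    for col in ("variants", "active_variants"):
        if col in out.columns:
            out[col] = out[col].map(
                lambda v: tuple(str(v).split(";")) if isinstance(v, str) and v
                else ()
            )
    return out


def read_primer_tsv(path: str | Path) -> list[PrimerSet]:
    df = read_tsv(path)
    for col in ("name", "forward", "reverse"):
        if col not in df.columns:
            raise ConfigError(f"primer file {path} lacks column {col!r}")
    return [
        PrimerSet(str(row[0]), str(row[1]), str(row[2]))
        for row in df[["name", "forward", "reverse"]].itertuples(index=False)
    ]


def write_population(population: Population, outdir: str | Path) -> None:
    """FASTA per accession + metadata and truth TSVs."""
    outdir = Path(outdir)
    fasta_dir = outdir / "fasta"
    fasta_dir.mkdir(parents=True, exist_ok=True)
    for acc in population.accessions:
        write_fasta(acc.sequences, fasta_dir / f"{acc.accession_id}.fasta")
    write_tsv(population.metadata_frame(), outdir / "metadata.tsv")
    write_tsv(population.truth_frame(), outdir / "truth.tsv")


def read_population_fastas(fasta_dir: str | Path) -> dict[str, dict[str, str]]:
    """accession id (file stem) -> {sequence id -> DNA}."""
    fasta_dir = Path(fasta_dir)
    out = {}
    for path in sorted(fasta_dir.glob("*.fasta")):
        out[path.stem] = read_fasta(path)
    if not out:
        raise InputError(f"no .fasta files in {fasta_dir}")
    return out


# --------------------------------------------------------------------------
# configuration


@dataclass
class PipelineConfig:
    """One structured config drives the whole run."""

    seed: int = 0
    out_dir: str = "lmwgs-out"
    #: "reference" uses the packaged 157-accession panel; custom genotype
    #: definitions/region counts may be given over the packaged variants.
    population_source: str = "reference"
    genotype_defs: dict | None = None
    region_counts: dict | None = None
    snp_rate: float = 0.0
    indel_rate: float = 0.0
    indel_unit: int = 24
    premature_stop_probability: float = 0.0
    t_gene: float = 0.95
    naming_prefix: str = "TuA3-"
    primers: str = "reference"  # or a path to a primer TSV
    newick_decimals: int = 6

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(
                f"unknown config key(s): {', '.join(sorted(unknown))}"
            )
        return cls(**raw)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as handle:
            raw = yaml.safe_load(handle) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"config {path} is not a mapping")
        return cls.from_dict(raw)

    def mutation_spec(self) -> MutationSpec:
        return MutationSpec(
            snp_rate=self.snp_rate,
            indel_rate=self.indel_rate,
            indel_unit=self.indel_unit,
            premature_stop_probability=self.premature_stop_probability,
            seed=self.seed,
        )

    def primer_sets(self) -> list[PrimerSet]:
        if self.primers == "reference":
            return reference.reference_primer_sets()
        path = Path(self.primers)
        if not path.exists():
            raise ConfigError(f"primer file not found: {path}")
        return read_primer_tsv(path)

    def population_config(self) -> PopulationConfig:
        base = reference.reference_population_config()
        base.primer_sets = self.primer_sets()
        if self.population_source == "reference":
            return base
        if self.population_source != "custom":
            raise ConfigError(
                f"unknown population source {self.population_source!r}"
            )
        if not self.genotype_defs or not self.region_counts:
            raise ConfigError(
                "custom population needs genotype_defs and region_counts"
            )
        base.genotype_defs = {
            g: tuple(v) for g, v in self.genotype_defs.items()
        }
        base.region_counts = {
            g: dict(c) for g, c in self.region_counts.items()
        }
        base.named_accessions = {}
        base.validate()
        return base


# --------------------------------------------------------------------------
# pipeline


def _stage(name: str, n: int | None = None):
    log.info("stage %s: start%s", name, "" if n is None else f" (n={n})")


def _stage_done(name: str, n: int | None = None):
    log.info("stage %s: done%s", name, "" if n is None else f" (n={n})")


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full analysis and write the report bundle.

    Returns the summary report (also written as ``report.json``).  All
    validation that can fail fast (primer files, population config) happens
    before any output is created.
    """
    # fail-fast validation before touching the filesystem
    primer_sets = config.primer_sets()
    pop_config = config.population_config()
    mutations = config.mutation_spec()
    mutations.validate()

    outdir = Path(config.out_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    _stage("simulate")
    population = make_population(pop_config, mutations)
    write_population(population, outdir)
    _stage_done("simulate", len(population.accessions))

    # ---- annotation of unique sequences --------------------------------
    _stage("annotate")
    unique_dna: dict[str, list[str]] = {}
    for acc in population.accessions:
        for seq_id, dna in acc.sequences.items():
            unique_dna.setdefault(dna, []).append(seq_id)
    annotations = {dna: annotate_gene(dna) for dna in sorted(unique_dna)}
    _stage_done("annotate", len(annotations))

    # ---- marker genotyping ----------------------------------------------
    _stage("genotype")
    profiles = [
        build_profile(acc.accession_id, acc.sequences, primer_sets)
        for acc in population.accessions
    ]
    calls = call_genotypes(profiles, population.sequences_by_accession())
    write_tsv(profiles_to_frame(profiles), outdir / "fragment_sizes.tsv")
    write_tsv(triplets_to_frame(profiles), outdir / "fragment_triplets.tsv")
    write_tsv(calls, outdir / "genotype_calls.tsv")
    _stage_done("genotype", len(calls))

    # ---- catalog clustering ---------------------------------------------
    _stage("cluster")
    accessions_by_dna: dict[str, set[str]] = {}
    for acc in population.accessions:
        for dna in acc.sequences.values():
            accessions_by_dna.setdefault(dna, set()).add(acc.accession_id)
    lmwgs1 = next(ps for ps in primer_sets if ps.name == "LMWGS1")
    size_by_dna: dict[str, int] = {}
    for dna in accessions_by_dna:
        size = virtual_amplicon(dna, lmwgs1)
        # non-amplified sequences fall back to their theoretical full length
        size_by_dna[dna] = size if isinstance(size, int) else len(dna)
    entries = [
        SequenceEntry(
            sequence_id=min(unique_dna[dna]),
            dna=dna,
            accession_count=len(accessions_by_dna[dna]),
            lmwgs1_size=size_by_dna[dna],
        )
        for dna in sorted(unique_dna)
    ]
    catalog = cluster_variants(
        entries, t_gene=config.t_gene, prefix=config.naming_prefix
    )
    write_tsv(catalog.to_frame(), outdir / "catalog.tsv")
    _stage_done("cluster", catalog.n_variants)

    # ---- genotype table computed from the pipeline's own calls ----------
    _stage("diversity")
    name_by_dna = {v.dna: v.name for v in catalog.variants()}
    active_by_name = {
        name_by_dna[dna]: annotations[dna].orf_status == "active"
        for dna in name_by_dna
    }
    type_by_name = {
        name_by_dna[dna]: annotations[dna].subunit_type for dna in name_by_dna
    }
    call_by_acc = dict(zip(calls["accession_id"], calls["genotype"]))
    rows = []
    for acc in population.accessions:
        variants = tuple(
            sorted(name_by_dna[dna] for dna in acc.sequences.values())
        )
        rows.append(
            {
                "accession_id": acc.accession_id,
                "region": acc.region,
                "genotype": call_by_acc[acc.accession_id],
                "variants": variants,
                "active_variants": tuple(
                    v for v in variants if active_by_name[v]
                ),
            }
        )
    table = pd.DataFrame(rows)
    write_tsv(genotype_table_to_frame(table), outdir / "genotype_table.tsv")

    summary_df = genotype_summary(table)
    census, census_summary = active_gene_census(
        table, type_by_name, active_variants={
            v for v, a in active_by_name.items() if a
        },
    )
    regions_df = regional_summary(table, catalog.variant_to_gene())
    freqs = variant_frequencies(catalog, table)
    haplos = haplotype_cosegregation(table)
    write_tsv(summary_df, outdir / "genotype_summary.tsv")
    write_tsv(census, outdir / "active_gene_census.tsv")
    write_tsv(regions_df, outdir / "region_summary.tsv")
    write_tsv(freqs, outdir / "variant_frequencies.tsv")
    write_tsv(haplos, outdir / "haplotypes.tsv")
    _stage_done("diversity", len(summary_df))

    # ---- annotation table with catalog-aware stop localisation ----------
    annotation_rows = []
    gene_by_name = catalog.variant_to_gene()
    active_rep: dict[str, str] = {}
    for gene in catalog.genes:
        for v in gene.variants:
            if active_by_name[v.name]:
                active_rep.setdefault(gene.name, v.dna)
    for v in catalog.variants():
        a = annotations[v.dna]
        stop_domain, flag = a.stop_domain, None
        if a.orf_status == "pseudo":
            ref_dna = active_rep.get(gene_by_name[v.name])
            if ref_dna is not None:
                ref_ann = annotations[ref_dna]
                stop_domain, flag = localize_stop(
                    a.protein, ref_ann.protein, ref_ann
                )
            else:
                stop_domain, flag = localize_stop(a.protein)
        annotation_rows.append(
            {
                "variant": v.name,
                "gene": gene_by_name[v.name],
                "subunit_type": a.subunit_type,
                "orf_status": a.orf_status,
                "stop_domain": stop_domain,
                "stop_localisation": flag or "",
                "mature_length": a.mature_length,
                "n_cysteines": len(a.cysteine_positions),
                "cys_CI": a.cysteines_per_domain["C-terminal I"],
                "cys_CII": a.cysteines_per_domain["C-terminal II"],
                "cys_CIII": a.cysteines_per_domain["C-terminal III"],
                "mw_da": round(a.mw_da, 2) if a.mw_da else "",
                "pi": a.pi if a.pi else "",
            }
        )
    write_tsv(pd.DataFrame(annotation_rows), outdir / "annotations.tsv")

    # ---- phylogeny -------------------------------------------------------
    _stage("phylo")
    taxa = {v.name: v.dna for v in catalog.variants()}
    dm = pdistance_matrix(taxa)
    tree = neighbor_joining(dm)
    dm.to_frame().to_csv(outdir / "distances.tsv", sep="\t")
    (outdir / "tree.nwk").write_text(
        tree.newick(config.newick_decimals) + "\n", encoding="utf-8"
    )
    gene_mono = check_monophyly(tree, gene_by_name)
    type_mono = check_monophyly(tree, type_by_name)
    _stage_done("phylo", len(dm.taxa))

    # ---- truth recovery ---------------------------------------------------
    truth_genotype = {
        a.accession_id: a.genotype for a in population.accessions
    }
    called_partition = _partition(call_by_acc)
    truth_partition = _partition(truth_genotype)
    type_ok = orf_ok = 0
    seq_lookup = population.all_sequences()
    for t in population.truth:
        a = annotations[seq_lookup[t.sequence_id]]
        type_ok += a.subunit_type == t.subunit_type
        orf_ok += a.orf_status == t.orf_status
    n_seq = len(population.truth)
    truth_recovery = {
        "genotype_partition_equal": called_partition == truth_partition,
        "n_called_genotypes": len(called_partition),
        "n_truth_genotypes": len(truth_partition),
        "n_genes_truth": len(
            {t.gene_id for t in population.truth}
        ),
        "n_genes_called": catalog.n_genes,
        "type_call_accuracy": round(type_ok / n_seq, 4),
        "orf_call_accuracy": round(orf_ok / n_seq, 4),
    }

    report = {
        "n_accessions": len(population.accessions),
        "n_sequences": n_seq,
        "n_genes": catalog.n_genes,
        "n_variants": catalog.n_variants,
        "n_genotypes": int(calls["genotype"].nunique()),
        "top_genotypes": [
            {
                "genotype": r.genotype,
                "n_accessions": int(r.n_accessions),
                "share_pct": r.share_pct,
            }
            for r in summary_df.head(4).itertuples(index=False)
        ],
        "pct_three_active_i": census_summary["pct_three_active_i"],
        "region_ranking": list(regions_df["region"]),
        "gene_monophyly": gene_mono,
        "type_monophyly": type_mono,
        "truth_recovery": truth_recovery,
    }
    (outdir / "report.json").write_text(
        json.dumps(report, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    log.info("pipeline complete: report written to %s", outdir / "report.json")
    return report


def _partition(assignment: dict[str, str]) -> set[frozenset]:
    groups: dict[str, set[str]] = {}
    for item, label in assignment.items():
        groups.setdefault(label, set()).add(item)
    return {frozenset(g) for g in groups.values()}
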