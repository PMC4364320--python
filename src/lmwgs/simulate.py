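"""Synthetic LMW-GS genes and populations with full truth labels.

Real LMW-GS coding sequences are intronless and follow a modular protein
layout, which makes the family convenient to emulate: a gene template lists
the protein parts (signal peptide, type-specific N-terminal domain, a
repetitive domain built from short Q/P-rich motifs, and the three
C-terminal domains carrying the canonical 6/1/1 cysteines), and the DNA is
obtained by back-translation through a fixed codon table so that fragment
sizes are exactly reproducible.  Sequence variation is layered on top:
substitutions at a per-site rate, motif-multiple (in-frame) indels inside
the repetitive domain, and premature stop codons that turn a copy into a
pseudo-gene.

Every emitted sequence carries a truth record (gene, variant, type, ORF
status, post-mutation domain coordinates and theoretical amplicon sizes),
so downstream genotyping, clustering and annotation can be scored against
a known answer.  One top-level seed drives everything; per-sequence
generators are spawned from it through ``numpy``'s ``SeedSequence`` with
the sequence's global index as spawn key, so populations are reproducible
and order-independent in parallel settings.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from . import annotate as _ann
from .errors import ConfigError, ValidationError
from .marker import NOT_AMPLIFIED, PrimerSet, virtual_amplicon

# --------------------------------------------------------------------------
# codon usage
#
# One codon per amino acid ("most common wheat codon" style choice),
# version 1; determinism of the encoded DNA is what matters downstream.

CODON = {
    "A": "GCC", "R": "AGG", "N": "AAC", "D": "GAC", "C": "TGC",
    "Q": "CAA", "E": "GAG", "G": "GGC", "H": "CAC", "I": "ATC",
    "L": "CTG", "K": "AAG", "M": "ATG", "F": "TTC", "P": "CCA",
    "S": "TCA", "T": "ACA", "W": "TGG", "Y": "TAC", "V": "GTG",
}
STOP_CODON = "TAA"

#: Alternate synonymous codon for each encodable amino acid (M and W have
#: single codons and are absent).  Used for silent variant-tagging edits.
SYNONYMOUS_ALT = {
    "A": "GCT", "R": "AGA", "N": "AAT", "D": "GAT", "C": "TGT",
    "Q": "CAG", "E": "GAA", "G": "GGT", "H": "CAT", "I": "ATT",
    "L": "CTC", "K": "AAA", "F": "TTT", "P": "CCT", "S": "TCT",
    "T": "ACT", "Y": "TAT", "V": "GTT",
}


def encode_protein(protein: str) -> str:
    """Back-translate a protein through the fixed codon table (no stop)."""
    try:
        return "".join(CODON[aa] for aa in protein)
    except KeyError as exc:
        raise ValidationError(f"cannot encode residue {exc.args[0]!r}") from None


# --------------------------------------------------------------------------
# gene templates


@dataclass(frozen=True)
class GeneTemplate:
    """Blueprint of one LMW-GS gene.

    The repetitive domain is built by concatenating ``repeat_motifs[:-1]``
    once (a fixed head) followed by ``repeat_motifs[-1]`` repeated
    ``repeat_count`` times; length polymorphism between allelic variants is
    expressed by varying ``repeat_count``.
    """

    gene_id: str
    subunit_type: str                     # "i" | "m" | "s"
    signal_peptide: str                   # 20 residues
    n_terminal: str                       # "" for i-type
    repeat_motifs: tuple[str, ...]
    repeat_count: int
    cterm1: str                           # 6 cysteines
    cterm2: str                           # 1 cysteine
    cterm3: str                           # 1 cysteine
    #: primer-set name -> (forward, reverse) nucleotide anchors, reverse
    #: given 5'->3' on the minus strand; may be empty.
    primer_sites: dict[str, tuple[str, str]] = field(default_factory=dict)

    def validate(self) -> None:
        for name, part, want in (
            ("cterm1", self.cterm1, 6),
            ("cterm2", self.cterm2, 1),
            ("cterm3", self.cterm3, 1),
        ):
            got = part.count("C")
            if got != want:
                raise ValidationError(
                    f"{self.gene_id}: domain {name} has {got} cysteines, "
                    f"expected {want}"
                )
        if len(self.signal_peptide) != 20:
            raise ValidationError(
                f"{self.gene_id}: signal peptide must be 20 residues"
            )
        for label, part in (
            ("signal_peptide", self.signal_peptide),
            ("n_terminal", self.n_terminal),
            ("repeat_motifs", "".join(self.repeat_motifs)),
        ):
            if "C" in part:
                raise ValidationError(
                    f"{self.gene_id}: cysteine outside C-terminal domains "
                    f"(in {label})"
                )
        if self.subunit_type == "i":
            if self.n_terminal:
                raise ValidationError(
                    f"{self.gene_id}: i-type template must lack an "
                    "N-terminal domain"
                )
            if not self.repeat_motifs or not self.repeat_motifs[0].startswith("I"):
                raise ValidationError(
                    f"{self.gene_id}: i-type mature protein must start with Ile"
                )
        elif self.subunit_type == "m":
            if not self.n_terminal.startswith("M"):
                raise ValidationError(
                    f"{self.gene_id}: m-type mature protein must start with Met"
                )
        elif self.subunit_type == "s":
            if not self.n_terminal.startswith(_ann.S_TYPE_NTERM):
                raise ValidationError(
                    f"{self.gene_id}: s-type N-terminal must begin "
                    f"{_ann.S_TYPE_NTERM!r}"
                )
        else:
            raise ValidationError(
                f"{self.gene_id}: unknown subunit type {self.subunit_type!r}"
            )
        if self.repeat_count < 1:
            raise ValidationError(f"{self.gene_id}: repeat_count must be >= 1")

    # ---- protein layout -------------------------------------------------

    @property
    def repeat_region(self) -> str:
        head = "".join(self.repeat_motifs[:-1])
        return head + self.repeat_motifs[-1] * self.repeat_count

    @property
    def protein(self) -> str:
        """Full precursor protein (signal included)."""
        return (
            self.signal_peptide
            + self.n_terminal
            + self.repeat_region
            + self.cterm1
            + self.cterm2
            + self.cterm3
        )

    @property
    def mature_start(self) -> int:
        """Index of the first mature residue (MEN is cleaved from s-types)."""
        return len(self.signal_peptide) + (3 if self.subunit_type == "s" else 0)

    def domain_map(self) -> dict[str, tuple[int, int]]:
        """Truth domain coordinates on the mature protein (0-based, half-open)."""
        nterm = len(self.n_terminal) - (3 if self.subunit_type == "s" else 0)
        rep = len(self.repeat_region)
        c1, c2, c3 = len(self.cterm1), len(self.cterm2), len(self.cterm3)
        bounds = np.cumsum([0, nterm, rep, c1, c2, c3])
        return {
            name: (int(bounds[i]), int(bounds[i + 1]))
            for i, name in enumerate(_ann.MATURE_DOMAINS)
        }

    def encode(self) -> str:
        """CDS nucleotide sequence (ATG ... stop)."""
        return encode_protein(self.protein) + STOP_CODON


def standard_primer_sites(template: GeneTemplate) -> dict[str, tuple[str, str]]:
    """Default anchor scheme for the three conserved primer sets.

    All three amplicons span the repetitive domain, so fragment sizes of
    one gene move together across sets (LMWGS2 the longest, then LMWGS1,
    then LMWGS3), which is what makes cross-set correspondence work.
    """
    sig = template.signal_peptide

    def enc(aa: str) -> str:
        return encode_protein(aa)

    def rev(aa: str) -> str:
        return str(Seq(enc(aa)).reverse_complement())

    return {
        "LMWGS1": (enc(sig[0:7]), rev(template.cterm2[0:7])),
        "LMWGS2": (enc(sig[0:7]), rev(template.cterm3[-7:])),
        "LMWGS3": (enc(sig[13:20]), rev(template.cterm1[-7:])),
    }


def primer_sets_from_sites(
    sites: dict[str, tuple[str, str]]
) -> list[PrimerSet]:
    return [PrimerSet(name, fwd, rv) for name, (fwd, rv) in sorted(sites.items())]


# --------------------------------------------------------------------------
# mutation model


@dataclass(frozen=True)
class MutationSpec:
    """Stochastic variation applied to an encoded gene.

    ``snp_rate`` is per nucleotide site; ``indel_rate`` is the expected
    number of motif-multiple indel events per sequence (each inserting or
    deleting ``indel_unit`` nucleotides, a multiple of 3, at a codon
    boundary inside the repetitive domain); ``premature_stop_probability``
    is per sequence, with the stop written at a codon boundary inside
    ``stop_domain``.
    """

    snp_rate: float = 0.0
    indel_rate: float = 0.0
    indel_unit: int = 24
    premature_stop_probability: float = 0.0
    stop_domain: str = _ann.DOMAIN_REPETITIVE
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 <= self.snp_rate <= 1.0:
            raise ValidationError("snp_rate must be in [0, 1]")
        if not 0.0 <= self.premature_stop_probability <= 1.0:
            raise ValidationError("premature_stop_probability must be in [0, 1]")
        if self.indel_rate < 0:
            raise ValidationError("indel_rate must be >= 0")
        if self.indel_unit <= 0 or self.indel_unit % 3:
            raise ValidationError("indel_unit must be a positive multiple of 3")

    @property
    def is_null(self) -> bool:
        return (
            self.snp_rate == 0
            and self.indel_rate == 0
            and self.premature_stop_probability == 0
        )


def sequence_rng(seed: int, index: int) -> np.random.Generator:
    """Per-sequence generator: top-level seed + global sequence counter."""
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(index,))
    )


# --------------------------------------------------------------------------
# truth records


@dataclass
class TruthRow:
    """Ground truth for one emitted sequence."""

    sequence_id: str
    accession_id: str
    gene_id: str
    variant_id: str
    subunit_type: str
    orf_status: str
    stop_domain: str
    mature_start: int
    domains: dict[str, tuple[int, int]]
    amplicons: dict[str, int | str]
    dna_length: int

    def as_dict(self) -> dict:
        row = {
            "sequence_id": self.sequence_id,
            "accession_id": self.accession_id,
            "gene_id": self.gene_id,
            "variant_id": self.variant_id,
            "subunit_type": self.subunit_type,
            "orf_status": self.orf_status,
            "stop_domain": self.stop_domain,
            "mature_start": self.mature_start,
            "dna_length": self.dna_length,
        }
        for name, (lo, hi) in self.domains.items():
            row[f"{name} span"] = f"{lo}-{hi}"
        for name, size in sorted(self.amplicons.items()):
            row[f"size {name}"] = size
        return row


def refresh_orf_truth(dna: str, truth: TruthRow) -> None:
    """Recompute ORF status/stop domain of a truth row from its final DNA."""
    protein = str(Seq(dna[: len(dna) - len(dna) % 3]).translate())
    if protein.endswith("*"):
        protein = protein[:-1]
    stops = [i for i, aa in enumerate(protein) if aa == "*"]
    if stops:
        truth.orf_status = "pseudo"
        first = stops[0]
        if first < truth.mature_start:
            truth.stop_domain = _ann.DOMAIN_SIGNAL
        else:
            truth.stop_domain = _ann.domain_of_position(
                truth.domains, first - truth.mature_start
            )
    else:
        truth.orf_status = "active"
        truth.stop_domain = _ann.DOMAIN_NONE
    truth.dna_length = len(dna)


def _shift_domains(
    domains: dict[str, tuple[int, int]], after: str, delta: int
) -> dict[str, tuple[int, int]]:
    """Grow/shrink ``after`` by ``delta`` residues, shifting later domains."""
    out, shift = {}, 0
    for name in _ann.MATURE_DOMAINS:
        lo, hi = domains[name]
        lo += shift
        if name == after:
            shift += delta
        out[name] = (lo, hi + shift)
    return out


def apply_mutations(
    dna: str, truth: TruthRow, spec: MutationSpec, rng: np.random.Generator
) -> tuple[str, TruthRow]:
    """Mutate an encoded gene, keeping the truth record consistent.

    Order: indels, then a possible premature stop, then SNPs; ORF status is
    re-derived from the final sequence (so SNP-created stops are recorded
    truthfully too).
    """
    truth = replace(truth, domains=dict(truth.domains))
    if spec.is_null:
        refresh_orf_truth(dna, truth)
        return dna, truth
    seq = list(dna)
    unit_codons = spec.indel_unit // 3

    def codon_span(domain: str) -> tuple[int, int]:
        lo, hi = truth.domains[domain]
        return truth.mature_start + lo, truth.mature_start + hi

    if spec.indel_rate > 0:
        for _ in range(rng.poisson(spec.indel_rate)):
            lo, hi = codon_span(_ann.DOMAIN_REPETITIVE)
            deletion = bool(rng.integers(2))
            if deletion and hi - lo <= unit_codons:
                continue  # repetitive domain too short to shrink further
            top = hi - unit_codons if deletion else hi - unit_codons
            if top <= lo:
                continue
            c = int(rng.integers(lo, top))
            if deletion:
                del seq[3 * c : 3 * (c + unit_codons)]
                delta = -unit_codons
            else:  # tandem duplication of an existing repeat stretch
                seq[3 * c : 3 * c] = seq[3 * c : 3 * (c + unit_codons)]
                delta = unit_codons
            truth.domains = _shift_domains(
                truth.domains, _ann.DOMAIN_REPETITIVE, delta
            )
    if spec.premature_stop_probability > 0 and (
        rng.random() < spec.premature_stop_probability
    ):
        lo, hi = codon_span(spec.stop_domain)
        if hi - lo > 1:
            c = int(rng.integers(lo + 1, hi))
            seq[3 * c : 3 * c + 3] = list(STOP_CODON)
    if spec.snp_rate > 0:
        hits = np.flatnonzero(rng.random(len(seq)) < spec.snp_rate)
        bases = "ACGT"
        for i in hits:
            current = seq[i]
            choices = [b for b in bases if b != current]
            seq[i] = choices[int(rng.integers(3))]
    mutated = "".join(seq)
    refresh_orf_truth(mutated, truth)
    return mutated, truth


# --------------------------------------------------------------------------
# single-gene generation


def gene_truth(
    template: GeneTemplate,
    sequence_id: str = "",
    accession_id: str = "",
    variant_id: str = "",
) -> TruthRow:
    """Truth record of an unmutated template encoding."""
    dna = template.encode()
    truth = TruthRow(
        sequence_id=sequence_id or template.gene_id,
        accession_id=accession_id,
        gene_id=template.gene_id,
        variant_id=variant_id or template.gene_id,
        subunit_type=template.subunit_type,
        orf_status="active",
        stop_domain=_ann.DOMAIN_NONE,
        mature_start=template.mature_start,
        domains=template.domain_map(),
        amplicons={},
        dna_length=len(dna),
    )
    return truth


def measure_amplicons(
    dna: str, primer_sets: list[PrimerSet]
) -> dict[str, int | str]:
    sizes: dict[str, int | str] = {}
    for ps in primer_sets:
        try:
            sizes[ps.name] = virtual_amplicon(dna, ps)
        except Exception:
            sizes[ps.name] = NOT_AMPLIFIED
    return sizes


def make_gene(
    template: GeneTemplate,
    mutations: MutationSpec,
    sequence_index: int = 0,
    primer_sets: list[PrimerSet] | None = None,
) -> tuple[str, TruthRow]:
    """Encode one gene from its template and apply the mutation model.

    ``sequence_index`` selects the spawned per-sequence RNG stream, so a
    population generator can hand out consecutive indices and stay
    reproducible.  Truth records post-mutation domain coordinates, ORF
    status, and (when primer sets are given) theoretical amplicon sizes.
    """
    template.validate()
    mutations.validate()
    dna = template.encode()
    truth = gene_truth(template)
    rng = sequence_rng(mutations.seed, sequence_index)
    dna, truth = apply_mutations(dna, truth, mutations, rng)
    if primer_sets is None and template.primer_sites:
        primer_sets = primer_sets_from_sites(template.primer_sites)
    if primer_sets:
        truth.amplicons = measure_amplicons(dna, primer_sets)
    return dna, truth


# --------------------------------------------------------------------------
# populations


@dataclass
class Accession:
    accession_id: str
    region: str
    genotype: str
    sequences: dict[str, str]             # sequence id -> DNA


@dataclass
class Population:
    accessions: list[Accession]
    truth: list[TruthRow]

    def metadata_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "accession_id": [a.accession_id for a in self.accessions],
                "region": [a.region for a in self.accessions],
            }
        )

    def genotype_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "accession_id": [a.accession_id for a in self.accessions],
                "region": [a.region for a in self.accessions],
                "genotype": [a.genotype for a in self.accessions],
            }
        )

    def truth_frame(self) -> pd.DataFrame:
        return pd.DataFrame([t.as_dict() for t in self.truth])

    def sequences_by_accession(self) -> dict[str, list[str]]:
        return {
            a.accession_id: [a.sequences[k] for k in sorted(a.sequences)]
            for a in self.accessions
        }

    def all_sequences(self) -> dict[str, str]:
        out: dict[str, str] = {}
        for a in self.accessions:
            out.update(a.sequences)
        return out


@dataclass
class PopulationConfig:
    """Population blueprint: genotypes as variant multisets, spread over regions.

    ``variant_dna``/``variant_truth`` define the variant library (e.g. from
    the packaged reference panel, or from templates of the caller's own
    design); each accession receives a fresh, independently mutated copy of
    every variant its genotype lists.
    """

    genotype_defs: dict[str, tuple[str, ...]]
    region_counts: dict[str, dict[str, int]]
    variant_dna: dict[str, str]
    variant_truth: dict[str, TruthRow]
    primer_sets: list[PrimerSet] = field(default_factory=list)
    named_accessions: dict[str, tuple[str, str]] = field(default_factory=dict)
    accession_prefix: str = "TU"
    region_order: tuple[str, ...] | None = None

    def validate(self) -> None:
        for name, variants in self.genotype_defs.items():
            for vid in variants:
                if vid not in self.variant_dna:
                    raise ConfigError(
                        f"genotype {name} references undefined variant {vid}"
                    )
        for name, counts in self.region_counts.items():
            if name not in self.genotype_defs:
                raise ConfigError(f"region counts given for unknown genotype {name}")
            for region, n in counts.items():
                if n < 0:
                    raise ConfigError(
                        f"negative count for {name} in {region}"
                    )
        for acc, (gt, region) in self.named_accessions.items():
            if self.region_counts.get(gt, {}).get(region, 0) < 1:
                raise ConfigError(
                    f"named accession {acc}: no {gt} accession collected in {region}"
                )


def _natural_key(name: str):
    m = re.fullmatch(r"([A-Za-z]*)(\d+)", name)
    return (m.group(1), int(m.group(2))) if m else (name, -1)


def make_population(
    config: PopulationConfig, mutations: MutationSpec
) -> Population:
    """Emit a whole population with one truth row per sequence.

    Accessions are laid out deterministically (genotypes in natural-sort
    order, regions in ``region_order``), each carrying its genotype's
    variant sequences after independent per-sequence mutation; the output
    is byte-identical across runs with the same seed.
    """
    config.validate()
    mutations.validate()
    regions = config.region_order or tuple(
        sorted({r for c in config.region_counts.values() for r in c})
    )
    named_by_slot: dict[tuple[str, str], list[str]] = {}
    for acc, slot in sorted(config.named_accessions.items()):
        named_by_slot.setdefault(slot, []).append(acc)
    accessions: list[Accession] = []
    truth_rows: list[TruthRow] = []
    serial = 0
    seq_index = 0
    for genotype in sorted(config.genotype_defs, key=_natural_key):
        counts = config.region_counts.get(genotype, {})
        for region in regions:
            pending = list(named_by_slot.get((genotype, region), []))
            for _ in range(counts.get(region, 0)):
                if pending:
                    acc_id = pending.pop(0)
                else:
                    serial += 1
                    acc_id = f"{config.accession_prefix}{serial:04d}"
                sequences: dict[str, str] = {}
                for vid in config.genotype_defs[genotype]:
                    rng = sequence_rng(mutations.seed, seq_index)
                    seq_index += 1
                    base = config.variant_truth[vid]
                    truth = replace(
                        base,
                        sequence_id=f"{acc_id}|{vid}",
                        accession_id=acc_id,
                        domains=dict(base.domains),
                        amplicons=dict(base.amplicons),
                    )
                    dna, truth = apply_mutations(
                        config.variant_dna[vid], truth, mutations, rng
                    )
                    if config.primer_sets:
                        truth.amplicons = measure_amplicons(
                            dna, config.primer_sets
                        )
                    sequences[truth.sequence_id] = dna
                    truth_rows.append(truth)
                accessions.append(
                    Accession(acc_id, region, genotype, sequences)
                )
    return Population(accessions=accessions, truth=truth_rows)
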