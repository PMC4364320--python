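"""Annotation of LMW-GS gene sequences.

Low-molecular-weight glutenin subunit (LMW-GS) genes encode seed-storage
prolamins with a stereotyped layout: a ~20-residue signal peptide, a short
N-terminal domain (absent from i-type subunits), a glutamine/proline-rich
repetitive domain, and three conserved C-terminal sub-domains (I/II/III)
that together house eight cysteines (6/1/1).  Subunit types are named after
the first residue of the mature protein: i (isoleucine), m (methionine) and
s (serine; the s-type N-terminus MENSHIPGLEKPS loses its leading MEN
tripeptide on maturation).  Gene copies whose reading frame is interrupted
by a premature stop codon are pseudo-genes; the stop is reported by the
domain it falls in.

This module works on a single nucleotide sequence at a time:

* :func:`find_orf` - read-through translation from the first ATG, internal
  stops reported (so they can later be localised to a domain);
* :func:`cleave_and_type` - signal-peptide cleavage and i/m/s typing;
* :func:`segment_domains` - domain segmentation by cysteine ordinals;
* :func:`localize_stop` - map a premature stop onto the domain map of an
  intact variant of the same gene;
* :func:`molecular_weight` / :func:`isoelectric_point` - protein chemistry
  from packaged average-mass and pKa tables;
* :func:`annotate_gene` / :func:`annotate_population` - the one-call
  front-ends producing :class:`GeneAnnotation` records.

Coordinates are 0-based half-open throughout; the five mature-protein
domains tile the mature sequence exactly.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import pandas as pd
from Bio.Align import PairwiseAligner
from Bio.Seq import Seq

from .errors import AnnotationError, AtypicalCysteineWarning, InputError

# --------------------------------------------------------------------------
# constants

DOMAIN_SIGNAL = "signal"
DOMAIN_NTERM = "N-terminal"
DOMAIN_REPETITIVE = "repetitive"
DOMAIN_CTERM1 = "C-terminal I"
DOMAIN_CTERM2 = "C-terminal II"
DOMAIN_CTERM3 = "C-terminal III"
DOMAIN_NONE = "none"

#: Order of the domains that tile the mature protein.
MATURE_DOMAINS = (
    DOMAIN_NTERM,
    DOMAIN_REPETITIVE,
    DOMAIN_CTERM1,
    DOMAIN_CTERM2,
    DOMAIN_CTERM3,
)

#: s-type diagnostic N-terminus; the leading MEN tripeptide is cleaved.
S_TYPE_NTERM = "MENSHIPGLEKPS"

#: Mature-start motifs searched during signal cleavage, and the window
#: (residue indices on the translated protein) in which they may start.
CLEAVAGE_MOTIFS = ("ISQ", "MET", "MEN")
CLEAVAGE_WINDOW = (15, 30)
CLEAVAGE_FALLBACK = 20  # fixed cleavage after residue 20 when no motif hits

IUPAC_NT = set("ACGTRYSWKMBDHVN")

#: Average residue masses (Da), i.e. amino-acid mass minus one water.
#: Version 1 of the packaged table (standard IUPAC average atomic weights).
RESIDUE_MASS = {
    "G": 57.0519, "A": 71.0788, "S": 87.0782, "P": 97.1167, "V": 99.1326,
    "T": 101.1051, "C": 103.1388, "L": 113.1594, "I": 113.1594,
    "N": 114.1038, "D": 115.0886, "Q": 128.1307, "K": 128.1741,
    "E": 129.1155, "M": 131.1926, "H": 137.1411, "F": 147.1766,
    "R": 156.1875, "Y": 163.1760, "W": 186.2132,
}
WATER_MASS = 18.0153

#: pKa set used for net-charge/pI calculations (Lehninger values; packaged
#: as data so pI ordering is reproducible across releases).
PKA_POSITIVE = {"nterm": 9.69, "K": 10.53, "R": 12.48, "H": 6.00}
PKA_NEGATIVE = {"cterm": 2.34, "D": 3.65, "E": 4.25, "C": 8.18, "Y": 10.07}


# --------------------------------------------------------------------------
# data model


@dataclass
class GeneAnnotation:
    """Full annotation of one LMW-GS gene sequence.

    ``domains`` maps mature-domain names to ``[start, end)`` coordinates on
    the mature protein; the five domains are contiguous and tile it.
    ``mw_da``/``pi`` are reported for intact (active) subunits only.
    """

    orf_status: str                       # "active" | "pseudo"
    stop_domain: str                      # domain of first premature stop
    subunit_type: str                     # "i" | "m" | "s" | "unknown"
    mature_start: int                     # index into the translated protein
    domains: dict[str, tuple[int, int]]
    cysteine_positions: list[int]         # mature-protein indices
    cysteines_per_domain: dict[str, int]
    mw_da: float | None
    pi: float | None
    internal_stop_positions: list[int] = field(default_factory=list)
    flags: list[str] = field(default_factory=list)
    protein: str = ""                     # read-through translation
    mature: str = ""

    @property
    def mature_length(self) -> int:
        return len(self.mature)


# --------------------------------------------------------------------------
# ORF finding and translation


def find_orf(dna: str) -> tuple[str, list[int]]:
    """Translate ``dna`` from its first ATG, reading through internal stops.

    Returns the protein string (internal stops marked ``*``; the terminal
    stop, if any, is trimmed) and the 0-based protein positions of internal
    stops.  Read-through translation keeps downstream residues so premature
    stops can later be localised to a domain.
    """
    if not isinstance(dna, str) or len(dna) < 3:
        raise InputError("sequence shorter than one codon")
    seq = dna.upper()
    bad = [i for i, c in enumerate(seq) if c not in IUPAC_NT]
    if bad:
        raise InputError(
            f"non-IUPAC nucleotide {seq[bad[0]]!r} at position {bad[0]}"
        )
    start = seq.find("ATG")
    if start < 0:
        raise AnnotationError("no ORF: sequence contains no ATG start codon")
    coding = seq[start:]
    coding = coding[: len(coding) - len(coding) % 3]
    protein = str(Seq(coding).translate())  # '*' marks stops, 'X' ambiguity
    if protein.endswith("*"):
        protein = protein[:-1]
    stops = [i for i, aa in enumerate(protein) if aa == "*"]
    return protein, stops


# --------------------------------------------------------------------------
# signal cleavage and subunit typing


def cleave_and_type(protein: str) -> tuple[str, str, int]:
    """Remove the signal peptide and type the subunit.

    The cleavage site is the earliest occurrence of a mature-start motif
    (``ISQ``/``MET``/``MEN``) beginning within residues 15-30; if none is
    found the protein is cleaved after residue 20.  When the post-signal
    region starts with the s-type N-terminus ``MENSHIPGLEKPS`` the leading
    ``MEN`` tripeptide is additionally removed and the type is ``s``;
    otherwise the type follows the first mature residue (I/M/S -> i/m/s).

    Returns ``(mature, subunit_type, mature_start)`` where ``mature_start``
    indexes the first mature residue on ``protein``.
    """
    if len(protein) < 30:
        raise AnnotationError(
            f"protein too short to cleave ({len(protein)} < 30 residues)"
        )
    lo, hi = CLEAVAGE_WINDOW
    cut = None
    for pos in range(lo, min(hi, len(protein) - 3) + 1):
        if any(protein.startswith(m, pos) for m in CLEAVAGE_MOTIFS):
            cut = pos
            break
    if cut is None:
        cut = CLEAVAGE_FALLBACK
    post_signal = protein[cut:]
    if post_signal.startswith(S_TYPE_NTERM):
        mature_start = cut + 3  # the MEN tripeptide is cleaved as well
        subunit_type = "s"
    else:
        mature_start = cut
        first = post_signal[0] if post_signal else ""
        subunit_type = {"I": "i", "M": "m", "S": "s"}.get(first, "unknown")
    mature = protein[mature_start:]
    if len(mature) < 10:
        raise AnnotationError("mature region shorter than 10 residues")
    return mature, subunit_type, mature_start


# --------------------------------------------------------------------------
# domain segmentation


def _nterm_length(mature: str, subunit_type: str, first_cys: int) -> int:
    """Length of the N-terminal domain under the type-specific rule.

    i-type subunits have no N-terminal domain.  For m- and s-types the
    domain ends where the Q/P-rich repetitive region begins, operationalised
    as the first run of four consecutive residues drawn from {Q, P}; if no
    such run precedes the first cysteine, a 13-residue default is used
    (capped at the first cysteine).
    """
    if subunit_type == "i":
        return 0
    limit = first_cys if first_cys >= 0 else len(mature)
    for i in range(0, max(limit - 3, 0)):
        if all(c in "QP" for c in mature[i : i + 4]):
            return i
    return min(13, limit)


def domain_map_from_cysteines(
    mature: str, nterm_len: int
) -> tuple[dict[str, tuple[int, int]], list[str]]:
    """Tile the mature protein into domains using cysteine ordinals.

    The canonical layout places cysteines 1-6 in C-terminal I, the 7th at
    the end of C-terminal II and the 8th inside C-terminal III:
    repetitive = [end of N-terminal, 1st Cys), C-I = [1st Cys, 6th Cys],
    C-II = (6th, 7th], C-III = (7th, end of protein].  With k < 8 cysteines
    the ordinals fall back to (k-2, k-1); with more than 8 the canonical
    ordinals are kept and the surplus flagged.  Returns the domain map and
    any flags raised.
    """
    flags: list[str] = []
    cys = [i for i, c in enumerate(mature) if c == "C"]
    k = len(cys)
    n = len(mature)
    if k >= 3:
        if k < 8:
            warnings.warn(
                f"atypical cysteine architecture: {k} cysteines (expected 8);"
                " falling back to available ordinals",
                AtypicalCysteineWarning,
                stacklevel=3,
            )
            flags.append(f"atypical-cysteines:{k}")
            e1, e2 = cys[k - 3], cys[k - 2]
        else:
            e1, e2 = cys[5], cys[6]
            if k > 8:
                flags.append(f"extra-cysteines:{k - 8}")
        c1 = cys[0]
        nterm_len = min(nterm_len, c1)
        domains = {
            DOMAIN_NTERM: (0, nterm_len),
            DOMAIN_REPETITIVE: (nterm_len, c1),
            DOMAIN_CTERM1: (c1, e1 + 1),
            DOMAIN_CTERM2: (e1 + 1, e2 + 1),
            DOMAIN_CTERM3: (e2 + 1, n),
        }
    else:
        warnings.warn(
            f"atypical cysteine architecture: only {k} cysteines; "
            "C-terminal domains cannot be delimited",
            AtypicalCysteineWarning,
            stacklevel=3,
        )
        flags.append(f"atypical-cysteines:{k}")
        nterm_len = min(nterm_len, n)
        domains = {
            DOMAIN_NTERM: (0, nterm_len),
            DOMAIN_REPETITIVE: (nterm_len, n),
            DOMAIN_CTERM1: (n, n),
            DOMAIN_CTERM2: (n, n),
            DOMAIN_CTERM3: (n, n),
        }
    return domains, flags


def segment_domains(
    mature: str, subunit_type: str
) -> tuple[dict[str, tuple[int, int]], dict[str, int], list[str]]:
    """Segment a mature protein into its five domains.

    Returns ``(domains, cysteines_per_domain, flags)``.  The domain map is
    contiguous and tiles the mature protein; cysteine counts are reported
    for the three C-terminal domains (canonically 6/1/1).
    """
    cys = [i for i, c in enumerate(mature) if c == "C"]
    first_cys = cys[0] if cys else -1
    nterm_len = _nterm_length(mature, subunit_type, first_cys)
    domains, flags = domain_map_from_cysteines(mature, nterm_len)
    per_domain = {
        name: sum(1 for p in cys if lo <= p < hi)
        for name, (lo, hi) in domains.items()
    }
    return domains, per_domain, flags


def domain_of_position(
    domains: dict[str, tuple[int, int]], position: int
) -> str:
    """Name of the mature-protein domain containing ``position``."""
    for name, (lo, hi) in domains.items():
        if lo <= position < hi:
            return name
    return DOMAIN_NONE


# --------------------------------------------------------------------------
# premature-stop localisation

# Protein aligner for stop localisation: simple identity scoring with affine
# gaps; '*' is treated as just another symbol so read-through proteins align.
_PROTEIN_ALIGNER = PairwiseAligner()
_PROTEIN_ALIGNER.mode = "global"
_PROTEIN_ALIGNER.match_score = 2
_PROTEIN_ALIGNER.mismatch_score = -2
_PROTEIN_ALIGNER.open_gap_score = -8
_PROTEIN_ALIGNER.extend_gap_score = -1


def _map_to_reference(pseudo: str, reference: str, position: int) -> int:
    """Reference coordinate aligned with ``pseudo[position]``.

    Positions falling in a reference gap are mapped to the nearest aligned
    reference residue on the left (or 0 at the very start).
    """
    alignment = _PROTEIN_ALIGNER.align(reference, pseudo)[0]
    ref_blocks, qry_blocks = alignment.aligned
    best = 0
    for (r0, _r1), (q0, q1) in zip(ref_blocks, qry_blocks):
        if q0 <= position < q1:
            return r0 + (position - q0)
        if q1 <= position:
            best = r0 + (q1 - q0) - 1
    return max(best, 0)


def localize_stop(
    pseudo_protein: str,
    reference_protein: str | None = None,
    reference_annotation: GeneAnnotation | None = None,
) -> tuple[str, str | None]:
    """Domain of the first premature stop in a read-through translation.

    With an intact reference variant of the same gene, the stop column is
    mapped through a global protein alignment into the reference's domain
    map.  Without one, the pseudo-gene's own cysteine ordinals are used and
    the result flagged ``"self-referenced"``.

    Returns ``(domain_name, flag)`` with ``flag`` in {None, "self-referenced"}.
    """
    stops = [i for i, aa in enumerate(pseudo_protein) if aa == "*"]
    if not stops:
        raise AnnotationError("protein has no internal stop to localise")
    stop = stops[0]
    if reference_protein is not None and reference_annotation is not None:
        ref_pos = _map_to_reference(pseudo_protein, reference_protein, stop)
        if ref_pos < reference_annotation.mature_start:
            return DOMAIN_SIGNAL, None
        mature_pos = ref_pos - reference_annotation.mature_start
        return domain_of_position(reference_annotation.domains, mature_pos), None
    # self-referenced fallback
    mature, subunit_type, mature_start = cleave_and_type(pseudo_protein)
    if stop < mature_start:
        return DOMAIN_SIGNAL, "self-referenced"
    domains, _, _ = segment_domains(mature, subunit_type)
    return domain_of_position(domains, stop - mature_start), "self-referenced"


# --------------------------------------------------------------------------
# protein chemistry


def molecular_weight(protein: str) -> float:
    """Average molecular mass in Daltons (residue masses + one water)."""
    mass = WATER_MASS
    for i, aa in enumerate(protein):
        try:
            mass += RESIDUE_MASS[aa]
        except KeyError:
            raise InputError(
                f"unknown residue {aa!r} at position {i}"
            ) from None
    return mass


def _net_charge(protein: str, ph: float) -> float:
    counts: dict[str, int] = {}
    for aa in protein:
        if aa not in RESIDUE_MASS:
            raise InputError(f"unknown residue {aa!r}")
        counts[aa] = counts.get(aa, 0) + 1
    positive = sum(
        n / (1.0 + 10.0 ** (ph - PKA_POSITIVE[aa]))
        for aa, n in counts.items()
        if aa in PKA_POSITIVE
    )
    positive += 1.0 / (1.0 + 10.0 ** (ph - PKA_POSITIVE["nterm"]))
    negative = sum(
        n / (1.0 + 10.0 ** (PKA_NEGATIVE[aa] - ph))
        for aa, n in counts.items()
        if aa in PKA_NEGATIVE
    )
    negative += 1.0 / (1.0 + 10.0 ** (PKA_NEGATIVE["cterm"] - ph))
    return positive - negative


def isoelectric_point(protein: str) -> float:
    """pH at which the net charge vanishes, by bisection (tolerance 0.01)."""
    if protein == "":
        raise InputError("cannot compute pI of an empty protein")
    lo, hi = 0.0, 14.0
    while hi - lo > 1e-3:
        mid = 0.5 * (lo + hi)
        if _net_charge(protein, mid) > 0:
            lo = mid
        else:
            hi = mid
    return round(0.5 * (lo + hi), 2)


# --------------------------------------------------------------------------
# front-ends


def annotate_gene(dna: str) -> GeneAnnotation:
    """Annotate one gene sequence end to end.

    Molecular weight and pI are reported for intact subunits only; for
    pseudo-genes the premature stop is localised on the sequence's own
    domain map (use :func:`localize_stop` with an intact reference for the
    catalog-aware call).
    """
    protein, stops = find_orf(dna)
    mature, subunit_type, mature_start = cleave_and_type(protein)
    domains, per_domain, flags = segment_domains(mature, subunit_type)
    internal = [s for s in stops]
    status = "pseudo" if internal else "active"
    if internal:
        first = internal[0]
        if first < mature_start:
            stop_domain = DOMAIN_SIGNAL
        else:
            stop_domain = domain_of_position(domains, first - mature_start)
        mw = pi = None
    else:
        stop_domain = DOMAIN_NONE
        mw = molecular_weight(mature)
        pi = isoelectric_point(mature)
    return GeneAnnotation(
        orf_status=status,
        stop_domain=stop_domain,
        subunit_type=subunit_type,
        mature_start=mature_start,
        domains=domains,
        cysteine_positions=[i for i, c in enumerate(mature) if c == "C"],
        cysteines_per_domain=per_domain,
        mw_da=mw,
        pi=pi,
        internal_stop_positions=internal,
        flags=flags,
        protein=protein,
        mature=mature,
    )


def annotate_population(records: dict[str, str]) -> pd.DataFrame:
    """Annotate a mapping of sequence id -> DNA into a tidy table."""
    rows = []
    for seq_id in sorted(records):
        a = annotate_gene(records[seq_id])
        row = {
            "sequence_id": seq_id,
            "subunit_type": a.subunit_type,
            "orf_status": a.orf_status,
            "stop_domain": a.stop_domain,
            "mature_length": a.mature_length,
            "n_cysteines": len(a.cysteine_positions),
            "mw_da": round(a.mw_da, 2) if a.mw_da is not None else math.nan,
            "pi": a.pi if a.pi is not None else math.nan,
            "flags": ";".join(a.flags),
        }
        for name in MATURE_DOMAINS:
            lo, hi = a.domains[name]
            row[f"{name} span"] = f"{lo}-{hi}"
            row[f"{name} cys"] = a.cysteines_per_domain[name]
        rows.append(row)
    return pd.DataFrame(rows)
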