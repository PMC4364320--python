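"""In-silico fragment genotyping with the three-primer LMW-GS marker system.

The marker system amplifies every member of the LMW-GS gene family with
three conserved primer sets (LMWGS1/LMWGS2/LMWGS3) and reads fragment sizes
off capillary electrophoresis.  Because all three amplicons span the
length-polymorphic repetitive domain, the sizes of the fragments that one
gene yields under the three sets move together, which is what lets
fragments be matched across sets ("correspondence triplets") and lets an
accession's fragment-size multiset act as its genotype.

Here amplification is purely virtual: a primer binds only where its
sequence (forward) or reverse complement (reverse) matches exactly, the
fragment size is the full primer-to-primer interval, and a missing or
mutated site yields the sentinel ``N`` (not amplified) - mirroring how the
bench assay scores a null allele.  Genotypes are called from size multisets
and, when sequences are available, size-identical genotypes that differ
only by SNPs are split and flagged (the published U5/U6 pair is such a
case).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import pandas as pd
from Bio.Seq import Seq

from .errors import AmbiguousAmplificationError, InputError

#: Sentinel for "not amplified by this primer set".
NOT_AMPLIFIED = "N"

PRIMER_SET_NAMES = ("LMWGS1", "LMWGS2", "LMWGS3")


@dataclass(frozen=True)
class PrimerSet:
    """One conserved primer pair.

    ``forward`` matches the plus strand; ``reverse`` is given 5'->3' on the
    minus strand, i.e. its reverse complement is searched on the sequence.
    """

    name: str
    forward: str
    reverse: str

    def __post_init__(self):
        if len(self.forward) < 15 or len(self.reverse) < 15:
            raise InputError(
                f"primer set {self.name}: primers must be >= 15 nt"
            )


@dataclass
class MarkerProfile:
    """Per-accession fragment sizes plus cross-set correspondence triplets."""

    accession_id: str
    #: primer-set name -> sorted multiset of fragment sizes (bp)
    fragments: dict[str, list[int]] = field(default_factory=dict)
    #: one (size1, size2, size3) triplet per gene; entries may be ``N``
    triplets: list[tuple] = field(default_factory=list)

    def size_key(self) -> tuple:
        """Hashable per-set size multiset, the genotype identity at size level."""
        return tuple(
            tuple(self.fragments.get(name, ())) for name in PRIMER_SET_NAMES
        )


def _find_sites(seq: str, probe: str) -> list[int]:
    sites, start = [], 0
    while True:
        pos = seq.find(probe, start)
        if pos < 0:
            return sites
        sites.append(pos)
        start = pos + 1


def virtual_amplicon(dna: str, primer_set: PrimerSet) -> int | str:
    """Theoretical amplicon size (bp) of ``primer_set`` on ``dna``.

    Exact-match binding; the size includes both primers.  Returns ``N``
    when either site is absent (e.g. mutated away).  More than one binding
    site for either primer raises :class:`AmbiguousAmplificationError`.
    """
    seq = dna.upper()
    fwd_sites = _find_sites(seq, primer_set.forward.upper())
    rev_probe = str(Seq(primer_set.reverse.upper()).reverse_complement())
    rev_sites = _find_sites(seq, rev_probe)
    if len(fwd_sites) > 1 or len(rev_sites) > 1:
        raise AmbiguousAmplificationError(
            f"primer set {primer_set.name} binds multiple sites",
            positions=fwd_sites + rev_sites,
        )
    if not fwd_sites or not rev_sites:
        return NOT_AMPLIFIED
    start = fwd_sites[0]
    end = rev_sites[0] + len(rev_probe)
    if end <= start:
        return NOT_AMPLIFIED
    return end - start


def build_profile(
    accession_id: str,
    sequences: dict[str, str],
    primer_sets: list[PrimerSet],
) -> MarkerProfile:
    """Amplify every gene of one accession with every primer set.

    ``sequences`` maps sequence id -> DNA.  Each input gene contributes one
    correspondence triplet (its three per-set sizes, ``N`` allowed), so the
    triplet count equals the accession's gene count; an empty accession
    yields an empty profile.
    """
    triplets = []
    per_set: dict[str, list[int]] = {ps.name: [] for ps in primer_sets}
    for seq_id in sorted(sequences):
        dna = sequences[seq_id]
        sizes = []
        for ps in primer_sets:
            size = virtual_amplicon(dna, ps)
            sizes.append(size)
            if size != NOT_AMPLIFIED:
                per_set[ps.name].append(size)
        triplets.append(tuple(sizes))
    for name in per_set:
        per_set[name].sort()
    return MarkerProfile(
        accession_id=accession_id,
        fragments=per_set,
        triplets=sorted(triplets, key=str),
    )


def call_genotypes(
    profiles: list[MarkerProfile],
    sequences: dict[str, list[str]] | None = None,
) -> pd.DataFrame:
    """Call a genotype label for every accession of a population.

    Accessions with identical per-set size multisets share a provisional
    genotype.  When ``sequences`` (accession id -> list of gene DNAs) is
    supplied, size-identical groups whose sequences differ are split into
    SNP-discriminated genotypes and flagged.  Labels ``U1, U2, ...`` are
    assigned in descending accession-frequency order, ties broken by the
    first occurrence after sorting accession ids, which makes the call
    invariant to input order.

    Returns a DataFrame with columns accession_id, genotype, flags.
    """
    if not profiles:
        raise InputError("no profiles to genotype")
    profiles = sorted(profiles, key=lambda p: p.accession_id)
    keys: dict[str, tuple] = {}
    flags: dict[str, str] = {}
    for profile in profiles:
        size_key = profile.size_key()
        keys[profile.accession_id] = (size_key,)
        flags[profile.accession_id] = ""
    if sequences is not None:
        # split size-identical groups that differ at sequence level
        by_size: dict[tuple, list[str]] = {}
        for acc, key in keys.items():
            by_size.setdefault(key, []).append(acc)
        for size_key, members in by_size.items():
            seq_keys = {
                acc: tuple(sorted(sequences.get(acc, []))) for acc in members
            }
            if len(set(seq_keys.values())) > 1:
                for acc in members:
                    keys[acc] = (size_key, seq_keys[acc])
                    flags[acc] = "SNP-discriminated"
    counts = Counter(keys.values())
    first_seen = {}
    for profile in profiles:
        first_seen.setdefault(keys[profile.accession_id], profile.accession_id)
    ordered = sorted(counts, key=lambda k: (-counts[k], first_seen[k]))
    label = {key: f"U{i + 1}" for i, key in enumerate(ordered)}
    return pd.DataFrame(
        {
            "accession_id": [p.accession_id for p in profiles],
            "genotype": [label[keys[p.accession_id]] for p in profiles],
            "flags": [flags[p.accession_id] for p in profiles],
        }
    )


# --------------------------------------------------------------------------
# tabular exports (GeneMapper-like size table, triplets, genotype calls)


def profiles_to_frame(profiles: list[MarkerProfile]) -> pd.DataFrame:
    rows = [
        {
            "accession_id": p.accession_id,
            "primer_set": name,
            "sizes": ",".join(str(s) for s in p.fragments.get(name, [])),
        }
        for p in sorted(profiles, key=lambda p: p.accession_id)
        for name in PRIMER_SET_NAMES
    ]
    return pd.DataFrame(rows)


def triplets_to_frame(profiles: list[MarkerProfile]) -> pd.DataFrame:
    rows = []
    for p in sorted(profiles, key=lambda p: p.accession_id):
        for s1, s2, s3 in p.triplets:
            rows.append(
                {
                    "accession_id": p.accession_id,
                    "LMWGS1": s1,
                    "LMWGS2": s2,
                    "LMWGS3": s3,
                }
            )
    return pd.DataFrame(rows)
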