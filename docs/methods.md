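# Methods

## The analysis

`lmwgs` re-implements, as a reusable pipeline, the characterisation of a
low-molecular-weight glutenin subunit (LMW-GS) gene family in a diploid
wheat population: fragment-based genotyping with three conserved primer
sets, gene/allelic-variant clustering and nomenclature, subunit typing and
domain annotation, pseudo-gene calling, population and geographic diversity
tabulation, and a neighbor-joining phylogeny. The pipeline runs these
stages in order (`simulate → annotate → genotype → cluster → diversity →
phylo → report`) and scores itself against the ground truth that the
synthetic generator emits alongside every sequence.

## Gene model and annotation

An LMW-GS coding sequence is modelled as an intronless CDS encoding

    signal peptide (20 aa) · N-terminal domain · repetitive domain ·
    C-terminal I · C-terminal II · C-terminal III

with eight cysteines distributed 6/1/1 over the C-terminal domains.
Subunit types follow the first mature residue: i (Ile; no N-terminal
domain), m (Met), s (Ser; the N-terminus `MENSHIPGLEKPS` loses its leading
`MEN` on maturation).

Annotation decisions that the underlying biology leaves open are fixed as
package conventions:

- **Signal cleavage.** The cleavage point is the earliest occurrence of a
  mature-start motif (`ISQ`, `MET`, `MEN`; configurable) beginning within
  residues 15–30 of the translated protein, falling back to a fixed cut
  after residue 20. Signal peptides are fixed at 20 residues in templates,
  a typical length for this family.
- **Domain boundaries by cysteine ordinals.** On the mature protein:
  repetitive = [end of N-terminal, 1st Cys), C-I = [1st Cys, 6th Cys],
  C-II = (6th, 7th], C-III = (7th, protein end]. The C-III/protein-end
  boundary (trailing residues after the 8th cysteine belong to C-III) is a
  convention of this package. With fewer than 8 cysteines the segmentation
  falls back to the available ordinals (k−2, k−1) and warns; with more, the
  canonical ordinals are kept and the surplus flagged. All coordinates are
  0-based half-open, so the five domains tile the mature protein exactly —
  an invariant the tests assert.
- **N-terminal extent.** For m/s types the N-terminal domain ends at the
  first run of four consecutive Q/P residues (the start of the repetitive
  region); absent such a run it defaults to 13 residues. i-types have a
  zero-length N-terminal domain by definition.
- **Pseudo-genes.** Translation reads through internal stops so a premature
  stop can be localised to a domain. A sequence is a pseudo-gene iff it has
  any internal stop. Stops are localised against an intact variant of the
  same gene via global protein alignment; when a gene has no intact
  variant, the pseudo-gene's own cysteine ordinals are used and the result
  is flagged `self-referenced`.
- **MW / pI.** Average (not monoisotopic) residue masses, versioned in the
  package, with one water added; pI by bisection (tolerance 0.01 pH) on a
  net-charge model using the Lehninger pKa set (N-term 9.69, C-term 2.34,
  D 3.65, E 4.25, C 8.18, Y 10.07, H 6.00, K 10.53, R 12.48). pI is used
  only for relative ordering, so the choice of published pKa set is not
  critical; a 0.001-step grid scan is the test oracle. MW and pI are
  reported for intact subunits only.

## Virtual marker genotyping

Primer binding is exact-match (forward primer and reverse-complemented
reverse primer); fragment size is the full primer-to-primer interval
including both primers; a missing or mutated site yields the sentinel `N`
(mirroring the bench assay's null alleles) and multiple binding sites are a
hard error. Mismatch-tolerant binding is deliberately not modelled: the
assay treats non-amplification as a clean category and nothing constrains a
mismatch model. Because the real primer sequences belong to the marker
system's own publication rather than to the survey re-implemented here,
primers are configuration data, and the synthetic generator embeds matching
landing sites so the system is closed.

Accessions with identical per-set size multisets share a genotype; when
sequences are available, size-identical groups that differ at sequence
level are split and flagged `SNP-discriminated` (the published panel
contains exactly one such pair). Labels `U1, U2, …` are assigned by
descending frequency, ties broken by first occurrence after sorting
accession ids, making the calls invariant to input order.

## Clustering and nomenclature

Sequences are assigned to genes by single-linkage clustering on global
(end-to-end, affine-gap) nucleotide identity, with gap columns counted in
the denominator. Single linkage is chosen deliberately: ladders of
repeat-length variants chain into one gene even when the extreme rungs fall
below the threshold pairwise. The membership threshold `t_gene = 0.95`
sits between observed within-gene identities (>0.99 up to repeat-length
indels) and cross-gene homologies (≤0.90–0.94); the source survey states no
numeric threshold, so `t_gene` is this package's parameter and is exposed
in configuration. Alignment scoring defaults to match +2, mismatch −3 and
gap cost 7 + k for a length-k gap, which favours single long motif-multiple
indels over scattered gaps.

Within a gene every distinct sequence is a variant. The gene is named
`<prefix><LMWGS1 size of its most frequent variant>`; same-size variants
get letters `a, b, c…` by descending accession frequency. Frequency ties
are broken by smaller fragment size, then lexicographic sequence id, so
names are a pure function of the input. (The published inventory itself
deviates from the majority-variant rule for two gene names; the packaged
fixture carries the published names as data, while the clustering module
implements the rule.)

## Diversity arithmetic

Percentages are rounded half-up to two decimals, matching printed-table
style. The active-gene census counts intact-ORF genes per accession by
subunit type and reports the share of accessions with all three i-type
genes active. Regional summaries count genes/variants/genotypes per
collection region, mark entities unique to a single region (checked as the
complement of presence elsewhere), and rank regions by variant then
genotype richness. "Active" status comes from ORF calls on sequences, the
in-silico counterpart of confirming expression on protein gels. The region
vocabulary is fixed to the panel's six collection areas.

## Phylogeny

Pairwise global alignments give p-distances (mismatches over compared
columns, gap columns excluded — pairwise deletion); no multiple alignment
is built, a deliberate divergence from the original ClustalW2+MEGA
toolchain that leaves the distance-based NJ analysis intact. p-distance is
the default model (the original software's distance setting is not stated);
the aligner and distance function are injectable. Neighbor-joining is
implemented in the package because determinism matters for testing: Q-ties
break on the lexicographically smallest subtree-label pair, and negative
branch estimates are clamped to zero with the deficit moved to the sibling
branch. On additive matrices NJ returns the generating tree exactly, which
is the main oracle (random trees with n ≤ 6, cross-checked against
exhaustive topology enumeration with least-squares branch fitting, and
against scikit-bio's independent implementation). p-distances may violate
the triangle inequality; NJ does not require it. Newick output carries
branch lengths at 6 decimals.

## The synthetic generator and the packaged panel

The generator back-translates protein templates through a fixed one-codon-
per-amino-acid table (versioned in the package) so amplicon sizes are
reproducible, then layers on variation: per-site substitutions, in-frame
motif-multiple indels (default unit 24 bp) restricted to the repetitive
domain at codon boundaries, and premature stops written at codon boundaries
inside a named domain — conventions that keep the truth labels (domain
coordinates, stop domain) well defined after mutation. ORF truth is
re-derived from the final sequence, so stops created incidentally by
substitutions are recorded truthfully. One top-level seed drives
everything; per-sequence generators are spawned via `numpy.random.
SeedSequence` with a global sequence counter as spawn key.

The packaged reference panel encodes the published inventory of a
157-accession *T. urartu* collection: 8 genes (4 m, 1 s, 3 i), 39 variants,
15 genotypes (U1–U15) over six regions, with per-variant active/pseudo
flags and documented stop domains. Panel-level construction choices:

- **Fragment sizes are theoretical, labels nominal.** Published sizes are
  capillary-electrophoresis estimates (within-gene deltas of 1–2 bp cannot
  be in-frame coding indels), so the synthetic panel assigns each distinct
  nominal size its own rung on a 24-bp repeat ladder and derives exact
  amplicon sizes from the sequences. All population arithmetic depends only
  on the combinatorial structure, which is preserved exactly; a build-time
  check asserts the size ladder is collision-free across the panel.
- **Identity structure.** The eight gene templates share conserved primer
  anchors (signal peptide and three C-terminal blocks) and diverge
  elsewhere by seeded substitution: within-type paralogs sit near 85–90%
  nucleotide identity, types further apart, same-gene variants above 0.95
  to their nearest ladder neighbour — reproducing the identity regime the
  clustering threshold assumes, which the tests verify empirically.
- **Same-size variants** differ by silent third-position tags in C-terminal
  I, so they are invisible to fragment sizing but split by sequence-level
  genotyping — reproducing the published size-ambiguous genotype pair.
- Cross-primer correspondence triplets are emitted self-consistently by the
  generator (the published triplet table is typographically corrupted in
  the source; only the LMWGS1-based names are encoded as data).

What the generator does **not** emulate: electropherogram signal
intensities, PCR artefacts/stutter, mismatch-tolerant primer binding,
within-gene recombination, real codon usage heterogeneity, and real
sequence content (the deposited GenBank sequences are deliberately not
required). Passing tests therefore demonstrate the correctness of the
pipeline's logic and arithmetic on family-shaped data, not sequence-level
agreement with the real genes; in particular the molecular weights and pI
values of the synthetic subunits are realistic in ordering (i-types heavier
than m-types) but not in absolute value.

## Problem sizes

The packaged panel (157 accessions, 975 sequences, 39 unique variants)
runs end to end in well under a minute on one CPU; clustering and the
distance matrix each need ~750 pairwise alignments of ~1 kb. Property
suites use 1,000 synthetic subunits for the domain/cysteine invariants,
random trees with n ≤ 6 against exhaustive topology enumeration (up to 105
topologies) for NJ, and ≥20 input shuffles for clustering order
invariance.

## Known limitations

- Exact-match primer binding means a single SNP in a landing site silently
  converts a fragment to `N`; real assays are more tolerant.
- Gene naming needs an integer fragment size; sequences that fail to
  amplify fall back to their full length as "theoretical size".
- `t_gene` is a fixed global threshold; families whose paralogs are more
  similar than 0.95 would need it raised (it is a config field).
- The self-referenced stop localisation is only as good as the pseudo-gene
  sequence's own cysteine scaffold; heavily degraded copies may be
  assigned a neighbouring domain.
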