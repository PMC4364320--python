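# lmwgs

Analysis toolkit for **low-molecular-weight glutenin subunit (LMW-GS) gene
families** in diploid wheat populations.

LMW-GS proteins are seed-storage prolamins that largely determine the
bread-making quality of wheat flour. They are encoded by a multigene family
at the *Glu-3* loci whose members are hard to tell apart: paralogous genes
share 90%+ identity, and allelic variants of one gene differ only by SNPs
and by the length of a glutamine/proline-rich repetitive domain. The
practical workflow for dissecting such a family in a germplasm panel is:

1. **fragment genotyping** — amplify all family members with three
   conserved primer sets (LMWGS1/2/3) and read fragment sizes; an
   accession's size multiset is its multilocus genotype;
2. **clustering & nomenclature** — group cloned sequences into genes
   (high identity, repeat-length polymorphism allowed) and named allelic
   variants (`TuA3-502a` = prefix + LMWGS1 fragment size + frequency
   letter);
3. **annotation** — subunit type from the first mature residue
   (i = Ile, m = Met, s = Ser with the `MEN` tripeptide cleaved from
   `MENSHIPGLEKPS`), domain segmentation by the canonical 8 cysteines
   (6/1/1 over C-terminal I/II/III), pseudo-gene calls from premature
   stops, molecular weight and pI;
4. **diversity tabulation** — genotype frequencies, the share of
   accessions with all three i-type genes active, regional richness and
   uniqueness (center-of-diversity ranking);
5. **phylogeny** — pairwise p-distances and a neighbor-joining tree with
   clade (monophyly) checks.

This package implements all five stages as a library plus a thin `lmwgs`
command-line tool, together with a **synthetic-data generator** that emits
family-shaped genes and whole populations with full truth labels, and a
**packaged fixture** encoding the published inventory of a 157-accession
*Triticum urartu* panel (8 genes, 39 variants, 15 genotypes U1–U15 over six
Fertile Crescent regions). Every downstream stage is therefore testable
end to end without downloading anything.

At the core are a few well-defined procedures, in standard notation:

- global identity `I(a,b) = matches / alignment columns` (affine gaps,
  gap columns in the denominator); genes are single-linkage clusters at
  `I ≥ 0.95`;
- p-distance `p = mismatches / compared columns` (pairwise deletion);
- neighbor joining on `D = (p_ij)`: join the pair minimising
  `Q(i,j) = (n−2) d_ij − r_i − r_j`, with branch lengths
  `l_i = d_ij/2 + (r_i − r_j)/(2(n−2))`; exact on additive matrices;
- protein mass `MW = Σ residue masses + H₂O` (average masses), pI by
  bisection on the Henderson–Hasselbalch net charge.

See `docs/methods.md` for the full model, conventions and limitations.

## Worked example

Run the whole pipeline on the packaged reference panel:

```bash
cat > config.yaml <<EOF
out_dir: example-out
seed: 1
EOF
lmwgs run -c config.yaml
```

which prints

```
8 genes, 39 variants, 15 genotypes across 157 accessions; report in example-out/report.json
```

i.e. the marker genotyper resolves the panel into 15 genotypes (one pair of
genotypes has identical fragment sizes and is split only at sequence level,
flagged `SNP-discriminated`), and clustering recovers 8 genes carrying 39
allelic variants. `example-out/genotype_summary.tsv` starts

```
genotype  n_accessions  share_pct
U1        39            24.84
U2        35            22.29
U3        21            13.38
U4        16            10.19
```

the most abundant genotype covers 39 accessions (24.84% of 157) and the
runner-up 35 (22.29%). `region_summary.tsv` ranks Southeastern Turkey
first — all 8 genes, 34 of 39 variants, 13 of 15 genotypes, 10 variants and
7 genotypes found nowhere else — which is why it reads as the panel's
center of diversity. `report.json` additionally records that every gene's
variants form a clade in the NJ tree, that the i-type genes separate from
the m/s clade, that 61.78% of accessions carry three active i-type genes,
and a truth-recovery block confirming the zero-mutation run reproduces the
generator's ground truth exactly.

Other subcommands (`simulate`, `annotate`, `genotype`, `cluster`,
`diversity`, `phylo`, `fixture`) expose the individual stages; the library
API (`lmwgs.annotate_gene`, `lmwgs.cluster_variants`,
`lmwgs.neighbor_joining`, …) is the same machinery.

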