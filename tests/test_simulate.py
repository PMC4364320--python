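"""Synthetic generator: templates, mutation model, population assembly."""

import dataclasses

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lmwgs import reference
from lmwgs.annotate import MATURE_DOMAINS, annotate_gene, find_orf
from lmwgs.errors import ConfigError, ValidationError
from lmwgs.simulate import (
    MutationSpec,
    apply_mutations,
    gene_truth,
    make_gene,
    make_population,
    refresh_orf_truth,
)


@pytest.fixture(scope="module")
def templates():
    return reference.reference_templates()


def null_mutations(seed=0):
    return MutationSpec(seed=seed)


class TestGeneTemplate:
    def test_wrong_cysteine_count_rejected_naming_domain(self, templates):
        t = templates["TuA3-502"]
        broken = dataclasses.replace(t, cterm2=t.cterm2.replace("C", "S"))
        with pytest.raises(ValidationError, match="cterm2"):
            broken.validate()

    def test_itype_template_must_start_with_ile(self, templates):
        t = templates["TuA3-502"]
        bad = dataclasses.replace(t, repeat_motifs=("QSQQQQ",) + t.repeat_motifs[1:])
        with pytest.raises(ValidationError, match="Ile"):
            bad.validate()

    def test_truth_domains_tile_mature_protein(self, templates):
        for t in templates.values():
            domains = t.domain_map()
            spans = [domains[name] for name in MATURE_DOMAINS]
            assert spans[0][0] == 0
            for (_, hi), (lo, _) in zip(spans, spans[1:]):
                assert hi == lo
            mature_len = len(t.protein) - t.mature_start
            assert spans[-1][1] == mature_len


class TestMakeGene:
    def test_unmutated_itype_lacks_nterm_and_starts_ile(self, templates):
        dna, truth = make_gene(templates["TuA3-538"], null_mutations())
        annotation = annotate_gene(dna)
        assert annotation.subunit_type == "i"
        assert annotation.mature.startswith("I")
        lo, hi = annotation.domains["N-terminal"]
        assert hi - lo == 0
        assert truth.orf_status == "active"

    def test_zero_mutation_gives_active_orf_without_stops(self, templates):
        for t in templates.values():
            dna, truth = make_gene(t, null_mutations())
            _, stops = find_orf(dna)
            assert stops == []
            assert truth.orf_status == "active"

    def test_forced_stop_in_repeat_region_is_pseudo_repetitive(self, templates):
        t = templates["TuA3-385"]  # m-type
        spec = MutationSpec(premature_stop_probability=1.0, seed=5)
        dna, truth = make_gene(t, spec)
        assert truth.orf_status == "pseudo"
        assert truth.stop_domain == "repetitive"

    def test_same_seed_same_output(self, templates):
        spec = MutationSpec(snp_rate=0.01, indel_rate=1.0, seed=42)
        out1 = make_gene(templates["TuA3-576"], spec, sequence_index=3)
        out2 = make_gene(templates["TuA3-576"], spec, sequence_index=3)
        assert out1[0] == out2[0]
        assert out1[1].domains == out2[1].domains

    def test_indels_shift_domains_by_whole_units(self, templates):
        t = templates["TuA3-502"]
        base_len = t.domain_map()["repetitive"][1] - t.domain_map()["repetitive"][0]
        spec = MutationSpec(indel_rate=2.0, indel_unit=24, seed=7)
        for idx in range(8):
            dna, truth = make_gene(t, spec, sequence_index=idx)
            lo, hi = truth.domains["repetitive"]
            assert (hi - lo - base_len) % 8 == 0  # 24 bp = 8 residues
            spans = [truth.domains[name] for name in MATURE_DOMAINS]
            for (_, h), (l, _) in zip(spans, spans[1:]):
                assert h == l
            assert len(dna) % 3 == 0

    def test_invalid_mutation_rates_rejected(self):
        with pytest.raises(ValidationError):
            MutationSpec(snp_rate=1.5).validate()
        with pytest.raises(ValidationError):
            MutationSpec(indel_unit=10).validate()


class TestMakePopulation:
    def test_reference_panel_has_157_accessions(self, ref_population):
        assert len(ref_population.accessions) == 157
        assert ref_population.metadata_frame().shape[0] == 157

    def test_each_accession_carries_six_or_seven_genes(self, ref_population):
        sizes = {len(a.sequences) for a in ref_population.accessions}
        assert sizes == {6, 7}

    def test_zero_mutation_accession_matches_genotype_definition(
        self, ref_population
    ):
        variants = reference.variant_sequences()
        acc = next(
            a for a in ref_population.accessions if a.accession_id == "PI428198"
        )
        assert acc.genotype == "U14"
        expected = sorted(
            variants[vid] for vid in reference.GENOTYPE_DEFS["U14"]
        )
        assert sorted(acc.sequences.values()) == expected

    def test_same_seed_byte_identical_population(self):
        config = reference.reference_population_config()
        config = dataclasses.replace(
            config,
            genotype_defs={"G1": reference.GENOTYPE_DEFS["U6"]},
            region_counts={"G1": {"Syria": 2}},
            named_accessions={},
        )
        spec = MutationSpec(snp_rate=0.003, seed=11)
        pop1 = make_population(config, spec)
        pop2 = make_population(config, spec)
        assert pop1.all_sequences() == pop2.all_sequences()

    def test_undefined_variant_in_genotype_rejected(self):
        config = reference.reference_population_config()
        config.genotype_defs = {"G1": ("TuA3-999",)}
        config.region_counts = {"G1": {"Syria": 1}}
        config.named_accessions = {}
        with pytest.raises(ConfigError, match="TuA3-999"):
            make_population(config, MutationSpec())

    def test_truth_one_row_per_sequence(self, ref_population):
        n_seq = sum(len(a.sequences) for a in ref_population.accessions)
        assert len(ref_population.truth) == n_seq
        ids = {t.sequence_id for t in ref_population.truth}
        assert len(ids) == n_seq

    def test_genotype_table_layout_matches_population(
        self, ref_population, ref_genotype_table
    ):
        got = ref_population.genotype_frame()
        want = ref_genotype_table[["accession_id", "region", "genotype"]]
        assert got.reset_index(drop=True).equals(want.reset_index(drop=True))


class TestReferenceFixture:
    def test_fixture_counts(self):
        catalog, table, region_counts = reference.reference_fixture()
        assert len(table["genotype"].unique()) == 15
        assert catalog.n_variants == 39
        assert catalog.n_genes == 8
        total = sum(n for c in region_counts.values() for n in c.values())
        assert total == 157

    def test_region_totals_match_collection(self, ref_genotype_table):
        totals = ref_genotype_table["region"].value_counts().to_dict()
        assert totals == {
            "Northeastern Lebanon": 82,
            "Southeastern Turkey": 63,
            "Armenia": 5,
            "Syria": 5,
            "Iraq": 1,
            "Iran": 1,
        }

    def test_active_flags_are_consistent_with_truth(self, ref_population):
        truth_by_variant = {}
        for t in ref_population.truth:
            truth_by_variant[t.variant_id] = t.orf_status
        for vid, status in truth_by_variant.items():
            expected = "active" if vid in reference.ACTIVE_VARIANTS else "pseudo"
            assert status == expected, vid


@settings(max_examples=30, derandomize=True, deadline=None)
@given(
    st.sampled_from(list(reference.GENE_TYPES)),
    st.integers(min_value=4, max_value=40),
    st.integers(min_value=0, max_value=2**20),
)
def test_truth_stays_consistent_under_mutation(gene, repeats, seed):
    """Property: post-mutation truth domains tile and ORF status is real."""
    import numpy as np

    template = dataclasses.replace(
        reference.reference_templates()[gene], repeat_count=repeats
    )
    dna = template.encode()
    truth = gene_truth(template)
    spec = MutationSpec(
        snp_rate=0.003, indel_rate=1.0, premature_stop_probability=0.3,
        seed=seed,
    )
    rng = np.random.default_rng(seed)
    mutated, truth = apply_mutations(dna, truth, spec, rng)
    spans = [truth.domains[name] for name in MATURE_DOMAINS]
    for (_, hi), (lo, _) in zip(spans, spans[1:]):
        assert hi == lo
    if mutated.startswith("ATG"):  # else find_orf would use a later frame
        protein, stops = find_orf(mutated)
        assert (truth.orf_status == "pseudo") == bool(stops)
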