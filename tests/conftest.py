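"""Shared fixtures: the reference panel is built once per session."""

import pytest

from lmwgs import reference
from lmwgs.catalog import SequenceEntry, cluster_variants
from lmwgs.marker import build_profile, call_genotypes


@pytest.fixture(scope="session")
def ref_population():
    """The 157-accession panel, zero mutation (exact truth)."""
    return reference.reference_population(0)


@pytest.fixture(scope="session")
def ref_primer_sets():
    return reference.reference_primer_sets()


@pytest.fixture(scope="session")
def ref_profiles(ref_population, ref_primer_sets):
    return [
        build_profile(a.accession_id, a.sequences, ref_primer_sets)
        for a in ref_population.accessions
    ]


@pytest.fixture(scope="session")
def ref_calls(ref_population, ref_profiles):
    """Genotype calls with sequence-level disambiguation enabled."""
    return call_genotypes(ref_profiles, ref_population.sequences_by_accession())


@pytest.fixture(scope="session")
def ref_genotype_table():
    return reference.reference_genotype_table()


@pytest.fixture(scope="session")
def ref_variant_entries(ref_genotype_table):
    """The 39 variant sequences with published accession supports."""
    variants = reference.reference_variants()
    support = {vid: 0 for vid in reference.VARIANT_GENE}
    for row in ref_genotype_table.itertuples(index=False):
        for vid in row.variants:
            support[vid] += 1
    return [
        SequenceEntry(
            sequence_id=vid,
            dna=dna,
            accession_count=support[vid],
            lmwgs1_size=truth.amplicons["LMWGS1"],
        )
        for vid, (dna, truth) in variants.items()
    ]


@pytest.fixture(scope="session")
def ref_catalog(ref_variant_entries):
    """Clustered catalog of the 39 reference variants (~40 alignments/gene)."""
    return cluster_variants(ref_variant_entries)


@pytest.fixture(scope="session")
def pipeline_run(tmp_path_factory):
    """One full zero-mutation pipeline run on the reference panel."""
    from lmwgs.workflow import PipelineConfig, run_pipeline

    outdir = tmp_path_factory.mktemp("pipeline")
    config = PipelineConfig(out_dir=str(outdir), seed=0)
    report = run_pipeline(config)
    return outdir, report
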