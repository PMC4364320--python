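"""Annotation: ORF finding, typing, domain segmentation, MW and pI."""

import numpy as np
import pytest
from Bio.SeqUtils import molecular_weight as bp_molecular_weight
from hypothesis import given, settings
from hypothesis import strategies as st

from lmwgs import reference
from lmwgs.annotate import (
    MATURE_DOMAINS,
    RESIDUE_MASS,
    WATER_MASS,
    AtypicalCysteineWarning,
    annotate_gene,
    cleave_and_type,
    find_orf,
    isoelectric_point,
    localize_stop,
    molecular_weight,
    segment_domains,
    _net_charge,
)
from lmwgs.errors import AnnotationError, InputError


class TestFindOrf:
    def test_simple_orf_with_terminal_stop(self):
        protein, stops = find_orf("ATGGGTTGA")
        assert protein == "MG"
        assert stops == []

    def test_internal_stop_read_through(self):
        protein, stops = find_orf("ATGTAGGGTTGA")
        assert protein == "M*G"
        assert stops == [1]

    def test_leading_untranslated_bases_before_atg(self):
        protein, _ = find_orf("CCATGGGTTGA")
        assert protein.startswith("MG")

    def test_no_atg_is_an_error(self):
        with pytest.raises(AnnotationError, match="no ORF"):
            find_orf("CCCGGGTTT")

    def test_non_iupac_character_is_an_input_error(self):
        with pytest.raises(InputError, match="position 3"):
            find_orf("ATGZGG")

    def test_zero_mutation_synthetic_genes_have_no_internal_stops(self):
        for vid in ("TuA3-502a", "TuA3-538a", "TuA3-397b"):
            dna = reference.variant_sequences()[vid]
            _, stops = find_orf(dna)
            assert stops == []


class TestCleaveAndType:
    @pytest.mark.parametrize(
        "gene, expected_type, mature_prefix",
        [
            ("TuA3-460", "s", "SHIPGLEKPS"),
            ("TuA3-502", "i", "ISQ"),
            ("TuA3-385", "m", "MET"),
        ],
    )
    def test_type_from_mature_start(self, gene, expected_type, mature_prefix):
        template = reference.reference_templates()[gene]
        mature, subunit_type, _ = cleave_and_type(template.protein)
        assert subunit_type == expected_type
        assert mature.startswith(mature_prefix)

    def test_men_tripeptide_is_cleaved_from_s_type(self):
        template = reference.reference_templates()["TuA3-460"]
        mature, _, mature_start = cleave_and_type(template.protein)
        assert mature_start == 23  # 20-residue signal + MEN
        assert not mature.startswith("MEN")

    def test_short_protein_rejected(self):
        with pytest.raises(AnnotationError):
            cleave_and_type("MKT")


class TestSegmentDomains:
    def test_canonical_cysteine_census(self):
        for gene, template in reference.reference_templates().items():
            mature, subunit_type, _ = cleave_and_type(template.protein)
            domains, per_domain, flags = segment_domains(mature, subunit_type)
            assert per_domain["C-terminal I"] == 6
            assert per_domain["C-terminal II"] == 1
            assert per_domain["C-terminal III"] == 1
            assert flags == []

    def test_itype_has_empty_nterminal_domain(self):
        template = reference.reference_templates()["TuA3-576"]
        mature, subunit_type, _ = cleave_and_type(template.protein)
        domains, _, _ = segment_domains(mature, subunit_type)
        lo, hi = domains["N-terminal"]
        assert hi - lo == 0

    def test_domain_tiling(self):
        for template in reference.reference_templates().values():
            annotation = annotate_gene(template.encode())
            spans = [annotation.domains[name] for name in MATURE_DOMAINS]
            assert spans[0][0] == 0
            for (_, hi), (lo, _) in zip(spans, spans[1:]):
                assert hi == lo
            assert spans[-1][1] == annotation.mature_length

    def test_atypical_cysteine_count_warns_and_falls_back(self):
        template = reference.reference_templates()["TuA3-385"]
        mature, subunit_type, _ = cleave_and_type(template.protein)
        crippled = mature.replace("C", "S", 3)  # 5 cysteines left
        with pytest.warns(AtypicalCysteineWarning):
            domains, per_domain, flags = segment_domains(crippled, subunit_type)
        assert "atypical-cysteines:5" in flags
        assert sum(per_domain.values()) == 5


class TestLocalizeStop:
    def test_stop_against_active_reference(self, ref_population):
        seqs = reference.variant_sequences()
        ref_ann = annotate_gene(seqs["TuA3-502a"])
        for vid, expected in [
            ("TuA3-502b", "repetitive"),
            ("TuA3-502d", "repetitive"),
        ]:
            pseudo = annotate_gene(seqs[vid])
            domain, flag = localize_stop(
                pseudo.protein, ref_ann.protein, ref_ann
            )
            assert domain == expected
            assert flag is None

    def test_cterminal_ii_stop(self):
        seqs = reference.variant_sequences()
        ref_ann = annotate_gene(seqs["TuA3-576a"])
        pseudo = annotate_gene(seqs["TuA3-576d"])
        domain, _ = localize_stop(pseudo.protein, ref_ann.protein, ref_ann)
        assert domain == "C-terminal II"

    def test_stop_in_signal_region(self):
        template = reference.reference_templates()["TuA3-385"]
        ref_ann = annotate_gene(template.encode())
        protein = list(template.protein)
        protein[5] = "*"
        domain, _ = localize_stop("".join(protein), template.protein, ref_ann)
        assert domain == "signal"

    def test_self_referenced_fallback_without_active_variant(self):
        seqs = reference.variant_sequences()
        pseudo = annotate_gene(seqs["TuA3-460"])  # gene with no active variant
        domain, flag = localize_stop(pseudo.protein)
        assert domain == "repetitive"
        assert flag == "self-referenced"

    def test_no_stop_is_an_error(self):
        with pytest.raises(AnnotationError):
            localize_stop("MKTVLQ")


class TestMolecularWeight:
    def test_empty_protein_is_one_water(self):
        assert molecular_weight("") == pytest.approx(18.02, abs=0.01)

    def test_single_glycine(self):
        assert molecular_weight("G") == pytest.approx(75.07, abs=0.01)

    def test_acde_hand_sum(self):
        expected = (
            RESIDUE_MASS["A"] + RESIDUE_MASS["C"] + RESIDUE_MASS["D"]
            + RESIDUE_MASS["E"] + WATER_MASS
        )
        assert molecular_weight("ACDE") == pytest.approx(expected, abs=1e-9)
        assert expected == pytest.approx(436.44, abs=0.01)

    def test_unknown_residue_names_position(self):
        with pytest.raises(InputError, match="position 2"):
            molecular_weight("GGZG")

    def test_agrees_with_biopython_on_real_subunits(self):
        for vid in ("TuA3-502a", "TuA3-397b"):
            mature = annotate_gene(reference.variant_sequences()[vid]).mature
            assert molecular_weight(mature) == pytest.approx(
                bp_molecular_weight(mature, seq_type="protein"), rel=1e-3
            )

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(
        st.text(alphabet=sorted(RESIDUE_MASS), max_size=30),
        st.text(alphabet=sorted(RESIDUE_MASS), max_size=30),
    )
    def test_additivity(self, a, b):
        assert molecular_weight(a + b) == pytest.approx(
            molecular_weight(a) + molecular_weight(b) - WATER_MASS, abs=1e-6
        )


class TestIsoelectricPoint:
    def test_basic_residue_above_acidic_residue(self):
        assert isoelectric_point("K") > isoelectric_point("D")

    def test_bisection_bracket_is_valid(self):
        for protein in ("K", "D", "QQPPFSQQ", "MKTFLVF"):
            assert _net_charge(protein, 0.0) > 0
            assert _net_charge(protein, 14.0) < 0

    def test_matches_fine_grid_scan(self):
        proteins = [
            "KDEHRY",
            "QQPPFSQQQQPPFSQQ",
            annotate_gene(reference.variant_sequences()["TuA3-502a"]).mature,
        ]
        for protein in proteins:
            grid = np.arange(0.0, 14.0, 0.001)
            charges = np.array([_net_charge(protein, ph) for ph in grid])
            crossing = grid[np.argmax(charges < 0)]
            assert isoelectric_point(protein) == pytest.approx(
                crossing, abs=0.02
            )


class TestAnnotateGene:
    def test_pseudo_iff_internal_stop(self):
        seqs = reference.variant_sequences()
        for vid, dna in seqs.items():
            annotation = annotate_gene(dna)
            assert (annotation.orf_status == "pseudo") == bool(
                annotation.internal_stop_positions
            )
            if annotation.orf_status == "active":
                assert annotation.mw_da is not None
                assert annotation.pi is not None
            else:
                assert annotation.mw_da is None

    def test_itype_subunits_heavier_than_m_type(self):
        seqs = reference.variant_sequences()
        mw_i = annotate_gene(seqs["TuA3-502a"]).mw_da
        mw_m = annotate_gene(seqs["TuA3-397b"]).mw_da
        assert mw_i > mw_m
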