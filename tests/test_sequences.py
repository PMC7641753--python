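"""Conjugate design: reverse complements, hybridization, bulge arithmetic,
site classification."""

import warnings

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from poc import sequences as sq
from poc.sequences import (
    AmbiguousPlacementError,
    ConjugateDesign,
    NucleotideSequence,
    PlacementError,
    SequenceError,
    SiteLabel,
    SiteValidationError,
)


def seq(text, alphabet="DNA"):
    return NucleotideSequence.from_str(text, alphabet)


class TestNucleotideSequence:
    def test_tokenizes_modified_adenosine_and_separators(self):
        s = seq("TGGTGCGAATT-A*-GTGGATCGAA")
        assert len(s) == 22
        assert s.tokens.count("A*") == 1

    @pytest.mark.parametrize(
        "text,alphabet",
        [("", "DNA"), ("ACGU", "DNA"), ("ACGT", "RNA"), ("AXXA", "DNA"), ("ACB", "DNA")],
    )
    def test_rejects_invalid_sequences(self, text, alphabet):
        with pytest.raises(SequenceError):
            seq(text, alphabet)


class TestReverseComplement:
    @pytest.mark.parametrize(
        "dna,rna",
        [("GATCGAA", "UUCGAUC"), ("TGGTGCGAATT", "AAUUCGCACCA")],
    )
    def test_arm_complements(self, dna, rna):
        assert str(sq.reverse_complement(seq(dna), "RNA")) == rna

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.text(alphabet="ACGT", min_size=1, max_size=40))
    def test_involution_on_dna(self, text):
        s = seq(text)
        assert sq.reverse_complement(sq.reverse_complement(s, "DNA"), "DNA") == s

    def test_modified_adenosine_maps_as_a(self):
        assert str(sq.reverse_complement(seq("A*T"), "RNA")) == "AU"

    def test_abasic_rejected(self):
        with pytest.raises(SequenceError):
            sq.reverse_complement(seq("AXT"), "RNA")


class TestHybridize:
    def test_bc5_bulge_is_the_five_nt_target_region(self, bc5_complex):
        assert sq.bulge_size(bc5_complex) == 5
        study = [bc5_complex.local_to_study(p) for p in bc5_complex.bulge]
        assert study == [61, 62, 63, 64, 65]
        bases = "".join(bc5_complex.target[p - 1] for p in bc5_complex.bulge)
        assert bases == "CACAG"

    def test_bc2_bulge_is_a64_g65(self, bc2_complex):
        assert sq.bulge_size(bc2_complex) == 2
        study = [bc2_complex.local_to_study(p) for p in bc2_complex.bulge]
        assert study == [64, 65]

    def test_truncation_family_bulge_grows_one_per_truncated_base(self, designs, local_target):
        for k, name in enumerate(["BC2", "BC3", "BC4", "BC5"]):
            cx = sq.hybridize(designs[name], local_target)
            assert sq.bulge_size(cx) == 2 + k

    def test_fully_complementary_design_gives_zero_bulge(self, local_target):
        d = ConjugateDesign(
            name="full",
            arm5=seq("TGGTGCGAATT"),
            arm3=seq("CTGTGGATCGAA"),
            attachment="abasic_beta",
            peptide="p",
            peptide_length_A=36.5,
            linker_length_A=8.6,
        )
        assert sq.bulge_size(sq.hybridize(d, local_target)) == 0

    def test_pairing_is_antiparallel_bijection(self, bc5_complex):
        conj = [c for c, _ in bc5_complex.pairs]
        targ = [t for _, t in bc5_complex.pairs]
        assert len(set(conj)) == len(conj) and len(set(targ)) == len(targ)
        ordered = sorted(bc5_complex.pairs)
        assert all(t0 > t1 for (_, t0), (_, t1) in zip(ordered, ordered[1:]))

    def test_missing_arm_placement_raises(self, designs):
        other = seq("AAAAAAAAAAAAAAAAAAAAAAAA", "RNA")
        with pytest.raises(PlacementError):
            sq.hybridize(designs["BC5"], other)

    def test_ambiguous_placement_lists_candidates(self, designs):
        # two copies of the arm3 complement
        t = seq("UUCGAUCUUCGAUCCACAGAAUUCGCACCA", "RNA")
        with pytest.raises(AmbiguousPlacementError) as exc:
            sq.hybridize(designs["BC5"], t)
        assert len(exc.value.candidates) == 2

    def test_modified_adenosine_pairs_opposite_single_u(self):
        d = ConjugateDesign(
            name="astar",
            arm5=seq("GGGG"),
            arm3=seq("CCCC"),
            attachment="modified_adenosine",
            peptide="p",
            peptide_length_A=36.5,
            linker_length_A=8.6,
        )
        # GGGG-A*-CCCC against 3'...CCCC-U-GGGG...5' read 5'->3': GGGGUCCCC
        cx = sq.hybridize(d, seq("GGGGUCCCC", "RNA"))
        assert sq.bulge_size(cx) == 0
        assert len(cx.pairs) == 9

    def test_modified_adenosine_opposite_non_u_warns_and_stays_unpaired(self):
        d = ConjugateDesign(
            name="astar",
            arm5=seq("GGGG"),
            arm3=seq("CCCC"),
            attachment="modified_adenosine",
            peptide="p",
            peptide_length_A=36.5,
            linker_length_A=8.6,
        )
        with pytest.warns(UserWarning, match="unpaired"):
            cx = sq.hybridize(d, seq("GGGGACCCC", "RNA"))
        assert sq.bulge_size(cx) == 1


class TestMotifLength:
    @pytest.mark.parametrize(
        "name,expected",
        [("BC5", 19), ("BC4", 20), ("BC3", 21), ("BC2", 22),
         ("BC2-a", 26), ("BC5-b", 23), ("BC5L-a", 26)],
    )
    def test_mer_counting_convention(self, designs, name, expected):
        assert sq.motif_length(designs[name]) == expected


class TestClassifySite:
    def test_major_cleavage_site_in_bc5_bulge(self, bc5_complex):
        assert sq.classify_site(SiteLabel.from_str("C63-A64"), bc5_complex) == "bulge"

    def test_bc2_single_cut_site_is_a_junction(self, bc2_complex):
        assert sq.classify_site(SiteLabel.from_str("G65-A66"), bc2_complex) == "junction"

    def test_site_inside_arm_footprint_is_duplex(self, bc5_complex):
        assert sq.classify_site(SiteLabel.from_str("U54-U55"), bc5_complex) == "duplex"

    def test_base_letter_mismatch_rejected(self, bc5_complex):
        with pytest.raises(SiteValidationError):
            sq.classify_site(SiteLabel.from_str("G63-A64"), bc5_complex)

    def test_region_map_partitions_every_linkage(self, bc5_complex, bc2_complex):
        for cx in (bc5_complex, bc2_complex):
            regions = sq.region_map(cx)
            assert len(regions) == len(cx.target) - 1
            assert set(regions.values()) <= {"bulge", "duplex", "junction", "dangling", "outside"}


class TestIO:
    def test_fasta_reading_normalizes_t_with_warning(self, tmp_path):
        p = tmp_path / "t.fasta"
        p.write_text(">x\nACGTACGU\n")
        with pytest.warns(UserWarning, match="normalized"):
            s = sq.read_target_fasta(p)
        assert str(s) == "ACGUACGU"

    def test_packaged_table_has_the_full_library(self, designs):
        assert len(designs) == 14
        assert {d.attachment for d in designs.values()} == {
            "modified_adenosine", "abasic_alpha", "abasic_beta"
        }

    def test_hybrid_report_roundtrips_to_json(self, bc5_complex, tmp_path):
        import json

        out = tmp_path / "report.json"
        sq.write_hybrid_report([bc5_complex], out)
        data = json.loads(out.read_text())
        assert data[0]["bulge_size"] == 5
        assert data[0]["bulge_study"] == [61, 62, 63, 64, 65]
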