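"""Library model: digestion, loading, theoretical enumeration, truth labels."""

import pytest
from hypothesis import HealthCheck, given, settings
from hypothesis import strategies as st

from oracles import brute_label, brute_pair_count_grouped, brute_pair_count_pooled
from xlfdr.library import (
    InvalidConstructError,
    LibraryError,
    LibraryPeptide,
    PeptideLibrary,
    SynthesisConstruct,
    classify_pair,
    digest_construct,
    enumerate_theoretical,
    load_library,
    near_isobaric_pairs,
)
from xlfdr.synthetic import SimulationConfig, generate_library


class TestDigestConstruct:
    @pytest.mark.parametrize(
        "construct, expected",
        [
            (SynthesisConstruct(core="MAKTIK", n_tag="acetyl-WGGGGR", azide_k=True),
             "MAKTIK"),
            (SynthesisConstruct(core="VAVIKAVR"), "VAVIKAVR"),
            (SynthesisConstruct(core="APDLK", n_tag="acetyl-WGGGGR",
                                c_tag="GGGG-amide"), "APDLK"),
        ],
    )
    def test_tryptic_release(self, construct, expected):
        """Tags are stripped and azide-K reduces to plain K."""
        assert digest_construct(construct) == expected

    def test_n_tag_without_tryptic_site_rejected(self):
        with pytest.raises(InvalidConstructError):
            digest_construct(SynthesisConstruct(core="MAKTIK", n_tag="acetyl-WGGGG"))

    def test_empty_core_rejected(self):
        with pytest.raises(InvalidConstructError):
            digest_construct(SynthesisConstruct(core=""))


class TestLibraryInvariants:
    def test_exactly_one_reactive_residue_enforced(self):
        # two non-terminal lysines
        with pytest.raises(LibraryError):
            LibraryPeptide("AKAKAR", "G1", "P1", 1, 2)

    def test_terminal_lysine_not_counted_as_site(self):
        # MAKTIK: internal K3 is the site, tryptic C-terminal K is exempt
        p = LibraryPeptide("MAKTIK", "G1", "P1", 10, 3)
        assert p.protein_site == 12

    def test_acidic_chemistry_site(self):
        p = LibraryPeptide("AGDLTK", "G1", "P1", 1, 3, chemistry="acidic")
        assert p.sequence[p.site_pos - 1] == "D"

    def test_sequence_in_two_groups_rejected(self):
        with pytest.raises(LibraryError, match="two groups"):
            PeptideLibrary("x", [
                LibraryPeptide("GAKWR", "G1", "P1", 1, 3),
                LibraryPeptide("GAKWR", "G2", "P1", 1, 3),
            ])


class TestLoadLibrary:
    def test_parses_rows_and_groups(self, tmp_path):
        f = tmp_path / "lib.csv"
        f.write_text(
            "sequence,group,protein,start,site,chemistry\n"
            "MAKTIK,G1,P1,10,3,lysine\n"
            "GAKWR,G2,P1,7,3,lysine\n"
            "APKTLR,G2,P4,1,3,lysine\n"
        )
        lib = load_library(f)
        assert len(lib) == 3
        assert set(lib.groups) == {"G1", "G2"}

    def test_missing_column_named_in_error(self, tmp_path):
        f = tmp_path / "lib.csv"
        f.write_text("sequence,protein,start,site\nMAKTIK,P1,10,3\n")
        with pytest.raises(LibraryError, match="group"):
            load_library(f)

    def test_two_internal_lysines_rejected(self, tmp_path):
        f = tmp_path / "lib.csv"
        f.write_text("sequence,group,protein,start,site\nAKAKAR,G1,P1,1,2\n")
        with pytest.raises(LibraryError):
            load_library(f)

    def test_duplicate_rows_collapse(self, tmp_path):
        f = tmp_path / "lib.csv"
        f.write_text(
            "sequence,group,protein,start,site\n"
            "GAKWR,G1,P1,7,3\nGAKWR,G1,P1,7,3\n"
        )
        assert len(load_library(f)) == 1

    def test_generator_round_trip(self, tmp_path):
        """A simulator-written support file loads back to the same library."""
        cfg = SimulationConfig(n_peptides=100, seed=11)
        support = tmp_path / "support.csv"
        lib = generate_library(cfg, support)
        loaded = load_library(support)
        assert len(loaded) == 100
        assert [(p.sequence, p.group_id, p.protein_id, p.start_pos, p.site_pos)
                for p in loaded.peptides] == \
               [(p.sequence, p.group_id, p.protein_id, p.start_pos, p.site_pos)
                for p in lib.peptides]


class TestEnumerateTheoretical:
    def test_pooled_43_peptides_gives_946(self):
        lib = generate_library(SimulationConfig(n_peptides=43, group_sizes=[43],
                                                seed=5))
        assert len(enumerate_theoretical(lib, "pooled")) == 946

    def test_single_peptide_is_one_homeotypic_link(self):
        lib = PeptideLibrary("x", [LibraryPeptide("GAKWR", "G1", "P1", 1, 3)])
        space = enumerate_theoretical(lib, "pooled")
        assert len(space) == 1
        assert space.crosslinks[0].link_class == "homeotypic"

    def test_grouped_sizes_2_and_3_give_9(self):
        lib = generate_library(SimulationConfig(n_peptides=5, group_sizes=[2, 3],
                                                seed=6))
        assert len(enumerate_theoretical(lib, "grouped")) == 9

    @pytest.mark.parametrize("n", list(range(1, 51)))
    def test_pooled_matches_closed_form_and_brute_force(self, n):
        lib = generate_library(SimulationConfig(n_peptides=n, group_sizes=[n],
                                                seed=n))
        assert len(enumerate_theoretical(lib, "pooled")) \
            == n * (n + 1) // 2 == brute_pair_count_pooled(n)

    @pytest.mark.parametrize("sizes", [[2, 3], [6, 10, 7], [1, 1, 1], [10] * 4])
    def test_grouped_matches_brute_force(self, sizes):
        lib = generate_library(SimulationConfig(n_peptides=sum(sizes),
                                                group_sizes=sizes, seed=8))
        assert len(enumerate_theoretical(lib, "grouped")) \
            == brute_pair_count_grouped(sizes)

    def test_link_classes_partition_space(self, small_library):
        for mode in ("grouped", "pooled"):
            space = enumerate_theoretical(small_library, mode)
            c = space.counts
            assert c["homeotypic"] + c["intraprotein"] + c["interprotein"] \
                == c["total"] == len(space)

    def test_grouped_links_are_all_within_group_true(self, small_library):
        space = enumerate_theoretical(small_library, "grouped")
        assert all(x.same_group for x in space.crosslinks)
        for x in space.crosslinks:
            label, _ = classify_pair(x.peptide_a.sequence, x.peptide_b.sequence,
                                     small_library)
            assert label == "within_group_true"


class TestClassifyPair:
    def test_isobaric_permutation_is_non_library(self, small_library):
        # MAKLTK is not synthesized; only its permutation MAKTIK is
        label, cls = classify_pair("MAKLTK", "MAKLTK", small_library)
        assert (label, cls) == ("non_library_false", None)

    def test_cross_group_pair(self, small_library):
        label, cls = classify_pair("LSYDTEASIAKAK", "VAVIKAVR", small_library)
        assert label == "cross_group_false"
        assert cls == "interprotein"

    def test_self_pair_is_homeotypic_true(self, small_library):
        for p in small_library.peptides:
            assert classify_pair(p.sequence, p.sequence, small_library) \
                == ("within_group_true", "homeotypic")

    def test_same_protein_pair_is_intraprotein(self, small_library):
        label, cls = classify_pair("VAVIKAVR", "GAKWR", small_library)
        assert (label, cls) == ("within_group_true", "intraprotein")

    @settings(max_examples=100, derandomize=True,
              suppress_health_check=[HealthCheck.function_scoped_fixture])
    @given(st.data())
    def test_symmetric_and_matches_plain_lookup(self, small_library, data):
        seqs = [p.sequence for p in small_library.peptides] + ["MAKLTK", "AAAK"]
        a = data.draw(st.sampled_from(seqs))
        b = data.draw(st.sampled_from(seqs))
        groups = {p.sequence: p.group_id for p in small_library.peptides}
        assert classify_pair(a, b, small_library)[0] \
            == classify_pair(b, a, small_library)[0] \
            == brute_label(a, b, groups)


def test_near_isobaric_diagnostic_flags_permutations():
    lib = PeptideLibrary("x", [
        LibraryPeptide("MAKTIK", "G1", "P1", 1, 3),
        LibraryPeptide("MAKITK", "G1", "P1", 9, 3),
        LibraryPeptide("GAKWR", "G2", "P2", 1, 3),
    ])
    assert near_isobaric_pairs(lib) == [("MAKITK", "MAKTIK")]
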