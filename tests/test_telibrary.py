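"""TE library curation: parsing, filtering, merging, naming, accounting."""

import io

import pytest

from hybridte import telibrary as tl


def parse(rm_text, lines):
    return tl.parse_repeatmasker_out(io.StringIO(rm_text(lines)))


class TestParse:
    def test_span_is_one_based_inclusive(self, rm_text):
        recs = parse(rm_text, [("s1", 1000, 1500, "+", "Gypsy-1", "LTR/Gypsy", 1)])
        assert len(recs) == 1
        assert recs[0].length == 501
        assert recs[0].repeat_class == "LTR/Gypsy"

    def test_header_only_file_is_empty(self, rm_text):
        assert parse(rm_text, []) == []

    def test_strand_c_maps_to_minus(self, rm_text):
        recs = parse(rm_text, [("s1", 10, 20, "-", "X", "LTR/Copia", 1)])
        assert recs[0].strand == "-"

    def test_non_numeric_begin_raises_with_line_number(self, rm_text):
        text = rm_text([("s1", 10, 20, "+", "X", "LTR/Copia", 1)]).replace(" 10 ", " ten ")
        with pytest.raises(tl.RepeatMaskerParseError, match="line 4"):
            tl.parse_repeatmasker_out(io.StringIO(text))

    def test_wrong_column_count_raises(self, rm_text):
        text = rm_text([]) + "1 2 3\n"
        with pytest.raises(tl.RepeatMaskerParseError, match="line 4"):
            tl.parse_repeatmasker_out(io.StringIO(text))


class TestFilterNonTE:
    @pytest.mark.parametrize(
        "cls,kept",
        [
            ("Simple_repeat", False),
            ("Satellite", False),
            ("Low_complexity", False),
            ("rRNA", False),
            ("tRNA", False),
            ("Unknown", False),
            ("LTR/Gypsy", True),
            ("DNA/TcMar-Tc1", True),
            ("LINE/Jockey", True),
            ("Satellite/W-chromosome", False),  # top-level token match
        ],
    )
    def test_banned_classes(self, rm_text, cls, kept):
        recs = parse(rm_text, [("s1", 100, 900, "+", "X", cls, 1)])
        assert bool(tl.filter_non_te(recs)) is kept

    def test_order_preserved(self, rm_text):
        recs = parse(
            rm_text,
            [
                ("s1", 100, 900, "+", "A", "LTR/Gypsy", 1),
                ("s1", 1000, 1100, "+", "B", "Simple_repeat", 2),
                ("s1", 2000, 2900, "+", "C", "LINE/R1", 3),
            ],
        )
        assert [r.repeat_name for r in tl.filter_non_te(recs)] == ["A", "C"]


class TestCanonicalName:
    @pytest.mark.parametrize(
        "raw,expected",
        [
            ("Gypsy-1-Dmoj", "Gypsy-1"),
            ("Gypsy-1", "Gypsy-1"),
            ("Helitron-2-Dari", "Helitron-2"),
        ],
    )
    def test_suffix_stripping(self, raw, expected):
        assert tl.canonical_family_name(raw) == expected

    def test_idempotent_even_for_double_suffix(self):
        once = tl.canonical_family_name("Copia-3-Dmoj-Dari")
        assert tl.canonical_family_name(once) == once


class TestMergeFragments:
    def test_same_block_id_merges_to_span_union(self, rm_text):
        recs = parse(
            rm_text,
            [
                ("s1", 100, 400, "+", "Gypsy-1", "LTR/Gypsy", 7),
                ("s1", 450, 900, "+", "Gypsy-1", "LTR/Gypsy", 7),
            ],
        )
        out = tl.merge_fragments(recs)
        assert len(out) == 1
        assert (out[0].start, out[0].end) == (99, 900)  # 0-based half-open

    def test_ltr_flank_internal_pair_merges_to_element(self, rm_text):
        recs = parse(
            rm_text,
            [
                ("s1", 100, 350, "+", "Gypsy-1_LTR", "LTR/Gypsy", 1),
                ("s1", 400, 2400, "+", "Gypsy-1-int", "LTR/Gypsy", 2),
                ("s1", 2450, 2700, "+", "Gypsy-1_LTR", "LTR/Gypsy", 3),
            ],
        )
        out = tl.merge_fragments(recs)
        assert len(out) == 1
        assert out[0].family == "Gypsy-1"
        assert (out[0].start, out[0].end) == (99, 2700)

    def test_different_scaffolds_never_merge(self, rm_text):
        recs = parse(
            rm_text,
            [
                ("s1", 100, 900, "+", "Gypsy-1", "LTR/Gypsy", 1),
                ("s2", 100, 900, "+", "Gypsy-1", "LTR/Gypsy", 1),
            ],
        )
        assert len(tl.merge_fragments(recs)) == 2

    def test_different_strands_never_merge(self, rm_text):
        recs = parse(
            rm_text,
            [
                ("s1", 100, 350, "+", "Gypsy-1_LTR", "LTR/Gypsy", 1),
                ("s1", 400, 2400, "-", "Gypsy-1-int", "LTR/Gypsy", 2),
            ],
        )
        assert len(tl.merge_fragments(recs)) == 2

    def test_solo_ltr_pair_does_not_merge(self, rm_text):
        recs = parse(
            rm_text,
            [
                ("s1", 100, 350, "+", "Gypsy-1_LTR", "LTR/Gypsy", 1),
                ("s1", 400, 650, "+", "Gypsy-1_LTR", "LTR/Gypsy", 2),
            ],
        )
        assert len(tl.merge_fragments(recs)) == 2

    def test_gap_beyond_threshold_blocks_merge(self, rm_text):
        recs = parse(
            rm_text,
            [
                ("s1", 100, 350, "+", "Gypsy-1_LTR", "LTR/Gypsy", 1),
                ("s1", 6000, 8000, "+", "Gypsy-1-int", "LTR/Gypsy", 2),
            ],
        )
        assert len(tl.merge_fragments(recs, max_gap=5000)) == 2
        assert len(tl.merge_fragments(recs, max_gap=10000)) == 1


class TestLengthFilter:
    def test_boundary_100nt_is_kept(self, rm_text):
        recs = parse(
            rm_text,
            [
                ("s1", 1, 100, "+", "A", "LTR/Gypsy", 1),  # exactly 100 nt
                ("s1", 7000, 7098, "+", "B", "LTR/Gypsy", 2),  # 99 nt
            ],
        )
        kept = tl.filter_min_length(tl.merge_fragments(recs), 100)
        assert [i.family for i in kept] == ["A"]


class TestBuildLibrary:
    def _ins(self, family, species, order="LTR", start=0):
        return tl.TEInsertion(
            insertion_id=f"{species}:{family}:{start}",
            family=family, te_order=order, scaffold="s1",
            start=start, end=start + 500, strand="+", source_species=species,
        )

    def test_shared_exclusive_tallies(self):
        lib = tl.build_library(
            {
                "Dmoj": [self._ins("f1", "Dmoj"), self._ins("f2", "Dmoj")],
                "Dari": [self._ins("f2", "Dari"), self._ins("f3", "Dari")],
            }
        )
        assert lib.tallies == {"shared": 1, "exclusive_Dmoj": 1, "exclusive_Dari": 1}
        assert lib.n_families == 3

    def test_single_species_all_exclusive(self):
        lib = tl.build_library({"Dari": [self._ins("f1", "Dari")]})
        assert lib.tallies == {"shared": 0, "exclusive_Dmoj": 0, "exclusive_Dari": 1}

    def test_tallies_sum_to_family_total(self):
        lib = tl.build_library(
            {
                "Dmoj": [self._ins(f"f{i}", "Dmoj") for i in range(5)],
                "Dari": [self._ins(f"f{i}", "Dari") for i in range(3, 8)],
            }
        )
        assert sum(lib.tallies.values()) == lib.n_families

    def test_order_conflict_raises_by_default(self):
        insertions = {
            "Dmoj": [self._ins("f1", "Dmoj", order="LTR")],
            "Dari": [self._ins("f1", "Dari", order="TIR")],
        }
        with pytest.raises(ValueError, match="conflicting TE orders"):
            tl.build_library(insertions)
        lib = tl.build_library(insertions, order_conflict="majority")
        assert lib.families["f1"].te_order in ("LTR", "TIR")

    def test_unknown_species_key_raises(self):
        with pytest.raises(ValueError, match="unknown species"):
            tl.build_library({"Dsim": []})


class TestWriteFasta:
    def test_extraction_and_reverse_complement(self):
        ins_plus = tl.TEInsertion("i1", "f", "LTR", "s1", 0, 4, "+", "Dmoj")
        ins_minus = tl.TEInsertion("i2", "f", "LTR", "s1", 0, 4, "-", "Dmoj")
        lib = tl.TELibrary(
            families={"f": tl.TEFamily("f", "LTR", {"Dmoj"}, {"Dmoj": 2})},
            insertions=[ins_plus, ins_minus],
            tallies={"shared": 0, "exclusive_Dmoj": 1, "exclusive_Dari": 0},
        )
        buf = io.StringIO()
        tl.write_library_fasta(lib, {"Dmoj": {"s1": "ACGTTT"}}, buf)
        entries = buf.getvalue().split(">")[1:]
        assert entries[0].splitlines()[1] == "ACGT"
        assert entries[1].splitlines()[1] == "ACGT"  # ACGT is its own revcomp
        # an asymmetric span pins the orientation
        ins = tl.TEInsertion("i3", "f", "LTR", "s1", 1, 5, "-", "Dmoj")
        lib.insertions = [ins]
        buf = io.StringIO()
        tl.write_library_fasta(lib, {"Dmoj": {"s1": "ACGTTT"}}, buf)
        assert buf.getvalue().splitlines()[1] == "AACG"  # revcomp("CGTT")

    def test_missing_scaffold_names_insertion(self):
        ins = tl.TEInsertion("bad-ins", "f", "LTR", "nope", 0, 4, "+", "Dmoj")
        lib = tl.TELibrary(
            families={"f": tl.TEFamily("f", "LTR", {"Dmoj"}, {"Dmoj": 1})},
            insertions=[ins],
            tallies={"shared": 0, "exclusive_Dmoj": 1, "exclusive_Dari": 0},
        )
        with pytest.raises(KeyError, match="bad-ins"):
            tl.write_library_fasta(lib, {"Dmoj": {"s1": "ACGTTT"}}, io.StringIO())
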