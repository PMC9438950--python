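"""Selection, sorting, homopolymer compression/decompression."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gfakit import io as gio
from gfakit import stats as gs
from gfakit import transform as gt
from gfakit.seq import homopolymer_compress, homopolymer_decompress

from conftest import random_assembly

THREE = b">sc1\nACGT\n>sc2\nTTTTTTT\n>sc3\nGGNNGG\n"


class TestSelection:
    def test_include_names(self):
        asm = gio.read_fasta(THREE)
        out = gt.apply_selection(asm, gt.SelectionSpec(
            include_names=["sc2"]))
        assert [p.name for p in out.paths.values()] == ["sc2"]
        assert len(asm.paths) == 3  # original untouched

    def test_include_order_follows_list(self):
        asm = gio.read_fasta(THREE)
        out = gt.apply_selection(asm, gt.SelectionSpec(
            include_names=["sc3", "sc1"]))
        assert [p.name for p in out.paths.values()] == ["sc3", "sc1"]

    def test_exclude_names(self):
        asm = gio.read_fasta(THREE)
        out = gt.apply_selection(asm, gt.SelectionSpec(
            exclude_names=["sc1", "sc3"]))
        assert [p.name for p in out.paths.values()] == ["sc2"]

    def test_empty_exclude_is_identity(self):
        asm = gio.read_fasta(THREE)
        out = gt.apply_selection(asm, gt.SelectionSpec(exclude_names=[]))
        assert gio.write_fasta(out) == gio.write_fasta(asm)

    def test_unknown_name_warns_by_default(self):
        asm = gio.read_fasta(THREE)
        warnings = []
        gt.apply_selection(asm, gt.SelectionSpec(include_names=["nope"]),
                           warn=warnings.append)
        assert warnings

    def test_unknown_name_strict_raises(self):
        asm = gio.read_fasta(THREE)
        with pytest.raises(gt.SelectionError):
            gt.apply_selection(asm, gt.SelectionSpec(
                include_names=["nope"]), strict=True)

    def test_include_interval_extracts_subrange(self):
        asm = gio.read_fasta(b">sc1\nACGNNNTTG\n")
        out = gt.apply_selection(asm, gt.SelectionSpec(
            include_intervals=[gt.BedInterval("sc1", 1, 8)]))
        p = out.path_by_name("sc1:1-8")
        assert p is not None
        assert out.linearize(p) == "CGNNNTT"

    def test_include_interval_pure_gap_flagged(self):
        asm = gio.read_fasta(b">sc1\nACGNNNTTG\n")
        warnings = []
        out = gt.apply_selection(asm, gt.SelectionSpec(
            include_intervals=[gt.BedInterval("sc1", 3, 6)]),
            warn=warnings.append)
        p = out.path_by_name("sc1:3-6")
        assert out.linearize(p) == "NNN"
        assert warnings and "no contig bases" in warnings[0]

    def test_interval_beyond_length_is_error(self):
        asm = gio.read_fasta(b">sc1\nACGT\n")
        with pytest.raises(gt.SelectionError, match="outside"):
            gt.apply_selection(asm, gt.SelectionSpec(
                include_intervals=[gt.BedInterval("sc1", 0, 99)]))

    def test_exclude_interval_erases_range(self):
        asm = gio.read_fasta(b">sc1\nAAAATTTT\n")
        out = gt.apply_selection(asm, gt.SelectionSpec(
            exclude_intervals=[gt.BedInterval("sc1", 4, 8)]))
        assert out.linearize(out.path_by_name("sc1")) == "AAAA"

    def test_selection_then_stats_matches_subset(self):
        for seed in range(3):
            asm = random_assembly(seed)
            names = [p.name for p in asm.paths.values()][:2]
            sub = gt.apply_selection(asm, gt.SelectionSpec(
                include_names=names))
            rep = gs.summarize(sub)
            fasta = gio.write_fasta(asm).split(">")
            kept = ">" + ">".join(r for r in fasta[1:]
                                  if r.split()[0].split("\n")[0] in names)
            rep2 = gs.summarize(gio.read_fasta(kept.encode()))
            assert rep.total_scaffold_len == rep2.total_scaffold_len
            assert rep.n_contigs == rep2.n_contigs
            assert rep.scaffold_n50 == rep2.scaffold_n50


class TestSort:
    def test_length_descending(self):
        asm = gio.read_fasta(b">a\nAAAAA\n>b\nCCCCCCCCC\n>c\nGGGGGGG\n")
        out = gt.sort_assembly(asm, gt.SortSpec("LENGTH", descending=True))
        assert [asm_p.name for asm_p in out.paths.values()] == \
            ["b", "c", "a"]

    def test_natural_name_sort(self):
        asm = gio.read_fasta(b">s2\nAA\n>s10\nCC\n>s1\nGG\n")
        out = gt.sort_assembly(asm, gt.SortSpec("NAME"))
        assert [p.name for p in out.paths.values()] == ["s1", "s2", "s10"]

    def test_custom_list_then_input_order(self):
        asm = gio.read_fasta(THREE)
        out = gt.sort_assembly(asm, gt.SortSpec(
            "CUSTOM_LIST", custom_order=["sc3"]))
        assert [p.name for p in out.paths.values()] == \
            ["sc3", "sc1", "sc2"]

    def test_idempotent(self):
        asm = random_assembly(4)
        spec = gt.SortSpec("LENGTH", descending=True)
        once = gt.sort_assembly(asm, spec)
        twice = gt.sort_assembly(once, spec)
        assert gio.write_fasta(once) == gio.write_fasta(twice)

    def test_sort_preserves_stats(self):
        asm = random_assembly(6)
        out = gt.sort_assembly(asm, gt.SortSpec("NAME"))
        r1, r2 = gs.summarize(asm), gs.summarize(out)
        for f in ("n_scaffolds", "n_contigs", "n_gaps", "scaffold_n50",
                  "contig_n50", "total_scaffold_len", "gc_content"):
            assert getattr(r1, f) == getattr(r2, f)


class TestHomopolymer:
    def test_run_length_example(self):
        comp, runs = homopolymer_compress("AAACCGTT")
        assert comp == "ACGT"
        assert runs == [3, 2, 1, 2]

    def test_fixed_point(self):
        assert homopolymer_compress("ACGT") == ("ACGT", [1, 1, 1, 1])

    def test_empty(self):
        assert homopolymer_compress("") == ("", [])

    def test_case_insensitive_runs_keep_first_case(self):
        comp, runs = homopolymer_compress("aAAcC")
        assert comp == "ac"
        assert runs == [3, 2]

    def test_expansion(self):
        assert homopolymer_decompress("ACGT", [3, 2, 1, 2]) == "AAACCGTT"

    def test_track_mismatch_raises(self):
        with pytest.raises(ValueError, match="track"):
            homopolymer_decompress("ACGT", [1, 2])

    # runs are drawn as (base, case, length) so long runs and mixed case
    # across runs are covered; within one run the case is uniform, the
    # only regime where run-length expansion can be exact
    run_lists = st.lists(
        st.tuples(st.sampled_from("ACGT"), st.booleans(),
                  st.integers(1, 30)),
        min_size=0, max_size=40)

    @given(run_lists)
    @settings(max_examples=300, deadline=None)
    def test_round_trip_exact(self, runs_spec):
        cleaned = []
        for b, low, n in runs_spec:  # adjacent same-base runs would merge
            if cleaned and cleaned[-1][0] == b:
                continue
            cleaned.append((b, low, n))
        s = "".join((b.lower() if low else b) * n for b, low, n in cleaned)
        comp, runs = homopolymer_compress(s)
        assert homopolymer_decompress(comp, runs) == s
        assert sum(runs) == len(s)
        assert len(comp) == len(cleaned)
        assert (len(comp) < len(s)) == any(n > 1 for _, _, n in cleaned)

    @given(st.text(alphabet="ACGTacgt", min_size=0, max_size=200))
    @settings(max_examples=200, deadline=None)
    def test_round_trip_case_insensitive(self, s):
        # arbitrary soft-masking: exact up to case (runs merge across a
        # mask boundary by design)
        comp, runs = homopolymer_compress(s)
        assert homopolymer_decompress(comp, runs).upper() == s.upper()

    def test_assembly_level_round_trip(self):
        asm = random_assembly(9)
        comp, tracks = gt.homopolymer_compress(asm)
        back = gt.homopolymer_decompress(comp, tracks)
        assert {s.name: s.sequence for s in back.segments.values()} == \
            {s.name: s.sequence for s in asm.segments.values()}

    def test_gaps_untouched(self, toy):
        comp, _ = gt.homopolymer_compress(toy)
        assert gs.summarize(comp).total_gap_len == \
            gs.summarize(toy).total_gap_len

    def test_missing_track_errors(self, toy):
        comp, tracks = gt.homopolymer_compress(toy)
        tracks.pop(next(iter(tracks)))
        with pytest.raises(ValueError, match="no homopolymer track"):
            gt.homopolymer_decompress(comp, tracks)

    def test_sidecar_tsv_round_trip(self, toy):
        _, tracks = gt.homopolymer_compress(toy)
        assert gt.read_tracks(gt.write_tracks(tracks)) == tracks
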