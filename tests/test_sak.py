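"""SAK parsing and execution: edit semantics, inverses, conservation."""

import numpy as np
import pytest

from gfakit import io as gio
from gfakit import sak as gk
from gfakit import stats as gs
from gfakit.fixtures import random_sak_script
from gfakit.model import ElementKind, build_graph, walk_components
from gfakit.seq import revcomp

from conftest import build_three_segment_scaffold, random_assembly


class TestParse:
    def test_join_instruction(self):
        ins = gk.parse_script("JOIN sc1+ sc2+ 100 scJ")
        assert len(ins) == 1
        assert ins[0].verb == "JOIN"
        assert ins[0].operands == ["sc1+", "sc2+", "100", "scJ"]

    def test_comments_and_blanks(self):
        assert gk.parse_script("# comment\n\n   \n") == []

    def test_unknown_verb(self):
        with pytest.raises(gk.SakParseError, match="line 1"):
            gk.parse_script("FROBNICATE x")

    def test_wrong_arity(self):
        with pytest.raises(gk.SakParseError, match="SPLIT"):
            gk.parse_script("SPLIT onlyone")

    def test_case_insensitive_verbs(self):
        assert gk.parse_script("rvcp sc1")[0].verb == "RVCP"

    def test_all_or_nothing(self):
        with pytest.raises(gk.SakParseError):
            gk.parse_script("RVCP sc1\nBOGUS x\n")


class TestSplitJoin:
    def test_split_disconnects_first_segment(self, abc_scaffold):
        out, log = gk.execute(abc_scaffold, "SPLIT A B")
        comps = walk_components(build_graph(out))
        sets = sorted(sorted(out.segments[u].name for u in c.segment_uids)
                      for c in comps)
        assert sets == [["A"], ["B", "C"]]
        assert len(out.paths) == 2
        # input untouched
        assert len(abc_scaffold.paths) == 1

    def test_rejoin_restores_totals(self, abc_scaffold):
        before = gs.summarize(abc_scaffold)
        out, _ = gk.execute(
            abc_scaffold,
            "TRIM_NS scaf\nSPLIT A B\nJOIN scaf.1+ scaf.2+ 3 scaf\n")
        after = gs.summarize(out)
        assert after.n_scaffolds == 1
        assert after.total_contig_len == before.total_contig_len
        path = next(iter(out.paths.values()))
        assert out.linearize(path) == "ACGTACNNNGGTTGGNNNNCATCAT"

    def test_empty_script_is_identity(self, toy):
        out, log = gk.execute(toy, "")
        assert log == []
        assert gio.write_fasta(out) == gio.write_fasta(toy)

    def test_join_reverse_orientation(self):
        a = gio.read_fasta(b">p1\nAACG\n>p2\nTTTT\n")
        out, _ = gk.execute(a, "JOIN p1- p2+ 2 merged")
        path = out.path_by_name("merged")
        assert out.linearize(path) == revcomp("AACG") + "NN" + "TTTT"

    def test_join_unknown_gap(self):
        a = gio.read_fasta(b">p1\nAACG\n>p2\nTTTT\n")
        out, _ = gk.execute(a, "JOIN p1+ p2+ * merged")
        path = out.path_by_name("merged")
        assert len(out.linearize(path)) == 8 + 100

    def test_join_terminal_gap_end_is_error(self, abc_scaffold):
        seg = abc_scaffold.add_segment("Z", "TTTT")
        from gfakit.model import PathElement
        abc_scaffold.add_path("p2", [PathElement(ElementKind.SEGMENT,
                                                 seg.uid)])
        with pytest.raises(gk.SakExecutionError, match="terminal gap"):
            gk.execute(abc_scaffold, "JOIN scaf+ p2+ 5 out")

    def test_split_non_adjacent_is_error(self, abc_scaffold):
        with pytest.raises(gk.SakExecutionError, match="not adjacent"):
            gk.execute(abc_scaffold, "SPLIT A C")

    def test_join_split_mutual_inverse(self):
        rng = np.random.default_rng(5)
        for seed in range(10):
            asm = random_assembly(seed, terminal_gap_prob=0.0)
            paths = [p.name for p in asm.paths.values()]
            a, b = paths[0], paths[1]
            joined, _ = gk.execute(asm, f"JOIN {a}+ {b}+ 50 tmp")
            p = joined.path_by_name("tmp")
            els = p.elements
            # find the join gap: last segment of a / first segment of b
            seg_a = None
            for i, el in enumerate(els):
                if el.kind is ElementKind.GAP and \
                        joined.gaps[el.uid].distance == 50 and \
                        joined.gaps[el.uid].name.startswith("tmp."):
                    seg_a = joined.segments[els[i - 1].uid].name
                    seg_b = joined.segments[els[i + 1].uid].name
            back, _ = gk.execute(
                joined,
                f"SPLIT {seg_a} {seg_b}\nRENAME tmp.1 {a}\n"
                f"RENAME tmp.2 {b}")

            def records(asm_):
                return {p.name: asm_.linearize(p)
                        for p in asm_.paths.values()}

            assert records(back) == records(asm)


class TestExciseRemoveErase:
    def test_excise_keeps_contig_as_singleton(self, abc_scaffold):
        before = gs.summarize(abc_scaffold)
        out, _ = gk.execute(abc_scaffold, "EXCISE B 7")
        after = gs.summarize(out)
        assert after.total_contig_len == before.total_contig_len
        assert after.n_scaffolds == before.n_scaffolds + 1
        scaf = out.path_by_name("scaf")
        assert "B" not in [out.segments[u].name
                           for u in scaf.segment_uids()]
        assert out.path_by_name("B") is not None
        # segment + two flanking gaps replaced by one gap of length 7
        assert out.linearize(scaf) == "NN" + "ACGTAC" + "N" * 7 \
            + "CATCAT" + "NN"

    def test_remove_deletes_contig(self, abc_scaffold):
        before = gs.summarize(abc_scaffold)
        out, _ = gk.execute(abc_scaffold, "REMOVE B")
        after = gs.summarize(out)
        assert after.total_contig_len == before.total_contig_len - 6
        assert out.segment_by_name("B") is None

    def test_erase_middle_of_contig_leaves_zero_gap(self):
        asm = gio.read_fasta(b">s1\nAAAATTTT\n")
        out, _ = gk.execute(asm, "ERASE s1 4-6")
        path = out.path_by_name("s1")
        assert out.linearize(path) == "AAAATT"
        kinds = [e.kind for e in path.elements]
        assert kinds == [ElementKind.SEGMENT, ElementKind.GAP,
                         ElementKind.SEGMENT]
        assert out.gaps[path.elements[1].uid].distance == 0

    def test_erase_whole_contig_and_gap(self, toy):
        # erase contig 2 plus the gap: 3..9 of ACGNNNTTG
        out, _ = gk.execute(toy, "ERASE sc1 3-9")
        path = out.path_by_name("sc1")
        assert out.linearize(path) == "ACG"
        assert len(out.segments) == 1

    def test_erase_out_of_range(self, toy):
        with pytest.raises(gk.SakExecutionError, match="out of bounds"):
            gk.execute(toy, "ERASE sc1 5-99")

    def test_erase_exact_scaffold_shrink(self):
        for seed in range(5):
            asm = random_assembly(seed)
            rng = np.random.default_rng(seed)
            p = list(asm.paths.values())[0]
            total = asm.path_length(p)
            a = int(rng.integers(0, total - 1))
            b = int(rng.integers(a + 1, total + 1))
            out, _ = gk.execute(asm, f"ERASE {p.name} {a}-{b}")
            before = gs.summarize(asm).total_scaffold_len
            after = gs.summarize(out).total_scaffold_len
            assert after == before - (b - a)


class TestOrientationOps:
    def test_rvcp_sequence(self):
        asm = gio.read_fasta(b">s\nAACG\n")
        out, _ = gk.execute(asm, "RVCP s.ctg1")
        assert out.segment_by_name("s.ctg1").sequence == "CGTT"

    def test_rvcp_scaffold_linearization(self, abc_scaffold):
        original = abc_scaffold.linearize(
            abc_scaffold.path_by_name("scaf"))
        out, _ = gk.execute(abc_scaffold, "RVCP scaf")
        assert out.linearize(out.path_by_name("scaf")) == revcomp(original)

    def test_rvcp_involution(self):
        for seed in range(5):
            asm = random_assembly(seed)
            names = [p.name for p in asm.paths.values()]
            script = "".join(f"RVCP {n}\n" for n in names) * 2
            out, _ = gk.execute(asm, script)
            assert gio.write_fasta(out) == gio.write_fasta(asm)

    def test_invert_twice_is_identity(self, abc_scaffold):
        out, _ = gk.execute(abc_scaffold, "INVERT B\nINVERT B")
        assert gio.write_fasta(out) == gio.write_fasta(abc_scaffold)

    def test_invert_flips_linearized_block(self, abc_scaffold):
        out, _ = gk.execute(abc_scaffold, "INVERT B")
        assert out.linearize(out.path_by_name("scaf")) == \
            "NN" + "ACGTAC" + "NNN" + revcomp("GGTTGG") + "NNNN" \
            + "CATCAT" + "NN"


class TestTrimRename:
    def test_trim_ns_drops_terminal_gaps(self, abc_scaffold):
        before = gs.summarize(abc_scaffold)
        out, _ = gk.execute(abc_scaffold, "TRIM_NS scaf")
        after = gs.summarize(out)
        assert after.total_scaffold_len == before.total_scaffold_len - 4
        assert after.n_gaps == before.n_gaps - 2
        path = out.path_by_name("scaf")
        assert path.elements[0].kind is ElementKind.SEGMENT
        assert path.elements[-1].kind is ElementKind.SEGMENT

    def test_trim_ns_all_scaffolds(self):
        asm = gio.read_fasta(b">a\nNNACGT\n>b\nTTTTNN\n")
        out, _ = gk.execute(asm, "TRIM_NS")
        assert gs.summarize(out).n_gaps == 0

    def test_rename_scaffold_and_segment(self, toy):
        out, _ = gk.execute(toy, "RENAME sc1 chr1\nRENAME sc1.ctg1 c1")
        assert out.path_by_name("chr1") is not None
        assert out.segment_by_name("c1") is not None

    def test_rename_collision(self):
        asm = gio.read_fasta(b">a\nACGT\n>b\nTTTT\n")
        with pytest.raises(gk.SakExecutionError, match="already in use"):
            gk.execute(asm, "RENAME a b")


class TestTransactional:
    def test_error_aborts_whole_run(self, toy):
        before = gio.write_fasta(toy)
        with pytest.raises(gk.SakExecutionError, match="instruction 2"):
            gk.execute(toy, "RENAME sc1 ok\nRVCP nonexistent")
        assert gio.write_fasta(toy) == before

    def test_name_resolution_is_sequential(self):
        asm = gio.read_fasta(b">a\nACGT\n")
        out, _ = gk.execute(asm, "RENAME a b\nRENAME b c")
        assert out.path_by_name("c") is not None


class TestLog:
    def test_one_entry_per_instruction(self, abc_scaffold):
        _, log = gk.execute(abc_scaffold, "SPLIT A B\nRENAME scaf.1 left")
        assert [e.index for e in log] == [1, 2]
        assert log[0].instruction == "SPLIT A B"

    def test_log_replay_reproduces_edit(self):
        rng = np.random.default_rng(123)
        for seed in range(5):
            asm = random_assembly(seed)
            script = random_sak_script(asm, rng, 6)
            edited, log = gk.execute(asm, script)
            replay_script = "\n".join(e.instruction for e in log)
            replayed, _ = gk.execute(asm, replay_script)
            assert gio.write_fasta(replayed) == gio.write_fasta(edited)

    def test_format_log_tsv(self, abc_scaffold):
        _, log = gk.execute(abc_scaffold, "SPLIT A B")
        text = gk.format_log(log)
        assert text.splitlines()[0].startswith("index\t")
        assert "SPLIT A B" in text
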