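"""Streaming readers/writers: FASTA, FASTQ, GFA1, GFA2 (+gzip), AGP, BED, sizes.

Every sequence format maps to and from the :class:`~gfakit.model.Assembly`
model. FASTA/FASTQ records become scaffolds: maximal runs of ``N``/``n``
split a record into contigs separated by sized gaps; leading/trailing runs
become terminal gaps. Conversions are lossless where the target format can
express the content; the one documented lossy case (GFA1 has no gap lines)
is worked around with a reserved ``gl`` tag on P lines that records the
collapsed gap lengths, so GFA1 round-trips restore them.

Coordinate conventions: BED is 0-based half-open; AGP is 1-based inclusive;
everything internal is 0-based half-open.
"""

from __future__ import annotations

import gzip
import io as _stdio
from dataclasses import dataclass
from typing import Iterable, Optional, TextIO

from . import seq as _seq
from .model import (
    Assembly,
    AssemblyError,
    DEFAULT_UNKNOWN_GAP_LEN,
    ElementKind,
    PathElement,
    SegmentEnd,
    Side,
    UNKNOWN,
)

GZIP_MAGIC = b"\x1f\x8b"

#: Reserved tag names the converter uses internally.
COMMENT_TAG = "cm"    # FASTA/FASTQ header comment, on paths
QUAL_TAG = "ql"       # per-base qualities, on segments (GFA carriage)
GAPLEN_TAG = "gl"     # collapsed gap lengths, on GFA1 P lines
SOURCE_TAG = "sf"     # record source format: fasta|fastq, on paths


class ParseError(ValueError):
    """Malformed input; message carries line number or record name."""


@dataclass
class FormatDialect:
    kind: str                 # FASTA | FASTQ | GFA1 | GFA2
    gzipped: bool = False
    line_width: Optional[int] = 60  # FASTA wrap; None = unlimited


# ---------------------------------------------------------------------------
# Detection / opening
# ---------------------------------------------------------------------------

def _open_text(source) -> TextIO:
    """Open a path or binary/text stream as text, transparently gunzipping."""
    if isinstance(source, str):
        raw = open(source, "rb")
    elif isinstance(source, bytes):
        raw = _stdio.BytesIO(source)
    elif hasattr(source, "read"):
        data = source.read()
        if isinstance(data, str):
            return _stdio.StringIO(data)
        raw = _stdio.BytesIO(data)
    else:
        raise TypeError(f"cannot open {source!r}")
    head = raw.read(2)
    raw.seek(0)
    if head == GZIP_MAGIC:
        return _stdio.TextIOWrapper(gzip.GzipFile(fileobj=raw))
    return _stdio.TextIOWrapper(raw)


def detect_format(source) -> FormatDialect:
    """Sniff the dialect from content (extension is never trusted).

    gzip is recognized by its magic bytes; GFA1 vs GFA2 by the header VN
    tag when present, else by line-type evidence (E/G/O/F => GFA2, L/P =>
    GFA1, S-line field shape as last resort).
    """
    if isinstance(source, str):
        with open(source, "rb") as fh:
            data = fh.read()
    elif isinstance(source, bytes):
        data = source
    else:
        data = source.read()
        if isinstance(data, str):
            data = data.encode()
    gzipped = data[:2] == GZIP_MAGIC
    if gzipped:
        data = gzip.decompress(data)
    text = data.decode(errors="replace")
    first = None
    for line in text.splitlines():
        if line.strip():
            first = line[0]
            break
    if first == ">":
        return FormatDialect("FASTA", gzipped)
    if first == "@":
        return FormatDialect("FASTQ", gzipped)
    if first in set("HSLEGPOUJF#"):
        return FormatDialect(_sniff_gfa_version(text), gzipped)
    raise ParseError(f"unrecognized format (first character {first!r})")


def _sniff_gfa_version(text: str) -> str:
    for line in text.splitlines():
        if line.startswith("H"):
            for tag in line.split("\t")[1:]:
                if tag.startswith("VN:Z:"):
                    return "GFA2" if tag[5:].startswith("2") else "GFA1"
    for line in text.splitlines():
        t = line[:1]
        if t in "EGOUF":
            return "GFA2"
        if t in "LP":
            return "GFA1"
    for line in text.splitlines():
        if line.startswith("S\t"):
            fields = line.rstrip("\n").split("\t")
            if len(fields) >= 3 and fields[2].isdigit():
                return "GFA2"
            return "GFA1"
    return "GFA2"


# ---------------------------------------------------------------------------
# FASTA / FASTQ reading
# ---------------------------------------------------------------------------

def _add_scaffold_record(asm: Assembly, name: str, comment: str,
                         sequence: str, qualities: Optional[str],
                         lineno: int, source_fmt: str) -> None:
    """Split one linear record at N-runs into segments/gaps + one path."""
    bad = _seq.first_invalid_char(sequence)
    if bad >= 0:
        raise ParseError(
            f"record {name!r} near line {lineno}: invalid character "
            f"{sequence[bad]!r}")
    if qualities is not None and len(qualities) != len(sequence):
        raise ParseError(
            f"record {name!r}: quality length {len(qualities)} != "
            f"sequence length {len(sequence)}")
    contig_spans, gap_spans = _seq.split_at_n_runs(sequence)
    tags = {SOURCE_TAG: f"Z:{source_fmt}"}
    if comment:
        tags[COMMENT_TAG] = f"Z:{comment}"
    path = asm.add_path(name, tags=tags)

    segs = []
    for i, (a, b) in enumerate(contig_spans, 1):
        segs.append(asm.add_segment(
            f"{name}.ctg{i}", sequence[a:b],
            qualities[a:b] if qualities is not None else None))

    elements = []
    gi = 0
    events = sorted(
        [(a, b, "C", idx) for idx, (a, b) in enumerate(contig_spans)] +
        [(a, b, "G", idx) for idx, (a, b) in enumerate(gap_spans)])
    for a, b, kind, idx in events:
        if kind == "C":
            elements.append(PathElement(ElementKind.SEGMENT, segs[idx].uid))
        else:
            # attachment: a leading run has no left segment, a trailing
            # run no right segment (terminal gap, one open side)
            left = None
            right = None
            for j, (ca, cb) in enumerate(contig_spans):
                if cb == a:
                    left = SegmentEnd(segs[j].uid, Side.TAIL)
                if ca == b:
                    right = SegmentEnd(segs[j].uid, Side.HEAD)
            gi += 1
            gap = asm.add_gap(left, right, b - a, name=f"{name}.gap{gi}")
            elements.append(PathElement(ElementKind.GAP, gap.uid))
    path.elements = elements


def _fasta_records(fh: TextIO):
    """Yield (header, sequence, lineno) streaming one record at a time."""
    header = None
    chunks = []
    start_line = 0
    for lineno, line in enumerate(fh, 1):
        line = line.rstrip("\r\n")
        if not line:
            continue
        if line.startswith(">"):
            if header is not None:
                yield header, "".join(chunks), start_line
            header = line[1:]
            chunks = []
            start_line = lineno
        else:
            if header is None:
                raise ParseError(f"line {lineno}: sequence before header")
            chunks.append(line)
    if header is not None:
        yield header, "".join(chunks), start_line


def read_fasta(source, dialect: Optional[FormatDialect] = None) -> Assembly:
    """Parse FASTA (optionally gzipped) into an assembly, single pass."""
    asm = Assembly()
    with _open_text(source) as fh:
        for header, sequence, lineno in _fasta_records(fh):
            name, _, comment = header.partition(" ")
            if not sequence:
                raise ParseError(f"record {name!r}: empty sequence")
            _add_scaffold_record(asm, name, comment, sequence, None,
                                 lineno, "fasta")
    return asm


def read_fastq(source, dialect: Optional[FormatDialect] = None) -> Assembly:
    """Parse 4-line FASTQ records; qualities split at the same N-runs."""
    asm = Assembly()
    with _open_text(source) as fh:
        it = enumerate((ln.rstrip("\r\n") for ln in fh), 1)
        lineno = 0
        while True:
            head = None
            for lineno, ln in it:  # skip blank lines between records
                if ln:
                    head = ln
                    break
            if head is None:
                break
            rec = []
            for lineno, ln in it:
                rec.append(ln)
                if len(rec) == 3:
                    break
            if len(rec) < 3:
                raise ParseError(
                    f"truncated FASTQ record near line {lineno}")
            sequence, plus, qual = rec
            if not head.startswith("@") or not plus.startswith("+"):
                raise ParseError(f"malformed FASTQ record near line {lineno}")
            name, _, comment = head[1:].partition(" ")
            _add_scaffold_record(asm, name, comment, sequence, qual,
                                 lineno, "fastq")
    return asm


# ---------------------------------------------------------------------------
# FASTA / FASTQ writing
# ---------------------------------------------------------------------------

def _wrap(sequence: str, width: Optional[int]) -> str:
    if not width:
        return sequence + "\n"
    return "\n".join(sequence[i:i + width]
                     for i in range(0, len(sequence), width)) + "\n"


def _path_header(path) -> str:
    comment = path.tags.get(COMMENT_TAG, "")
    if comment.startswith("Z:"):
        comment = comment[2:]
    return f"{path.name} {comment}".rstrip()


def write_fasta(assembly: Assembly, line_width: Optional[int] = 60,
                unknown_gap_len: int = DEFAULT_UNKNOWN_GAP_LEN) -> str:
    """One record per path; sized gaps emit exactly their length in Ns."""
    out = []
    for path in assembly.paths.values():
        out.append(f">{_path_header(path)}\n")
        out.append(_wrap(assembly.linearize(path, unknown_gap_len),
                         line_width))
    return "".join(out)


def write_fastq(assembly: Assembly, gap_quality: str = "!",
                unknown_gap_len: int = DEFAULT_UNKNOWN_GAP_LEN) -> str:
    out = []
    for path in assembly.paths.values():
        seqstr = assembly.linearize(path, unknown_gap_len)
        qual = assembly.linearize_qualities(path, gap_quality,
                                            unknown_gap_len)
        out.append(f"@{_path_header(path)}\n{seqstr}\n+\n{qual}\n")
    return "".join(out)


# ---------------------------------------------------------------------------
# GFA reading
# ---------------------------------------------------------------------------

def _parse_tags(fields: Iterable[str]) -> dict:
    tags = {}
    for f in fields:
        name, _, rest = f.partition(":")
        tags[name] = rest
    return tags


def _fmt_tags(tags: dict, skip=()) -> str:
    parts = [f"\t{k}:{v}" for k, v in tags.items() if k not in skip]
    return "".join(parts)


def _ref_to_end(name_ori: str, which: int, seg_uids: dict):
    """GFA reference 'name+'/'name-' -> SegmentEnd; '*' -> open side.

    ``which`` is 1 for the left (donor) reference, 2 for the right
    (acceptor): s1+ attaches at s1's TAIL, s2+ at s2's HEAD.
    """
    if name_ori == "*":
        return None
    name, ori = name_ori[:-1], name_ori[-1]
    if ori not in "+-":
        raise ParseError(f"reference {name_ori!r} lacks orientation")
    if name not in seg_uids:
        raise ParseError(f"reference to undefined segment {name!r}")
    if which == 1:
        side = Side.TAIL if ori == "+" else Side.HEAD
    else:
        side = Side.HEAD if ori == "+" else Side.TAIL
    return SegmentEnd(seg_uids[name], side)


def _end_to_ref(end, which: int, assembly: Assembly) -> str:
    if end is None:
        return "*"
    name = assembly.segments[end.segment_uid].name
    if which == 1:
        ori = "+" if end.side is Side.TAIL else "-"
    else:
        ori = "+" if end.side is Side.HEAD else "-"
    return f"{name}{ori}"


def read_gfa(source, dialect: Optional[FormatDialect] = None) -> Assembly:
    """Parse GFA1 or GFA2 (auto-detected when no dialect is given).

    Forward references are allowed within the file; gap/edge/path lines
    are resolved once all segments are known. Unknown line types are
    preserved verbatim and re-emitted on write.
    """
    with _open_text(source) as fh:
        text = fh.read()
    if dialect is None:
        dialect = FormatDialect(_sniff_gfa_version(text))
    version = 2 if dialect.kind == "GFA2" else 1

    asm = Assembly()
    seg_uids: dict = {}
    pending_gaps = []   # (lineno, fields)
    pending_edges = []
    pending_paths = []

    for lineno, line in enumerate(text.splitlines(), 1):
        if not line.strip():
            continue
        t = line[0]
        fields = line.split("\t")
        if t == "#":
            asm.extra_lines.append(line)
        elif t == "H":
            asm.header_tags.update(_parse_tags(fields[1:]))
        elif t == "S":
            _read_s_line(asm, seg_uids, fields, version, lineno)
        elif t == "G" and version == 2:
            pending_gaps.append((lineno, fields))
        elif t == "E" and version == 2:
            pending_edges.append((lineno, fields))
        elif t == "O" and version == 2:
            pending_paths.append((lineno, fields, "O"))
        elif t == "L" and version == 1:
            pending_edges.append((lineno, fields))
        elif t == "P" and version == 1:
            pending_paths.append((lineno, fields, "P"))
        else:
            asm.extra_lines.append(line)

    gap_uids: dict = {}
    for lineno, fields in pending_gaps:
        if len(fields) < 5:
            raise ParseError(f"line {lineno}: G line needs >=5 fields")
        _, gid, ref1, ref2, dist = fields[:5]
        var_and_tags = fields[5:]
        distance = UNKNOWN if dist == "*" else int(dist)
        gap = asm.add_gap(_ref_to_end(ref1, 1, seg_uids),
                          _ref_to_end(ref2, 2, seg_uids),
                          distance, name=None if gid == "*" else gid,
                          tags=_parse_tags(var_and_tags[1:])
                          if len(var_and_tags) > 1 else {})
        if gid != "*":
            gap_uids[gid] = gap.uid

    for lineno, fields in pending_edges:
        if version == 2:
            if len(fields) < 9:
                raise ParseError(f"line {lineno}: E line needs >=9 fields")
            _, eid, ref1, ref2, b1, e1, b2, e2, aln = fields[:9]
            asm.add_edge(_ref_to_end(ref1, 1, seg_uids),
                         _ref_to_end(ref2, 2, seg_uids),
                         overlap_spec=aln,
                         name=None if eid == "*" else eid,
                         coords=(b1, e1, b2, e2),
                         tags=_parse_tags(fields[9:]))
        else:
            if len(fields) < 6:
                raise ParseError(f"line {lineno}: L line needs >=6 fields")
            _, frm, fo, to, to_o, cigar = fields[:6]
            for nm in (frm, to):
                if nm not in seg_uids:
                    raise ParseError(
                        f"line {lineno}: L references undefined segment {nm!r}")
            end1 = SegmentEnd(seg_uids[frm],
                              Side.TAIL if fo == "+" else Side.HEAD)
            end2 = SegmentEnd(seg_uids[to],
                              Side.HEAD if to_o == "+" else Side.TAIL)
            asm.add_edge(end1, end2, overlap_spec=cigar,
                         tags=_parse_tags(fields[6:]))

    for lineno, fields, kind in pending_paths:
        if kind == "O":
            _read_o_line(asm, seg_uids, gap_uids, fields, lineno)
        else:
            _read_p_line(asm, seg_uids, fields, lineno)
    return asm


def _read_s_line(asm, seg_uids, fields, version, lineno):
    if version == 2:
        if len(fields) < 4:
            raise ParseError(f"line {lineno}: GFA2 S line needs >=4 fields")
        _, name, slen, sequence = fields[:4]
        tags = _parse_tags(fields[4:])
        sequence = None if sequence == "*" else sequence
        length = int(slen)
    else:
        if len(fields) < 3:
            raise ParseError(f"line {lineno}: GFA1 S line needs >=3 fields")
        _, name, sequence = fields[:3]
        tags = _parse_tags(fields[3:])
        if sequence == "*":
            sequence = None
            ln_tag = tags.get("LN", "")
            if not ln_tag.startswith("i:"):
                raise ParseError(
                    f"line {lineno}: segment {name!r} has '*' sequence "
                    "and no LN length tag")
            length = int(ln_tag[2:])
        else:
            length = len(sequence)
    if sequence is not None and _seq.first_invalid_char(sequence) >= 0:
        raise ParseError(f"line {lineno}: segment {name!r} has "
                         "non-nucleotide characters")
    qualities = None
    qt = tags.pop(QUAL_TAG, None)
    if qt is not None and qt.startswith("Z:"):
        qualities = qt[2:]
    seg = asm.add_segment(name, sequence, qualities, length=length, tags=tags)
    seg_uids[name] = seg.uid


def _read_o_line(asm, seg_uids, gap_uids, fields, lineno):
    if len(fields) < 3:
        raise ParseError(f"line {lineno}: O line needs >=3 fields")
    _, oid, refs = fields[:3]
    tags = _parse_tags(fields[3:])
    elements = []
    gap_by_name = {g.name: g for g in asm.gaps.values() if g.name}
    for ref in refs.split(" "):
        name, ori = (ref[:-1], ref[-1]) if ref[-1] in "+-" else (ref, "+")
        if name in seg_uids:
            elements.append(PathElement(ElementKind.SEGMENT,
                                        seg_uids[name], ori))
        elif name in gap_by_name:
            elements.append(PathElement(ElementKind.GAP,
                                        gap_by_name[name].uid))
        else:
            raise ParseError(
                f"line {lineno}: O member {ref!r} is neither a segment "
                "nor a gap")
    asm.add_path(oid, elements, tags=tags)


def _read_p_line(asm, seg_uids, fields, lineno):
    if len(fields) < 3:
        raise ParseError(f"line {lineno}: P line needs >=3 fields")
    _, name, members = fields[:3]
    rest = fields[3:]
    if rest and ":" not in rest[0]:
        rest = rest[1:]  # overlaps column, ignored
    tags = _parse_tags(rest)
    gap_lens = None
    gl = tags.pop(GAPLEN_TAG, None)
    if gl is not None and gl.startswith("Z:"):
        gap_lens = gl[2:].split(",")
    member_refs = members.split(",") if members else []
    elements = []
    gi = 0

    def gap_distance(idx):
        if gap_lens is None:
            return 0, True
        tok = gap_lens[idx]
        if tok == ".":
            return None, False
        return (UNKNOWN if tok == "*" else int(tok)), True

    n = len(member_refs)
    # gap_lens layout: lead, g1..g(n-1), trail  (when tag present)
    if gap_lens is not None and len(gap_lens) != n + 1:
        raise ParseError(f"line {lineno}: bad {GAPLEN_TAG} tag arity")
    prev_end = None
    if gap_lens is not None:
        dist, present = gap_distance(0)
        if present:
            first = member_refs[0]
            fe = _ref_to_end(first, 2, seg_uids)
            g = asm.add_gap(None, fe, dist, name=f"{name}.gap{gi + 1}")
            gi += 1
            elements.append(PathElement(ElementKind.GAP, g.uid))
    for i, ref in enumerate(member_refs):
        nm, ori = (ref[:-1], ref[-1]) if ref[-1] in "+-" else (ref, "+")
        if nm not in seg_uids:
            raise ParseError(
                f"line {lineno}: P references undefined segment {nm!r}")
        this_left = _ref_to_end(ref, 2, seg_uids)
        if i > 0:
            dist, present = (gap_distance(i) if gap_lens is not None
                             else (0, True))
            if not present:
                dist = 0
            g = asm.add_gap(prev_end, this_left, dist,
                            name=f"{name}.gap{gi + 1}")
            gi += 1
            elements.append(PathElement(ElementKind.GAP, g.uid))
        elements.append(PathElement(ElementKind.SEGMENT, seg_uids[nm], ori))
        prev_end = _ref_to_end(ref, 1, seg_uids)
    if gap_lens is not None and n:
        dist, present = gap_distance(n)
        if present:
            g = asm.add_gap(prev_end, None, dist, name=f"{name}.gap{gi + 1}")
            elements.append(PathElement(ElementKind.GAP, g.uid))
    asm.add_path(name, elements, tags=tags)


# ---------------------------------------------------------------------------
# GFA writing
# ---------------------------------------------------------------------------

def write_gfa(assembly: Assembly, version: int = 2) -> str:
    """Serialize to GFA2 (lossless) or GFA1 (gaps collapsed, documented).

    Element order is deterministic: header, segments by uid, then edges,
    gaps, paths, then preserved unknown lines.
    """
    if version == 2:
        return _write_gfa2(assembly)
    if version == 1:
        return _write_gfa1(assembly)
    raise ValueError("GFA version must be 1 or 2")


def _write_gfa2(assembly: Assembly) -> str:
    lines = ["H\tVN:Z:2.0" + _fmt_tags(assembly.header_tags, skip=("VN",))]
    for seg in assembly.segments.values():
        tags = dict(seg.tags)
        if seg.qualities is not None:
            tags[QUAL_TAG] = f"Z:{seg.qualities}"
        lines.append(
            f"S\t{seg.name}\t{seg.length}\t{seg.sequence or '*'}"
            + _fmt_tags(tags))
    for i, edge in enumerate(assembly.edges.values(), 1):
        b1, e1, b2, e2 = edge.coords or ("*", "*", "*", "*")
        lines.append(
            f"E\t{edge.name or f'edge{i}'}\t"
            f"{_end_to_ref(edge.end1, 1, assembly)}\t"
            f"{_end_to_ref(edge.end2, 2, assembly)}\t"
            f"{b1}\t{e1}\t{b2}\t{e2}\t{edge.overlap_spec}"
            + _fmt_tags(edge.tags))
    gap_names = {}
    for i, gap in enumerate(assembly.gaps.values(), 1):
        gname = gap.name or f"gap{i}"
        gap_names[gap.uid] = gname
        dist = "*" if gap.distance is UNKNOWN else str(gap.distance)
        lines.append(
            f"G\t{gname}\t{_end_to_ref(gap.end1, 1, assembly)}\t"
            f"{_end_to_ref(gap.end2, 2, assembly)}\t{dist}\t*"
            + _fmt_tags(gap.tags))
    for path in assembly.paths.values():
        refs = []
        for el in path.elements:
            if el.kind is ElementKind.SEGMENT:
                refs.append(assembly.segments[el.uid].name + el.orientation)
            else:
                refs.append(gap_names[el.uid])
        lines.append(f"O\t{path.name}\t{' '.join(refs)}"
                     + _fmt_tags(path.tags))
    lines.extend(assembly.extra_lines)
    return "\n".join(lines) + "\n"


def _write_gfa1(assembly: Assembly) -> str:
    lines = ["H\tVN:Z:1.0" + _fmt_tags(assembly.header_tags, skip=("VN",))]
    for seg in assembly.segments.values():
        tags = dict(seg.tags)
        if seg.qualities is not None:
            tags[QUAL_TAG] = f"Z:{seg.qualities}"
        if seg.sequence is None:
            tags.setdefault("LN", f"i:{seg.length}")
        lines.append(f"S\t{seg.name}\t{seg.sequence or '*'}"
                     + _fmt_tags(tags))
    for edge in assembly.edges.values():
        fo = "+" if edge.end1.side is Side.TAIL else "-"
        to = "+" if edge.end2.side is Side.HEAD else "-"
        lines.append(
            f"L\t{assembly.segments[edge.end1.segment_uid].name}\t{fo}\t"
            f"{assembly.segments[edge.end2.segment_uid].name}\t{to}\t"
            f"{edge.overlap_spec}" + _fmt_tags(edge.tags))
    for path in assembly.paths.values():
        members = []
        gap_tokens = []
        lead = "."
        trail = "."
        pending = None
        for el in path.elements:
            if el.kind is ElementKind.SEGMENT:
                if pending is not None and not members:
                    lead = pending
                elif members:
                    gap_tokens.append(pending if pending is not None else "0")
                pending = None
                members.append(assembly.segments[el.uid].name
                               + el.orientation)
            else:
                gap = assembly.gaps[el.uid]
                pending = "*" if gap.distance is UNKNOWN else str(gap.distance)
        if pending is not None:
            trail = pending
        gl = ",".join([lead] + gap_tokens + [trail])
        tags = dict(path.tags)
        tags[GAPLEN_TAG] = f"Z:{gl}"
        lines.append(f"P\t{path.name}\t{','.join(members)}\t*"
                     + _fmt_tags(tags))
    lines.extend(assembly.extra_lines)
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# AGP / BED / sizes
# ---------------------------------------------------------------------------

def write_agp(assembly: Assembly,
              unknown_gap_len: int = DEFAULT_UNKNOWN_GAP_LEN) -> str:
    """AGP v2.1: W rows for components, N rows for sized gaps, U for unknown.

    Coordinates are 1-based inclusive; rows of one scaffold tile its full
    length without overlap. Zero-length gaps produce no row.
    """
    lines = ["##agp-version\t2.1"]
    for path in assembly.paths.values():
        pos = 0  # 0-based running coordinate
        part = 1
        for el in path.elements:
            if el.kind is ElementKind.SEGMENT:
                seg = assembly.segments[el.uid]
                lines.append("\t".join([
                    path.name, str(pos + 1), str(pos + seg.length),
                    str(part), "W", seg.name, "1", str(seg.length),
                    el.orientation]))
                pos += seg.length
                part += 1
            else:
                gap = assembly.gaps[el.uid]
                glen = gap.length(unknown_gap_len)
                if glen == 0:
                    continue
                ctype = "U" if gap.distance is UNKNOWN else "N"
                lines.append("\t".join([
                    path.name, str(pos + 1), str(pos + glen), str(part),
                    ctype, str(glen), "scaffold", "yes", "unspecified"]))
                pos += glen
                part += 1
    return "\n".join(lines) + "\n"


def write_bed(assembly: Assembly, feature: str = "GAPS",
              unknown_gap_len: int = DEFAULT_UNKNOWN_GAP_LEN) -> str:
    """BED3+1 on scaffold coordinates, 0-based half-open."""
    feature = feature.upper()
    if feature not in ("SEGMENTS", "GAPS", "SCAFFOLDS"):
        raise ValueError(f"unknown BED feature {feature!r}")
    lines = []
    for path in assembly.paths.values():
        if feature == "SCAFFOLDS":
            total = assembly.path_length(path, unknown_gap_len)
            if total > 0:
                lines.append(f"{path.name}\t0\t{total}\t{path.name}")
            continue
        pos = 0
        for el in path.elements:
            if el.kind is ElementKind.SEGMENT:
                seg = assembly.segments[el.uid]
                if feature == "SEGMENTS" and seg.length > 0:
                    lines.append(f"{path.name}\t{pos}\t{pos + seg.length}"
                                 f"\t{seg.name}")
                pos += seg.length
            else:
                gap = assembly.gaps[el.uid]
                glen = gap.length(unknown_gap_len)
                if feature == "GAPS" and glen > 0:
                    lines.append(f"{path.name}\t{pos}\t{pos + glen}"
                                 f"\t{gap.name or f'gap{gap.uid}'}")
                pos += glen
    return "\n".join(lines) + ("\n" if lines else "")


def write_sizes(assembly: Assembly, tier: str = "SCAFFOLD",
                unknown_gap_len: int = DEFAULT_UNKNOWN_GAP_LEN) -> str:
    """Two-column name/length TSV for one tier, in assembly order."""
    tier = tier.upper()
    lines = []
    if tier == "SCAFFOLD":
        for path in assembly.paths.values():
            lines.append(f"{path.name}\t"
                         f"{assembly.path_length(path, unknown_gap_len)}")
    elif tier == "CONTIG":
        for seg in assembly.segments.values():
            lines.append(f"{seg.name}\t{seg.length}")
    elif tier == "GAP":
        for gap in assembly.gaps.values():
            lines.append(f"{gap.name or f'gap{gap.uid}'}\t"
                         f"{gap.length(unknown_gap_len)}")
    else:
        raise ValueError(f"unknown sizes tier {tier!r}")
    return "\n".join(lines) + ("\n" if lines else "")


# ---------------------------------------------------------------------------
# Generic entry points
# ---------------------------------------------------------------------------

def read(source, dialect: Optional[FormatDialect] = None) -> Assembly:
    """Read any supported sequence format, sniffing the dialect."""
    if isinstance(source, str):
        with open(source, "rb") as fh:
            data = fh.read()
    elif isinstance(source, bytes):
        data = source
    else:
        data = source.read()
        if isinstance(data, str):
            data = data.encode()
    if dialect is None:
        dialect = detect_format(data)
    reader = {"FASTA": read_fasta, "FASTQ": read_fastq,
              "GFA1": read_gfa, "GFA2": read_gfa}[dialect.kind]
    return reader(data, dialect)


def write(assembly: Assembly, path: str, out_format: str, **kwargs) -> None:
    """Write to a file; a ``.gz`` suffix gzip-compresses sequence formats."""
    text = to_text(assembly, out_format, **kwargs)
    if path.endswith(".gz"):
        with gzip.open(path, "wt") as fh:
            fh.write(text)
    else:
        with open(path, "w") as fh:
            fh.write(text)


def to_text(assembly: Assembly, out_format: str, **kwargs) -> str:
    """Serialize to one of fasta|fastq|gfa|gfa2|agp|bed|sizes."""
    fmt = out_format.lower()
    if fmt == "fasta":
        return write_fasta(assembly, **kwargs)
    if fmt == "fastq":
        return write_fastq(assembly, **kwargs)
    if fmt in ("gfa", "gfa1"):
        return write_gfa(assembly, version=1, **kwargs)
    if fmt == "gfa2":
        return write_gfa(assembly, version=2, **kwargs)
    if fmt == "agp":
        return write_agp(assembly, **kwargs)
    if fmt == "bed":
        return write_bed(assembly, **kwargs)
    if fmt == "sizes":
        return write_sizes(assembly, **kwargs)
    raise ValueError(f"unknown output format {out_format!r}")
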