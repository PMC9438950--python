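"""The "swiss army knife" (SAK): a sequential, human-readable edit script
executed against the assembly graph, doubling as a change log.

One instruction per line, ``#`` comments, verbs case-insensitive::

    JOIN    scaffold1[+|-] scaffold2[+|-] [gap_len|*] [new_name]
    SPLIT   segment1 segment2          # delete the gap between adjacent contigs
    EXCISE  segment [gap_len|*]        # pop a contig out of its scaffold
    REMOVE  segment                    # EXCISE then delete the contig
    ERASE   scaffold start-end         # delete a 0-based half-open range
    RVCP    name                       # reverse-complement scaffold or contig
    INVERT  segment                    # flip one contig's orientation in place
    TRIM_NS [scaffold]                 # drop terminal gap edges (all if omitted)
    RENAME  old new

Execution is transactional: any error aborts the whole run and the input
assembly is returned unchanged. Replaying the change log's raw
instructions on the original assembly reproduces the edited one.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from . import seq as _seq
from .model import (
    Assembly,
    DEFAULT_UNKNOWN_GAP_LEN,
    ElementKind,
    Path,
    PathElement,
    UNKNOWN,
    _unique_name,
    left_end,
    right_end,
)

VERBS = {
    "JOIN": (2, 4),
    "SPLIT": (2, 2),
    "EXCISE": (1, 2),
    "REMOVE": (1, 1),
    "ERASE": (2, 2),
    "RVCP": (1, 1),
    "INVERT": (1, 1),
    "TRIM_NS": (0, 1),
    "RENAME": (2, 2),
}


class SakParseError(ValueError):
    """Unknown verb or wrong arity; message names the line."""


class SakExecutionError(ValueError):
    """Failure applying an instruction; message cites its 1-based index."""


@dataclass
class Instruction:
    verb: str
    operands: list
    raw_text: str


@dataclass
class ChangeLogEntry:
    index: int
    instruction: str
    effect: str
    elements_created: list = field(default_factory=list)
    elements_deleted: list = field(default_factory=list)


def parse_script(text: str) -> list:
    """Parse a whole script; all-or-nothing (no partial scripts)."""
    instructions = []
    for lineno, line in enumerate(text.splitlines(), 1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        verb = parts[0].upper()
        if verb not in VERBS:
            raise SakParseError(f"line {lineno}: unknown instruction "
                                f"{parts[0]!r}")
        lo, hi = VERBS[verb]
        nops = len(parts) - 1
        if not lo <= nops <= hi:
            raise SakParseError(
                f"line {lineno}: {verb} takes {lo}-{hi} operands, got {nops}")
        instructions.append(Instruction(verb, parts[1:], line))
    return instructions


def execute(assembly: Assembly, script,
            unknown_gap_len: int = DEFAULT_UNKNOWN_GAP_LEN):
    """Run a script (text or parsed) in order; returns (Assembly, log).

    The input assembly is never modified; on any execution error the
    whole run is aborted (transactional semantics).
    """
    if isinstance(script, str):
        script = parse_script(script)
    asm = assembly.copy()
    log = []
    for i, ins in enumerate(script, 1):
        try:
            effect, created, deleted = _DISPATCH[ins.verb](
                asm, ins.operands, unknown_gap_len)
        except (KeyError, ValueError, IndexError) as exc:
            raise SakExecutionError(
                f"instruction {i} ({ins.raw_text!r}): {exc}") from exc
        log.append(ChangeLogEntry(i, ins.raw_text, effect, created, deleted))
    return asm, log


def format_log(log) -> str:
    """Change log as TSV: index, instruction, effect, created, deleted."""
    lines = ["index\tinstruction\teffect\tcreated\tdeleted"]
    for e in log:
        lines.append("\t".join([
            str(e.index), e.instruction, e.effect,
            ",".join(e.elements_created), ",".join(e.elements_deleted)]))
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Shared helpers
# ---------------------------------------------------------------------------

def _need_path(asm: Assembly, name: str) -> Path:
    p = asm.path_by_name(name)
    if p is None:
        raise SakExecutionError(f"no scaffold named {name!r}")
    return p


def _need_segment(asm: Assembly, name: str):
    s = asm.segment_by_name(name)
    if s is None:
        raise SakExecutionError(f"no segment named {name!r}")
    return s


def _parse_end_spec(spec: str):
    if spec and spec[-1] in "+-":
        return spec[:-1], spec[-1]
    return spec, "+"


def _parse_gap_len(token: str):
    if token == "*":
        return UNKNOWN
    n = int(token)
    if n < 0:
        raise SakExecutionError("gap length must be >= 0 or *")
    return n


def _refresh_gap_ends(asm: Assembly, path: Path) -> None:
    """Recompute end attachments of every gap element from its neighbors."""
    els = path.elements
    for i, el in enumerate(els):
        if el.kind is not ElementKind.GAP:
            continue
        gap = asm.gaps[el.uid]
        prev = els[i - 1] if i > 0 else None
        nxt = els[i + 1] if i + 1 < len(els) else None
        gap.end1 = (right_end(prev.uid, prev.orientation)
                    if prev is not None else None)
        gap.end2 = (left_end(nxt.uid, nxt.orientation)
                    if nxt is not None else None)


def _rvcp_elements(path: Path) -> None:
    path.elements.reverse()
    for el in path.elements:
        if el.kind is ElementKind.SEGMENT:
            el.orientation = "-" if el.orientation == "+" else "+"


def _delete_path(asm: Assembly, path: Path) -> None:
    del asm.paths[path.uid]


def _drop_gap_element(asm: Assembly, path: Path, idx: int) -> str:
    el = path.elements.pop(idx)
    gap = asm.gaps.pop(el.uid)
    return gap.name or f"gap{gap.uid}"


# ---------------------------------------------------------------------------
# Verb implementations
# ---------------------------------------------------------------------------

def op_join(asm, operands, unknown_gap_len=DEFAULT_UNKNOWN_GAP_LEN):
    """Merge two scaffolds end-to-end across a new gap.

    A ``-`` suffix reverse-complements that scaffold before joining; the
    join always happens between the first scaffold's right end and the
    second's left end (post-flip).
    """
    name_a, ori_a = _parse_end_spec(operands[0])
    name_b, ori_b = _parse_end_spec(operands[1])
    gap_len = _parse_gap_len(operands[2]) if len(operands) > 2 else UNKNOWN
    path_a = _need_path(asm, name_a)
    path_b = _need_path(asm, name_b)
    if path_a.uid == path_b.uid:
        raise SakExecutionError(f"cannot join {name_a!r} to itself")
    new_name = operands[3] if len(operands) > 3 else path_a.name
    if ori_a == "-":
        _rvcp_elements(path_a)
    if ori_b == "-":
        _rvcp_elements(path_b)
    for p, side in ((path_a, -1), (path_b, 0)):
        if not p.elements:
            raise SakExecutionError(f"scaffold {p.name!r} is empty")
        if p.elements[side].kind is ElementKind.GAP:
            raise SakExecutionError(
                f"scaffold {p.name!r} has a terminal gap at the join end; "
                "TRIM_NS first")
    gap = asm.add_gap(distance=gap_len,
                      name=_fresh_gap_name(asm, new_name))
    joined = (path_a.elements
              + [PathElement(ElementKind.GAP, gap.uid)]
              + path_b.elements)
    deleted = [path_a.name, path_b.name]
    _delete_path(asm, path_a)
    _delete_path(asm, path_b)
    new_path = asm.add_path(_unique_name(new_name, asm._path_names()), joined)
    _refresh_gap_ends(asm, new_path)
    glen = "*" if gap_len is UNKNOWN else gap_len
    return (f"joined {name_a}{ori_a} and {name_b}{ori_b} with gap {glen} "
            f"as {new_path.name}", [new_path.name], deleted)


def op_split(asm, operands, unknown_gap_len=DEFAULT_UNKNOWN_GAP_LEN):
    """Delete the gap between two adjacent contigs; the scaffold splits."""
    seg1 = _need_segment(asm, operands[0])
    seg2 = _need_segment(asm, operands[1])
    path = asm.path_of_segment(seg1.uid)
    if path is None or asm.path_of_segment(seg2.uid) is not path:
        raise SakExecutionError(
            f"{operands[0]!r} and {operands[1]!r} are not in one scaffold")
    els = path.elements
    idx = None
    for i in range(len(els) - 2):
        trio = els[i:i + 3]
        if (trio[0].kind is ElementKind.SEGMENT
                and trio[1].kind is ElementKind.GAP
                and trio[2].kind is ElementKind.SEGMENT
                and {trio[0].uid, trio[2].uid} == {seg1.uid, seg2.uid}):
            idx = i
            break
    if idx is None:
        raise SakExecutionError(
            f"{operands[0]!r} and {operands[1]!r} are not adjacent")
    gap_name = _drop_gap_element(asm, path, idx + 1)
    left_els = els[:idx + 1]
    right_els = els[idx + 1:]
    base = path.name
    _delete_path(asm, path)
    p1 = asm.add_path(_unique_name(f"{base}.1", asm._path_names()), left_els)
    p2 = asm.add_path(_unique_name(f"{base}.2", asm._path_names()), right_els)
    _refresh_gap_ends(asm, p1)
    _refresh_gap_ends(asm, p2)
    return (f"split {base} between {operands[0]} and {operands[1]}",
            [p1.name, p2.name], [base, gap_name])


def _detach_segment(asm, seg, gap_len, keep_singleton, unknown_gap_len):
    path = asm.path_of_segment(seg.uid)
    created, deleted = [], []
    if path is not None:
        els = path.elements
        i = next(k for k, el in enumerate(els)
                 if el.kind is ElementKind.SEGMENT and el.uid == seg.uid)
        lo = i - 1 if i > 0 else i
        hi = i + 1 if i + 1 < len(els) else i
        # the removal span: the segment plus adjacent gap elements
        for k in range(hi, lo - 1, -1):
            el = els[k]
            if el.kind is ElementKind.GAP:
                deleted.append(_drop_gap_element(asm, path, k))
            else:
                els.pop(k)
        # insert replacement gap only when contigs remain on both sides
        j = lo  # position where span was removed
        has_left = j > 0 and els[j - 1].kind is ElementKind.SEGMENT
        has_right = j < len(els) and els[j].kind is ElementKind.SEGMENT
        if has_left and has_right:
            gap = asm.add_gap(distance=gap_len,
                              name=_fresh_gap_name(asm, path.name))
            els.insert(j, PathElement(ElementKind.GAP, gap.uid))
            created.append(gap.name)
        if any(el.kind is ElementKind.SEGMENT for el in els):
            _refresh_gap_ends(asm, path)
        else:
            for el in list(els):  # only stray gaps left
                deleted.append(_drop_gap_element(asm, path, 0))
            deleted.append(path.name)
            _delete_path(asm, path)
    if keep_singleton:
        p = asm.add_path(_unique_name(seg.name, asm._path_names()),
                         [PathElement(ElementKind.SEGMENT, seg.uid)])
        created.append(p.name)
    else:
        del asm.segments[seg.uid]
        deleted.append(seg.name)
    return created, deleted


def op_excise(asm, operands, unknown_gap_len=DEFAULT_UNKNOWN_GAP_LEN):
    """Pop a contig out of its scaffold, leaving one replacement gap.

    The contig stays in the assembly as a singleton scaffold.
    """
    seg = _need_segment(asm, operands[0])
    gap_len = _parse_gap_len(operands[1]) if len(operands) > 1 else UNKNOWN
    created, deleted = _detach_segment(asm, seg, gap_len, True,
                                       unknown_gap_len)
    return f"excised {seg.name}", created, deleted


def op_remove(asm, operands, unknown_gap_len=DEFAULT_UNKNOWN_GAP_LEN):
    """EXCISE then delete the contig entirely."""
    seg = _need_segment(asm, operands[0])
    created, deleted = _detach_segment(asm, seg, UNKNOWN, False,
                                       unknown_gap_len)
    return f"removed {seg.name}", created, deleted


def op_erase(asm, operands, unknown_gap_len=DEFAULT_UNKNOWN_GAP_LEN):
    """Delete a 0-based half-open coordinate range within one scaffold.

    Contigs fully inside the range are deleted; partially covered contigs
    are truncated (a cut strictly inside one contig leaves two pieces
    joined by a 0-length gap). Gap lengths shrink by the overlap.
    """
    path = _need_path(asm, operands[0])
    try:
        a_s, _, b_s = operands[1].partition("-")
        start, end = int(a_s), int(b_s)
    except ValueError:
        raise SakExecutionError(
            f"bad range {operands[1]!r}; expected start-end")
    total = asm.path_length(path, unknown_gap_len)
    if not (0 <= start < end <= total):
        raise SakExecutionError(
            f"range {start}-{end} out of bounds for {path.name!r} "
            f"(length {total})")
    created, deleted = [], []
    items = []  # ('S', seq, qual, keep_el) | ('G', dist, gap_uid_or_None)
    pos = 0
    for el in path.elements:
        if el.kind is ElementKind.SEGMENT:
            seg = asm.segments[el.uid]
            length = seg.length
        else:
            gap = asm.gaps[el.uid]
            length = gap.length(unknown_gap_len)
        a, b = pos, pos + length
        pos = b
        keep = []
        if a < start:
            keep.append((a, min(b, start)))
        if b > end:
            keep.append((max(a, end), b))
        if keep == [(a, b)]:
            items.append(("KEEP", el))
            continue
        if el.kind is ElementKind.GAP:
            kept = sum(rb - ra for ra, rb in keep)
            deleted.append(_gap_label(asm.gaps[el.uid]))
            del asm.gaps[el.uid]
            if kept > 0:
                items.append(("G", kept))
            continue
        # segment: slice in path orientation
        seg = asm.segments[el.uid]
        if seg.sequence is None:
            raise SakExecutionError(
                f"segment {seg.name!r} has no sequence; cannot ERASE "
                "through it")
        oseq = (seg.sequence if el.orientation == "+"
                else _seq.revcomp(seg.sequence))
        oqual = seg.qualities if el.orientation == "+" else (
            seg.qualities[::-1] if seg.qualities is not None else None)
        pieces = [(oseq[ra - a:rb - a],
                   oqual[ra - a:rb - a] if oqual is not None else None)
                  for ra, rb in keep]
        deleted.append(seg.name)
        del asm.segments[seg.uid]
        for k, (pseq, pqual) in enumerate(pieces):
            if not pseq:
                continue
            nm = _unique_name(f"{seg.name}.{k + 1}", asm._segment_names())
            new_seg = asm.add_segment(nm, pseq, pqual)
            created.append(nm)
            items.append(("S", new_seg.uid))
            if k == 0 and len(pieces) == 2 and pieces[1][0]:
                items.append(("G", 0))  # interior cut: 0-length join
    # reassemble with strict alternation; merge touching gap remnants
    new_els = []

    def _merge_into_last_gap(extra_len):
        g = asm.gaps[new_els[-1].uid]
        g.distance = g.length(unknown_gap_len) + extra_len

    for item in items:
        if item[0] == "KEEP":
            el = item[1]
            if new_els and new_els[-1].kind is el.kind:
                if el.kind is ElementKind.SEGMENT:
                    new_els.append(_new_zero_gap(asm, path, created))
                else:
                    gap = asm.gaps.pop(el.uid)
                    deleted.append(_gap_label(gap))
                    _merge_into_last_gap(gap.length(unknown_gap_len))
                    continue
            new_els.append(el)
        elif item[0] == "S":
            if new_els and new_els[-1].kind is ElementKind.SEGMENT:
                new_els.append(_new_zero_gap(asm, path, created))
            new_els.append(PathElement(ElementKind.SEGMENT, item[1]))
        else:  # G: remnant of a partly erased gap
            if new_els and new_els[-1].kind is ElementKind.GAP:
                _merge_into_last_gap(item[1])
                continue
            gap = asm.add_gap(distance=item[1],
                              name=_fresh_gap_name(asm, path.name))
            created.append(gap.name)
            new_els.append(PathElement(ElementKind.GAP, gap.uid))
    # drop meaningless zero-length terminal gaps
    while new_els and new_els[0].kind is ElementKind.GAP \
            and asm.gaps[new_els[0].uid].distance == 0:
        deleted.append(_drop_gap_element_from(asm, new_els, 0))
    while new_els and new_els[-1].kind is ElementKind.GAP \
            and asm.gaps[new_els[-1].uid].distance == 0:
        deleted.append(_drop_gap_element_from(asm, new_els, len(new_els) - 1))
    path.elements = new_els
    if not new_els:
        deleted.append(path.name)
        _delete_path(asm, path)
    else:
        _refresh_gap_ends(asm, path)
    return (f"erased {path.name}:{start}-{end}", created, deleted)


def _gap_label(gap):
    return gap.name or f"gap{gap.uid}"


def _drop_gap_element_from(asm, els, idx):
    el = els.pop(idx)
    gap = asm.gaps.pop(el.uid)
    return _gap_label(gap)


def _fresh_gap_name(asm, base):
    taken = {g.name for g in asm.gaps.values() if g.name}
    i = 1
    while f"{base}.xgap{i}" in taken:
        i += 1
    return f"{base}.xgap{i}"


def _new_zero_gap(asm, path, created):
    gap = asm.add_gap(distance=0, name=_fresh_gap_name(asm, path.name))
    created.append(gap.name)
    return PathElement(ElementKind.GAP, gap.uid)


def op_rvcp(asm, operands, unknown_gap_len=DEFAULT_UNKNOWN_GAP_LEN):
    """Reverse-complement a scaffold (flip walk) or a contig (flip bases).

    For a contig inside a scaffold the stored bases are flipped *and* its
    path orientation flag is flipped, so the scaffold sequence is
    unchanged; on a standalone/singleton contig the bases flip.
    """
    name = operands[0]
    path = asm.path_by_name(name)
    if path is not None and not (
            len(path.elements) == 1
            and path.elements[0].kind is ElementKind.SEGMENT
            and asm.segments[path.elements[0].uid].name == name):
        _rvcp_elements(path)
        _refresh_gap_ends(asm, path)
        return f"reverse-complemented scaffold {name}", [], []
    seg = asm.segment_by_name(name)
    if seg is None:
        if path is not None:
            seg = asm.segments[path.elements[0].uid]
        else:
            raise SakExecutionError(f"no scaffold or segment named {name!r}")
    if seg.sequence is None:
        raise SakExecutionError(f"segment {name!r} has no stored sequence")
    seg.sequence = _seq.revcomp(seg.sequence)
    if seg.qualities is not None:
        seg.qualities = seg.qualities[::-1]
    owner = asm.path_of_segment(seg.uid)
    if owner is not None and len(owner.segment_uids()) > 1:
        for el in owner.elements:
            if el.kind is ElementKind.SEGMENT and el.uid == seg.uid:
                el.orientation = "-" if el.orientation == "+" else "+"
        _refresh_gap_ends(asm, owner)
    return f"reverse-complemented segment {seg.name}", [], []


def op_invert(asm, operands, unknown_gap_len=DEFAULT_UNKNOWN_GAP_LEN):
    """Flip one contig's orientation within its scaffold (stored bases
    unchanged; the linearized scaffold changes)."""
    seg = _need_segment(asm, operands[0])
    path = asm.path_of_segment(seg.uid)
    if path is None:
        raise SakExecutionError(f"segment {seg.name!r} is not in a scaffold")
    for el in path.elements:
        if el.kind is ElementKind.SEGMENT and el.uid == seg.uid:
            el.orientation = "-" if el.orientation == "+" else "+"
    _refresh_gap_ends(asm, path)
    return f"inverted {seg.name} in {path.name}", [], []


def op_trim_ns(asm, operands, unknown_gap_len=DEFAULT_UNKNOWN_GAP_LEN):
    """Drop all terminal gap edges of one scaffold (or of every scaffold)."""
    targets = ([_need_path(asm, operands[0])] if operands
               else list(asm.paths.values()))
    deleted = []
    for path in targets:
        while path.elements and path.elements[0].kind is ElementKind.GAP:
            deleted.append(_drop_gap_element(asm, path, 0))
        while path.elements and path.elements[-1].kind is ElementKind.GAP:
            deleted.append(_drop_gap_element(asm, path,
                                             len(path.elements) - 1))
        if not path.elements:
            deleted.append(path.name)
            _delete_path(asm, path)
        else:
            _refresh_gap_ends(asm, path)
    scope = operands[0] if operands else "all scaffolds"
    return f"trimmed terminal gaps of {scope}", [], deleted


def op_rename(asm, operands, unknown_gap_len=DEFAULT_UNKNOWN_GAP_LEN):
    """Rename a scaffold or a segment; name uniqueness enforced."""
    old, new = operands
    path = asm.path_by_name(old)
    if path is not None:
        if new in asm._path_names():
            raise SakExecutionError(f"path name {new!r} already in use")
        path.name = new
        return f"renamed scaffold {old} to {new}", [new], [old]
    seg = asm.segment_by_name(old)
    if seg is None:
        raise SakExecutionError(f"no scaffold or segment named {old!r}")
    if new in asm._segment_names():
        raise SakExecutionError(f"segment name {new!r} already in use")
    seg.name = new
    return f"renamed segment {old} to {new}", [new], [old]


_DISPATCH = {
    "JOIN": op_join,
    "SPLIT": op_split,
    "EXCISE": op_excise,
    "REMOVE": op_remove,
    "ERASE": op_erase,
    "RVCP": op_rvcp,
    "INVERT": op_invert,
    "TRIM_NS": op_trim_ns,
    "RENAME": op_rename,
}
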