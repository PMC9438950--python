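"""Unified GFA2-like in-memory assembly model and its bidirected graph.

An :class:`Assembly` holds segments (contigs), gaps, overlap edges and
paths (scaffolds). A scaffold is an ordered, oriented walk alternating
SEGMENT and GAP elements; abutting contigs are joined by an explicit
0-length gap so the alternation is strict and one conservation law holds:

    scaffold length = sum(segment lengths) + sum(gap lengths)

with unknown-length gaps counted at a configurable placeholder (100 bp by
default, the AGP "U" convention).

The bidirected graph view (:func:`build_graph`) has one node per segment
and one undirected edge per gap/overlap, attached to specific segment ends
(HEAD = 5' in + orientation, TAIL = 3'). Terminal gaps attach on one side
only; the other side is open.
"""

from __future__ import annotations

import copy
import enum
from dataclasses import dataclass, field
from typing import Iterable, Optional

from . import seq as _seq

#: Sentinel for a gap of unknown length (GFA2 distance "*").
UNKNOWN = None

#: Number of N characters emitted for an unknown gap on linearization.
DEFAULT_UNKNOWN_GAP_LEN = 100


class Side(enum.Enum):
    """Which end of a segment an edge attaches to."""

    HEAD = "head"
    TAIL = "tail"

    def flipped(self) -> "Side":
        return Side.TAIL if self is Side.HEAD else Side.HEAD


@dataclass(frozen=True)
class SegmentEnd:
    segment_uid: int
    side: Side


class ElementKind(enum.Enum):
    SEGMENT = "segment"
    GAP = "gap"


@dataclass
class Segment:
    """A contig: contiguous nucleotide sequence without unknown bases."""

    uid: int
    name: str
    sequence: Optional[str] = None
    qualities: Optional[str] = None
    length: int = 0
    tags: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.sequence is not None and self.length == 0:
            self.length = len(self.sequence)


@dataclass
class Gap:
    """A junction of unknown sequence between (or flanking) segment ends.

    ``distance`` is a non-negative int or UNKNOWN. A terminal gap has
    exactly one attached end (the other is ``None`` = open side).
    """

    uid: int
    name: Optional[str] = None
    end1: Optional[SegmentEnd] = None
    end2: Optional[SegmentEnd] = None
    distance: Optional[int] = 0
    tags: dict = field(default_factory=dict)

    @property
    def is_terminal(self) -> bool:
        return (self.end1 is None) != (self.end2 is None)

    def length(self, unknown_gap_len: int = DEFAULT_UNKNOWN_GAP_LEN) -> int:
        return unknown_gap_len if self.distance is UNKNOWN else self.distance


@dataclass
class OverlapEdge:
    uid: int
    end1: SegmentEnd
    end2: SegmentEnd
    overlap_spec: str = "*"
    name: Optional[str] = None
    coords: Optional[tuple] = None  # raw GFA2 beg/end fields, round-trip only
    tags: dict = field(default_factory=dict)


@dataclass
class PathElement:
    kind: ElementKind
    uid: int
    orientation: str = "+"  # '+' or '-'; gaps are always '+'


@dataclass
class Path:
    """One scaffold: an ordered, oriented walk over segments and gaps."""

    uid: int
    name: str
    elements: list = field(default_factory=list)
    tags: dict = field(default_factory=dict)

    def segment_uids(self) -> list:
        return [e.uid for e in self.elements if e.kind is ElementKind.SEGMENT]


class AssemblyError(ValueError):
    """Structural error in an assembly (dangling reference, bad invariant)."""


class Assembly:
    """Container for segments, gaps, overlap edges and paths.

    uids are dense integers in encounter order, one space per element
    class, stable across edits; names are the user-facing handles.
    """

    def __init__(self):
        self.segments: dict = {}
        self.gaps: dict = {}
        self.edges: dict = {}
        self.paths: dict = {}
        self.header_tags: dict = {}
        self.extra_lines: list = []  # unknown GFA line types, verbatim
        self._next_uid = {"segment": 0, "gap": 0, "edge": 0, "path": 0}

    # -- construction -------------------------------------------------

    def add_segment(self, name, sequence=None, qualities=None, length=None,
                    tags=None) -> Segment:
        if name in self._segment_names():
            raise AssemblyError(f"duplicate segment name {name!r}")
        uid = self._take_uid("segment")
        seg = Segment(uid, name, sequence, qualities,
                      length if length is not None else
                      (len(sequence) if sequence is not None else 0),
                      tags or {})
        self.segments[uid] = seg
        return seg

    def add_gap(self, end1=None, end2=None, distance=0, name=None,
                tags=None) -> Gap:
        uid = self._take_uid("gap")
        gap = Gap(uid, name, end1, end2, distance, tags or {})
        self.gaps[uid] = gap
        return gap

    def add_edge(self, end1, end2, overlap_spec="*", name=None, coords=None,
                 tags=None) -> OverlapEdge:
        uid = self._take_uid("edge")
        edge = OverlapEdge(uid, end1, end2, overlap_spec, name, coords,
                           tags or {})
        self.edges[uid] = edge
        return edge

    def add_path(self, name, elements=None, tags=None) -> Path:
        if name in self._path_names():
            raise AssemblyError(f"duplicate path name {name!r}")
        uid = self._take_uid("path")
        path = Path(uid, name, elements or [], tags or {})
        self.paths[uid] = path
        return path

    def _take_uid(self, kind: str) -> int:
        uid = self._next_uid[kind]
        self._next_uid[kind] = uid + 1
        return uid

    # -- lookup -------------------------------------------------------

    def _segment_names(self):
        return {s.name for s in self.segments.values()}

    def _path_names(self):
        return {p.name for p in self.paths.values()}

    def segment_by_name(self, name) -> Optional[Segment]:
        for s in self.segments.values():
            if s.name == name:
                return s
        return None

    def path_by_name(self, name) -> Optional[Path]:
        for p in self.paths.values():
            if p.name == name:
                return p
        return None

    def gap_by_name(self, name) -> Optional[Gap]:
        for g in self.gaps.values():
            if g.name == name:
                return g
        return None

    def path_of_segment(self, segment_uid: int) -> Optional[Path]:
        for p in self.paths.values():
            if segment_uid in p.segment_uids():
                return p
        return None

    def singleton_segments(self) -> list:
        """Segments that appear in no path."""
        in_paths = set()
        for p in self.paths.values():
            in_paths.update(p.segment_uids())
        return [s for s in self.segments.values() if s.uid not in in_paths]

    # -- derived quantities -------------------------------------------

    def path_length(self, path: Path,
                    unknown_gap_len: int = DEFAULT_UNKNOWN_GAP_LEN) -> int:
        total = 0
        for el in path.elements:
            if el.kind is ElementKind.SEGMENT:
                total += self.segments[el.uid].length
            else:
                total += self.gaps[el.uid].length(unknown_gap_len)
        return total

    def linearize(self, path: Path,
                  unknown_gap_len: int = DEFAULT_UNKNOWN_GAP_LEN) -> str:
        """Render one scaffold to a nucleotide string (gaps become Ns)."""
        parts = []
        for el in path.elements:
            if el.kind is ElementKind.SEGMENT:
                seg = self.segments[el.uid]
                if seg.sequence is None:
                    raise AssemblyError(
                        f"segment {seg.name!r} has no stored sequence; "
                        "cannot linearize")
                parts.append(seg.sequence if el.orientation == "+"
                             else _seq.revcomp(seg.sequence))
            else:
                parts.append("N" * self.gaps[el.uid].length(unknown_gap_len))
        return "".join(parts)

    def linearize_qualities(self, path: Path, gap_qual: str = "!",
                            unknown_gap_len: int = DEFAULT_UNKNOWN_GAP_LEN) -> str:
        parts = []
        for el in path.elements:
            if el.kind is ElementKind.SEGMENT:
                seg = self.segments[el.uid]
                qual = seg.qualities if seg.qualities is not None \
                    else "!" * seg.length
                parts.append(qual if el.orientation == "+" else qual[::-1])
            else:
                parts.append(gap_qual * self.gaps[el.uid].length(unknown_gap_len))
        return "".join(parts)

    def copy(self) -> "Assembly":
        return copy.deepcopy(self)

    def __repr__(self):
        return (f"Assembly({len(self.segments)} segments, "
                f"{len(self.gaps)} gaps, {len(self.edges)} edges, "
                f"{len(self.paths)} paths)")


# ---------------------------------------------------------------------------
# Bidirected graph
# ---------------------------------------------------------------------------

GAP_EDGE = "GAP"
OVERLAP_EDGE = "OVERLAP"


class AssemblyGraph:
    """Adjacency-list view: SegmentEnd -> [(edge_kind, edge_uid, other_end)].

    Every end of every segment is a key (possibly with an empty list), so
    the node count equals the segment count. Terminal gaps are listed once,
    with ``other_end`` None.
    """

    def __init__(self):
        self.adjacency: dict = {}

    def degree(self, end: SegmentEnd, internal_only: bool = True) -> int:
        entries = self.adjacency.get(end, [])
        if internal_only:
            return sum(1 for _, _, other in entries if other is not None)
        return len(entries)

    def segment_uids(self) -> list:
        return sorted({e.segment_uid for e in self.adjacency})


def build_graph(assembly: Assembly) -> AssemblyGraph:
    """Build the bidirected adjacency-list graph over segment ends.

    One undirected edge per gap/overlap: both attached ends list it
    (symmetry invariant); terminal gaps appear on their single attached
    end with an open other side.
    """
    graph = AssemblyGraph()
    for seg in assembly.segments.values():
        graph.adjacency[SegmentEnd(seg.uid, Side.HEAD)] = []
        graph.adjacency[SegmentEnd(seg.uid, Side.TAIL)] = []

    def attach(kind, uid, end1, end2, label):
        for me, other in ((end1, end2), (end2, end1)):
            if me is None:
                continue
            if me not in graph.adjacency:
                raise AssemblyError(
                    f"{label} {uid} references missing segment end {me}")
            graph.adjacency[me].append((kind, uid, other))

    for gap in assembly.gaps.values():
        attach(GAP_EDGE, gap.uid, gap.end1, gap.end2, "gap")
    for edge in assembly.edges.values():
        attach(OVERLAP_EDGE, edge.uid, edge.end1, edge.end2, "edge")
    return graph


@dataclass
class Component:
    """One connected component of the assembly graph."""

    segment_uids: set
    is_branching: bool
    #: (segment_uid, orientation) in linear end-to-end order; None when
    #: the component branches or contains a cycle.
    order: Optional[list] = None


def walk_components(graph: AssemblyGraph) -> list:
    """Partition segments into connected components via DFS.

    Components whose every end has internal degree <= 1 are linearized to
    a unique end-to-end order (deterministic: DFS starts at the
    lowest-uid segment, neighbors in insertion order). Branching or
    cyclic components are flagged, never silently linearized.
    """
    seen = set()
    components = []
    for start_uid in graph.segment_uids():
        if start_uid in seen:
            continue
        # collect the component by undirected reachability over segments
        members = {start_uid}
        stack = [start_uid]
        while stack:
            uid = stack.pop()
            for side in (Side.HEAD, Side.TAIL):
                for _, _, other in graph.adjacency.get(SegmentEnd(uid, side), []):
                    if other is not None and other.segment_uid not in members:
                        members.add(other.segment_uid)
                        stack.append(other.segment_uid)
        seen |= members
        branching = any(
            graph.degree(SegmentEnd(uid, side)) > 1
            for uid in members for side in (Side.HEAD, Side.TAIL))
        order = None
        if not branching:
            order = _linearize_component(graph, members)
        components.append(Component(members, branching or order is None, order))
    return components


def _linearize_component(graph: AssemblyGraph, members: set):
    """Unique linear order of a degree-<=1 component, or None for cycles."""
    first = min(members)
    if len(members) == 1:
        return [(first, "+")]
    # find an endpoint: a segment with one free end (internal degree 0)
    start = None
    for uid in sorted(members):
        for side in (Side.HEAD, Side.TAIL):
            if graph.degree(SegmentEnd(uid, side)) == 0:
                start = (uid, side)
                break
        if start is not None:
            break
    if start is None:
        return None  # cycle
    uid, free_side = start
    # entering through the free side: HEAD free => traverse head->tail = '+'
    orientation = "+" if free_side is Side.HEAD else "-"
    order = [(uid, orientation)]
    exit_end = SegmentEnd(uid, free_side.flipped())
    visited = {uid}
    while True:
        nxt = None
        for _, _, other in graph.adjacency.get(exit_end, []):
            if other is not None and other.segment_uid not in visited:
                nxt = other
                break
        if nxt is None:
            break
        uid = nxt.segment_uid
        orientation = "+" if nxt.side is Side.HEAD else "-"
        order.append((uid, orientation))
        visited.add(uid)
        exit_end = SegmentEnd(uid, nxt.side.flipped())
    if len(order) != len(members):
        return None
    return order


def _find_gap_between(assembly: Assembly, end_a: SegmentEnd,
                      end_b: SegmentEnd):
    for gap in assembly.gaps.values():
        if (gap.end1 == end_a and gap.end2 == end_b) or \
           (gap.end1 == end_b and gap.end2 == end_a):
            return gap
    return None


def _terminal_gap_at(assembly: Assembly, end: SegmentEnd):
    for gap in assembly.gaps.values():
        if gap.is_terminal and (gap.end1 == end or gap.end2 == end):
            return gap
    return None


def right_end(segment_uid: int, orientation: str) -> SegmentEnd:
    """End of a segment leaving in the walk direction."""
    return SegmentEnd(segment_uid,
                      Side.TAIL if orientation == "+" else Side.HEAD)


def left_end(segment_uid: int, orientation: str) -> SegmentEnd:
    """End of a segment entering in the walk direction."""
    return SegmentEnd(segment_uid,
                      Side.HEAD if orientation == "+" else Side.TAIL)


def paths_from_graph(assembly: Assembly, graph: AssemblyGraph,
                     warn=None) -> Assembly:
    """Synthesize Path records for segments not covered by any path.

    Non-branching components become one path each (terminal gaps attached
    at the corresponding ends); branching components fall back to one
    singleton path per segment and emit a warning. Existing paths are
    preserved untouched. Returns a new assembly; the input is unmodified.
    """
    out = assembly.copy()
    covered = set()
    for p in out.paths.values():
        covered.update(p.segment_uids())

    def used_names():
        return out._path_names()

    for comp in walk_components(build_graph(out)):
        if comp.segment_uids & covered:
            continue
        if comp.is_branching or comp.order is None:
            if warn is not None:
                names = sorted(out.segments[u].name for u in comp.segment_uids)
                warn(f"branching component {{{', '.join(names)}}}: "
                     "decomposed to singleton paths")
            for uid in sorted(comp.segment_uids):
                name = _unique_name(out.segments[uid].name, used_names())
                out.add_path(name, [PathElement(ElementKind.SEGMENT, uid)])
            continue
        elements = []
        first_uid, first_ori = comp.order[0]
        lead = _terminal_gap_at(out, left_end(first_uid, first_ori))
        if lead is not None:
            elements.append(PathElement(ElementKind.GAP, lead.uid))
        prev = None
        for uid, ori in comp.order:
            if prev is not None:
                gap = _find_gap_between(out, right_end(*prev),
                                        left_end(uid, ori))
                if gap is not None:
                    elements.append(PathElement(ElementKind.GAP, gap.uid))
                else:
                    # overlap-edge junction: keep alternation with a
                    # 0-length gap
                    zgap = out.add_gap(right_end(*prev), left_end(uid, ori), 0)
                    elements.append(PathElement(ElementKind.GAP, zgap.uid))
            elements.append(PathElement(ElementKind.SEGMENT, uid, ori))
            prev = (uid, ori)
        trail = _terminal_gap_at(out, right_end(*prev))
        if trail is not None:
            elements.append(PathElement(ElementKind.GAP, trail.uid))
        name = _unique_name(out.segments[comp.order[0][0]].name, used_names())
        out.add_path(name, elements)
    return out


def _unique_name(base: str, taken: set) -> str:
    if base not in taken:
        return base
    i = 2
    while f"{base}.{i}" in taken:
        i += 1
    return f"{base}.{i}"


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

def validate(assembly: Assembly) -> list:
    """Check every model invariant; return diagnostics (never raises).

    An empty list means the assembly is well-formed. Each diagnostic names
    the offending element and the violated rule.
    """
    diags = []
    seen_names = {}
    for seg in assembly.segments.values():
        if seg.sequence is not None:
            if len(seg.sequence) != seg.length:
                diags.append(f"segment {seg.name!r}: length {seg.length} != "
                             f"sequence length {len(seg.sequence)}")
            bad = _seq.first_invalid_char(seg.sequence)
            if bad >= 0:
                diags.append(f"segment {seg.name!r}: invalid character "
                             f"{seg.sequence[bad]!r} at position {bad}")
        if seg.qualities is not None and len(seg.qualities) != seg.length:
            diags.append(f"segment {seg.name!r}: qualities length "
                         f"{len(seg.qualities)} != length {seg.length}")
        if seg.name in seen_names:
            diags.append(f"duplicate segment name {seg.name!r}")
        seen_names[seg.name] = seg.uid

    def check_end(end, what):
        if end is not None and end.segment_uid not in assembly.segments:
            diags.append(f"{what}: dangling segment uid {end.segment_uid}")

    for gap in assembly.gaps.values():
        check_end(gap.end1, f"gap {gap.name or gap.uid}")
        check_end(gap.end2, f"gap {gap.name or gap.uid}")
        if gap.distance is not UNKNOWN and gap.distance < 0:
            diags.append(f"gap {gap.name or gap.uid}: negative distance")
    for edge in assembly.edges.values():
        check_end(edge.end1, f"edge {edge.name or edge.uid}")
        check_end(edge.end2, f"edge {edge.name or edge.uid}")

    seen_paths = set()
    seg_owner = {}
    for path in assembly.paths.values():
        if path.name in seen_paths:
            diags.append(f"duplicate path name {path.name!r}")
        seen_paths.add(path.name)
        prev_kind = None
        for el in path.elements:
            store = (assembly.segments if el.kind is ElementKind.SEGMENT
                     else assembly.gaps)
            if el.uid not in store:
                diags.append(f"path {path.name!r}: missing "
                             f"{el.kind.value} uid {el.uid}")
                prev_kind = el.kind
                continue
            if el.kind is ElementKind.SEGMENT:
                if prev_kind is ElementKind.SEGMENT:
                    diags.append(f"path {path.name!r}: adjacent segments "
                                 "without intervening gap")
                owner = seg_owner.get(el.uid)
                if owner is not None and owner != path.uid:
                    diags.append(
                        f"segment {assembly.segments[el.uid].name!r} "
                        "appears in more than one path")
                seg_owner[el.uid] = path.uid
            elif prev_kind is ElementKind.GAP:
                diags.append(f"path {path.name!r}: adjacent gaps")
            prev_kind = el.kind
    return diags
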