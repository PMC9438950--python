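"""Pre-processing: include/exclude selection, sorting, homopolymer ops.

Selection composes in a fixed order — include-names, exclude-names,
include-intervals, exclude-intervals — so a spec is deterministic however
it is assembled. Interval extraction names subrange scaffolds
``name:start-end`` (0-based half-open). Sorting permutes scaffold order
only; natural sort compares numeric substrings numerically (chr1 < chr2 <
chr10).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Optional

from . import seq as _seq
from .model import (
    Assembly,
    DEFAULT_UNKNOWN_GAP_LEN,
    ElementKind,
    PathElement,
    UNKNOWN,
)
from .sak import SakExecutionError, op_erase


class SelectionError(ValueError):
    pass


@dataclass
class BedInterval:
    chrom: str
    start: int  # 0-based inclusive
    end: int    # 0-based exclusive
    name: str = ""


@dataclass
class SelectionSpec:
    include_names: Optional[list] = None
    exclude_names: Optional[list] = None
    include_intervals: Optional[list] = None
    exclude_intervals: Optional[list] = None


@dataclass
class SortSpec:
    key: str = "INPUT_ORDER"  # NAME | LENGTH | CUSTOM_LIST | INPUT_ORDER
    descending: bool = False
    custom_order: Optional[list] = None


def read_name_list(source) -> list:
    text = source if isinstance(source, str) and "\n" in source else None
    if text is None:
        with open(source) as fh:
            text = fh.read()
    return [ln.strip() for ln in text.splitlines() if ln.strip()]


def read_bed(path_or_text: str) -> list:
    """Parse BED3(+1) into intervals."""
    if "\t" in path_or_text or "\n" in path_or_text:
        text = path_or_text
    else:
        with open(path_or_text) as fh:
            text = fh.read()
    out = []
    for lineno, ln in enumerate(text.splitlines(), 1):
        if not ln.strip() or ln.startswith(("#", "track", "browser")):
            continue
        fields = ln.split("\t")
        if len(fields) < 3:
            raise SelectionError(f"BED line {lineno}: needs >=3 columns")
        out.append(BedInterval(fields[0], int(fields[1]), int(fields[2]),
                               fields[3] if len(fields) > 3 else ""))
    return out


def _rebuild(assembly: Assembly, keep_paths: list) -> Assembly:
    """New assembly holding only the given paths (elements re-added).

    Segments not in any kept path are dropped (selection discards
    singletons of removed scaffolds); overlap edges between kept segments
    are retained.
    """
    out = Assembly()
    out.header_tags = dict(assembly.header_tags)
    uid_map = {}
    for path in keep_paths:
        els = []
        for el in path.elements:
            if el.kind is ElementKind.SEGMENT:
                seg = assembly.segments[el.uid]
                if el.uid not in uid_map:
                    ns = out.add_segment(seg.name, seg.sequence,
                                         seg.qualities, seg.length,
                                         dict(seg.tags))
                    uid_map[el.uid] = ns.uid
                els.append(PathElement(ElementKind.SEGMENT,
                                       uid_map[el.uid], el.orientation))
            else:
                gap = assembly.gaps[el.uid]
                ng = out.add_gap(None, None, gap.distance, gap.name,
                                 dict(gap.tags))
                els.append(PathElement(ElementKind.GAP, ng.uid))
        out.add_path(path.name, els, dict(path.tags))
    for edge in assembly.edges.values():
        if (edge.end1.segment_uid in uid_map
                and edge.end2.segment_uid in uid_map):
            from .model import SegmentEnd
            out.add_edge(SegmentEnd(uid_map[edge.end1.segment_uid],
                                    edge.end1.side),
                         SegmentEnd(uid_map[edge.end2.segment_uid],
                                    edge.end2.side),
                         edge.overlap_spec, edge.name, edge.coords,
                         dict(edge.tags))
    from .sak import _refresh_gap_ends
    for path in out.paths.values():
        _refresh_gap_ends(out, path)
    return out


def apply_selection(assembly: Assembly, spec: SelectionSpec,
                    strict: bool = False, warn=None,
                    unknown_gap_len: int = DEFAULT_UNKNOWN_GAP_LEN
                    ) -> Assembly:
    """Filter scaffolds by name lists and BED intervals; input untouched."""

    def missing(name):
        msg = f"no scaffold named {name!r}"
        if strict:
            raise SelectionError(msg)
        if warn is not None:
            warn(msg)

    paths = list(assembly.paths.values())
    if spec.include_names is not None:
        by_name = {p.name: p for p in paths}
        kept = []
        for name in spec.include_names:
            if name in by_name:
                kept.append(by_name[name])
            else:
                missing(name)
        paths = kept
    if spec.exclude_names is not None:
        drop = set(spec.exclude_names)
        for name in drop - {p.name for p in paths}:
            missing(name)
        paths = [p for p in paths if p.name not in drop]
    result = _rebuild(assembly, paths)

    if spec.include_intervals:
        pieces = []
        for iv in spec.include_intervals:
            path = result.path_by_name(iv.chrom)
            if path is None:
                missing(iv.chrom)
                continue
            total = result.path_length(path, unknown_gap_len)
            if not (0 <= iv.start < iv.end <= total):
                raise SelectionError(
                    f"interval {iv.chrom}:{iv.start}-{iv.end} outside "
                    f"scaffold (length {total})")
            pieces.append((path, iv.start, iv.end))
        result = _extract_intervals(result, pieces, warn, unknown_gap_len)

    if spec.exclude_intervals:
        for iv in spec.exclude_intervals:
            path = result.path_by_name(iv.chrom)
            if path is None:
                missing(iv.chrom)
                continue
            try:
                op_erase(result, [iv.chrom, f"{iv.start}-{iv.end}"],
                         unknown_gap_len)
            except SakExecutionError as exc:
                raise SelectionError(str(exc)) from exc
    return result


def _extract_intervals(assembly, pieces, warn, unknown_gap_len):
    """Subrange scaffolds via ERASE of the flanks, named name:start-end."""
    out = Assembly()
    out.header_tags = dict(assembly.header_tags)
    for path, start, end in pieces:
        sub = _rebuild(assembly, [path])
        p = sub.path_by_name(path.name)
        total = sub.path_length(p, unknown_gap_len)
        if end < total:
            op_erase(sub, [path.name, f"{end}-{total}"], unknown_gap_len)
        if start > 0 and sub.path_by_name(path.name) is not None:
            op_erase(sub, [path.name, f"0-{start}"], unknown_gap_len)
        new_name = f"{path.name}:{start}-{end}"
        p = sub.path_by_name(path.name)
        if p is None:
            # range covered only gap bases: keep an explicit pure-gap record
            if warn is not None:
                warn(f"interval {new_name} contains no contig bases")
            gp = out.add_gap(None, None, end - start,
                             name=f"{new_name}.gap1")
            out.add_path(new_name, [PathElement(ElementKind.GAP, gp.uid)])
            continue
        if not p.segment_uids() and warn is not None:
            warn(f"interval {new_name} contains no contig bases")
        # copy the trimmed single path into the output, uniquifying names
        from .model import _unique_name
        els = []
        gi = 0
        for el in p.elements:
            if el.kind is ElementKind.SEGMENT:
                seg = sub.segments[el.uid]
                nm = _unique_name(seg.name, out._segment_names())
                ns = out.add_segment(nm, seg.sequence, seg.qualities,
                                     seg.length, dict(seg.tags))
                els.append(PathElement(ElementKind.SEGMENT, ns.uid,
                                       el.orientation))
            else:
                gi += 1
                g = sub.gaps[el.uid]
                ng = out.add_gap(None, None, g.distance,
                                 name=f"{new_name}.gap{gi}")
                els.append(PathElement(ElementKind.GAP, ng.uid))
        out.add_path(new_name, els)
    from .sak import _refresh_gap_ends
    for path in out.paths.values():
        _refresh_gap_ends(out, path)
    return out


_NATURAL = re.compile(r"(\d+)")


def natural_key(name: str):
    return tuple(int(tok) if tok.isdigit() else tok
                 for tok in _NATURAL.split(name))


def sort_assembly(assembly: Assembly, spec: SortSpec,
                  unknown_gap_len: int = DEFAULT_UNKNOWN_GAP_LEN
                  ) -> Assembly:
    """Permute scaffold order (stable); element content is untouched."""
    paths = list(assembly.paths.values())
    if spec.key == "NAME":
        paths.sort(key=lambda p: natural_key(p.name),
                   reverse=spec.descending)
    elif spec.key == "LENGTH":
        paths.sort(key=lambda p: assembly.path_length(p, unknown_gap_len),
                   reverse=spec.descending)
    elif spec.key == "CUSTOM_LIST":
        if spec.custom_order is None:
            raise ValueError("CUSTOM_LIST sort requires custom_order")
        rank = {n: i for i, n in enumerate(spec.custom_order)}
        listed = [p for p in paths if p.name in rank]
        listed.sort(key=lambda p: rank[p.name])
        unlisted = [p for p in paths if p.name not in rank]
        paths = listed + unlisted
    elif spec.key != "INPUT_ORDER":
        raise ValueError(f"unknown sort key {spec.key!r}")
    return _rebuild(assembly, paths)


# ---------------------------------------------------------------------------
# Homopolymer compression
# ---------------------------------------------------------------------------

def homopolymer_compress(assembly: Assembly):
    """Collapse homopolymer runs in every segment; gaps untouched.

    Returns (new assembly, tracks) where tracks maps segment name to the
    per-retained-base run lengths needed for exact decompression.
    Per-base qualities cannot survive run-length compression and are
    dropped.
    """
    out = assembly.copy()
    tracks = {}
    for seg in out.segments.values():
        if seg.sequence is None:
            continue
        comp, runs = _seq.homopolymer_compress(seg.sequence)
        tracks[seg.name] = runs
        seg.sequence = comp
        seg.length = len(comp)
        seg.qualities = None
    return out, tracks


def homopolymer_decompress(assembly: Assembly, tracks: dict) -> Assembly:
    """Exact inverse of :func:`homopolymer_compress`."""
    out = assembly.copy()
    for seg in out.segments.values():
        if seg.sequence is None:
            continue
        if seg.name not in tracks:
            raise ValueError(f"no homopolymer track for segment {seg.name!r}")
        seg.sequence = _seq.homopolymer_decompress(seg.sequence,
                                                   tracks[seg.name])
        seg.length = len(seg.sequence)
    return out


def write_tracks(tracks: dict) -> str:
    """Sidecar TSV: segment name, comma-separated run lengths."""
    return "".join(f"{name}\t{','.join(map(str, runs))}\n"
                   for name, runs in tracks.items())


def read_tracks(source) -> dict:
    if "\t" in source or "\n" in source:
        text = source
    else:
        with open(source) as fh:
            text = fh.read()
    tracks = {}
    for ln in text.splitlines():
        if not ln.strip():
            continue
        name, _, runs = ln.partition("\t")
        tracks[name] = [int(x) for x in runs.split(",")] if runs else []
    return tracks
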