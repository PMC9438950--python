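"""Assembly summary statistics at scaffold, contig and gap tiers.

Definitions follow the community conventions:

* ``Nx``: the length of the shortest sequence in the minimal prefix of the
  descending-sorted length list whose sum reaches at least x% of a
  reference total (the assembly total for Nx, an expected genome size for
  NGx). ``Lx`` is the size of that prefix. Ties at exact halves resolve to
  the first qualifying prefix (the ">= half" convention).
* ``auN``: area under the Nx curve, sum(L_i^2)/sum(L_i) — a contiguity
  metric insensitive to the 50% threshold.
* GC content: 100*(G+C)/(A+C+G+T) over contig bases; N and other IUPAC
  ambiguity codes are excluded from the denominator.

Unknown-length gaps are counted at the linearization placeholder (100 bp
by default) and reported separately as ``n_unknown_gaps`` so either
convention can be reconstructed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import pandas as pd

from .model import (
    Assembly,
    DEFAULT_UNKNOWN_GAP_LEN,
    ElementKind,
    UNKNOWN,
    build_graph,
    walk_components,
)


@dataclass
class NxResult:
    x: float
    nx: int
    lx: int


def nx(lengths, x: float, reference_total: int) -> Optional[NxResult]:
    """Nx/Lx of a length multiset against a reference total.

    Returns None when x% of the reference exceeds the summed lengths
    (NGx undefined for an assembly shorter than the genome fraction).
    """
    if reference_total <= 0:
        raise ValueError("reference_total must be positive")
    if not lengths:
        return None
    threshold = x * reference_total / 100.0
    acc = 0
    for i, ln in enumerate(sorted(lengths, reverse=True), 1):
        acc += ln
        if acc >= threshold:
            return NxResult(x, ln, i)
    return None


def aun(lengths) -> Optional[float]:
    """Area under the Nx curve: sum(L^2)/sum(L), 2-decimal bp."""
    total = sum(lengths)
    if total == 0:
        return None
    return round(sum(ln * ln for ln in lengths) / total, 2)


def base_composition(assembly: Assembly):
    """(base_counts, gc_content, soft_masked) over contig bases only.

    base_counts has keys A, C, G, T, N and "other" (non-N ambiguity
    codes); counting is case-insensitive but lowercase bases are also
    tallied in soft_masked. Gap Ns are *not* included (they are lengths,
    not base calls). gc_content is None for an empty assembly.
    """
    counts = {"A": 0, "C": 0, "G": 0, "T": 0, "N": 0, "other": 0}
    soft = 0
    for seg in assembly.segments.values():
        s = seg.sequence
        if s is None:
            continue
        soft += sum(1 for c in s if c.islower())
        up = s.upper()
        for b in "ACGTN":
            counts[b] += up.count(b)
        counts["other"] += len(up) - sum(counts_b for counts_b in
                                         (up.count(b) for b in "ACGTN"))
    acgt = counts["A"] + counts["C"] + counts["G"] + counts["T"]
    gc = round(100.0 * (counts["G"] + counts["C"]) / acgt, 2) if acgt else None
    return counts, gc, soft


@dataclass
class StatsReport:
    """The full summary-statistics record for one assembly."""

    n_scaffolds: int = 0
    n_contigs: int = 0
    n_gaps: int = 0
    n_unknown_gaps: int = 0
    total_scaffold_len: int = 0
    total_contig_len: int = 0
    total_gap_len: int = 0
    largest_scaffold: int = 0
    largest_contig: int = 0
    largest_gap: int = 0
    avg_scaffold_len: Optional[float] = None
    avg_contig_len: Optional[float] = None
    avg_gap_len: Optional[float] = None
    scaffold_n50: int = 0
    scaffold_l50: int = 0
    contig_n50: int = 0
    contig_l50: int = 0
    scaffold_ng50: Optional[int] = None
    scaffold_lg50: Optional[int] = None
    contig_ng50: Optional[int] = None
    contig_lg50: Optional[int] = None
    scaffold_aun: Optional[float] = None
    contig_aun: Optional[float] = None
    gap_aun: Optional[float] = None
    base_counts: dict = field(default_factory=dict)
    gc_content: Optional[float] = None
    soft_masked: int = 0
    graph_segments: int = 0
    graph_edges: int = 0
    graph_gaps: int = 0
    graph_paths: int = 0
    graph_components: int = 0


def _tier(lengths, genome_size=None):
    """(total, largest, avg, n50, l50, ng50, lg50, aun) of one tier."""
    if not lengths:
        return 0, 0, None, 0, 0, None, None, None
    total = sum(lengths)
    r = nx(lengths, 50, total)
    ng = nx(lengths, 50, genome_size) if genome_size else None
    return (total, max(lengths), round(total / len(lengths), 2),
            r.nx, r.lx,
            ng.nx if ng else None, ng.lx if ng else None,
            aun(lengths))


def summarize(assembly: Assembly, genome_size: Optional[int] = None,
              unknown_gap_len: int = DEFAULT_UNKNOWN_GAP_LEN) -> StatsReport:
    """Fill every report field in one pass plus one sort per tier.

    Tiers: scaffold = linearized path length; contig = segment length;
    gap = gap distance (unknown at the placeholder). Segments outside any
    path still count as contigs (singletons).
    """
    rep = StatsReport()
    scaffold_lens = [assembly.path_length(p, unknown_gap_len)
                     for p in assembly.paths.values()]
    contig_lens = [s.length for s in assembly.segments.values()]
    gap_lens = [g.length(unknown_gap_len) for g in assembly.gaps.values()]
    rep.n_scaffolds = len(scaffold_lens)
    rep.n_contigs = len(contig_lens)
    rep.n_gaps = len(gap_lens)
    rep.n_unknown_gaps = sum(1 for g in assembly.gaps.values()
                             if g.distance is UNKNOWN)

    (rep.total_scaffold_len, rep.largest_scaffold, rep.avg_scaffold_len,
     rep.scaffold_n50, rep.scaffold_l50, rep.scaffold_ng50,
     rep.scaffold_lg50, rep.scaffold_aun) = _tier(scaffold_lens, genome_size)
    (rep.total_contig_len, rep.largest_contig, rep.avg_contig_len,
     rep.contig_n50, rep.contig_l50, rep.contig_ng50, rep.contig_lg50,
     rep.contig_aun) = _tier(contig_lens, genome_size)
    (rep.total_gap_len, rep.largest_gap, rep.avg_gap_len,
     _, _, _, _, rep.gap_aun) = _tier(gap_lens)

    rep.base_counts, rep.gc_content, rep.soft_masked = \
        base_composition(assembly)

    rep.graph_segments = len(assembly.segments)
    rep.graph_edges = len(assembly.edges)
    rep.graph_gaps = len(assembly.gaps)
    rep.graph_paths = len(assembly.paths)
    rep.graph_components = len(walk_components(build_graph(assembly)))
    return rep


def per_sequence_stats(assembly: Assembly,
                       unknown_gap_len: int = DEFAULT_UNKNOWN_GAP_LEN
                       ) -> pd.DataFrame:
    """One row per scaffold: name, length, n_contigs, n_gaps, gap_bp, gc.

    Rows are in assembly order; column sums match the report totals.
    """
    rows = []
    for path in assembly.paths.values():
        n_contigs = n_gaps = gap_bp = 0
        gc_num = acgt = 0
        for el in path.elements:
            if el.kind is ElementKind.SEGMENT:
                seg = assembly.segments[el.uid]
                n_contigs += 1
                if seg.sequence is not None:
                    up = seg.sequence.upper()
                    g, c = up.count("G"), up.count("C")
                    gc_num += g + c
                    acgt += g + c + up.count("A") + up.count("T")
            else:
                n_gaps += 1
                gap_bp += assembly.gaps[el.uid].length(unknown_gap_len)
        rows.append({
            "name": path.name,
            "length": assembly.path_length(path, unknown_gap_len),
            "n_contigs": n_contigs,
            "n_gaps": n_gaps,
            "gap_bp": gap_bp,
            "gc": round(100.0 * gc_num / acgt, 2) if acgt else None,
        })
    return pd.DataFrame(
        rows, columns=["name", "length", "n_contigs", "n_gaps",
                       "gap_bp", "gc"])


_REPORT_FIELDS = [
    ("n_scaffolds", "# scaffolds"),
    ("total_scaffold_len", "Total scaffold length"),
    ("avg_scaffold_len", "Average scaffold length"),
    ("scaffold_n50", "Scaffold N50"),
    ("scaffold_l50", "Scaffold L50"),
    ("scaffold_ng50", "Scaffold NG50"),
    ("scaffold_lg50", "Scaffold LG50"),
    ("scaffold_aun", "Scaffold auN"),
    ("largest_scaffold", "Largest scaffold"),
    ("n_contigs", "# contigs"),
    ("total_contig_len", "Total contig length"),
    ("avg_contig_len", "Average contig length"),
    ("contig_n50", "Contig N50"),
    ("contig_l50", "Contig L50"),
    ("contig_ng50", "Contig NG50"),
    ("contig_lg50", "Contig LG50"),
    ("contig_aun", "Contig auN"),
    ("largest_contig", "Largest contig"),
    ("n_gaps", "# gaps"),
    ("n_unknown_gaps", "# gaps of unknown length"),
    ("total_gap_len", "Total gap length"),
    ("avg_gap_len", "Average gap length"),
    ("largest_gap", "Largest gap"),
    ("gap_aun", "Gap auN"),
    ("gc_content", "GC content %"),
    ("soft_masked", "Soft-masked bases"),
    ("graph_segments", "# graph segments"),
    ("graph_edges", "# graph edges"),
    ("graph_gaps", "# graph gaps"),
    ("graph_paths", "# graph paths"),
    ("graph_components", "# connected components"),
]


def format_report(report: StatsReport, tabular: bool = False) -> str:
    """Render the report: "key: value" lines, or a 2-row TSV (--tabular).

    Field order is fixed and floats print with 2 decimals so outputs are
    byte-stable.
    """

    def fmt(v):
        if v is None:
            return "NA"
        if isinstance(v, float):
            return f"{v:.2f}"
        return str(v)

    base = ", ".join(f"{k}:{report.base_counts.get(k, 0)}"
                     for k in ("A", "C", "G", "T", "N", "other"))
    if tabular:
        header = [label for _, label in _REPORT_FIELDS] + ["Base composition"]
        values = [fmt(getattr(report, name)) for name, _ in _REPORT_FIELDS]
        return "\t".join(header) + "\n" + "\t".join(values + [base]) + "\n"
    lines = [f"{label}: {fmt(getattr(report, name))}"
             for name, label in _REPORT_FIELDS]
    lines.append(f"Base composition (A,C,G,T,N,other): {base}")
    return "\n".join(lines) + "\n"
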