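"""Synthetic-assembly generator with known ground-truth statistics.

The generator emulates a draft vertebrate-style assembly at reduced
scale: scaffold counts in the tens, log-normal contig lengths (heavy
right tail, median ~20 kb), Poisson gap counts per scaffold, log-normal
gap lengths, a fraction of gaps of unknown size (rendered at the 100-N
placeholder), and a mild AT-rich base composition (GC ~41%). Everything
is driven by one integer seed: the same seed yields byte-identical
FASTA.

Ground truth is computed from the generation bookkeeping itself with a
naive N50/auN implementation — independent of :mod:`gfakit.stats`, so it
doubles as an oracle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .model import ElementKind
from .stats import StatsReport


@dataclass
class FixtureSpec:
    n_scaffolds: int = 20
    contig_len_log_mean: float = math.log(20_000)
    contig_len_log_sigma: float = 0.8
    gaps_per_scaffold_mean: float = 3.0
    gap_len_log_mean: float = math.log(500)
    gap_len_log_sigma: float = 0.7
    unknown_gap_fraction: float = 0.1
    terminal_gap_prob: float = 0.05
    gc: float = 0.41
    unknown_gap_placeholder: int = 100
    line_width: int = 60
    seed: int = 0


_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _random_sequence(rng, length: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(_BASES, size=length, p=p)


def _naive_nx(lengths, x, reference_total):
    """Brute-force Nx/Lx: descending sort + prefix scan."""
    acc = 0
    for i, ln in enumerate(sorted(lengths, reverse=True), 1):
        acc += ln
        if acc >= x * reference_total / 100.0:
            return ln, i
    return None, None


def _naive_aun(lengths):
    total = sum(lengths)
    if total == 0:
        return None
    return round(sum(v * v for v in lengths) / total, 2)


def generate_fixture(spec: FixtureSpec):
    """Return (fasta_text, ground_truth StatsReport).

    The FASTA renders unknown gaps as the 100-N placeholder, so in the
    linear output they are book-kept as sized 100 bp gaps (a FASTA file
    cannot distinguish the two).
    """
    rng = np.random.default_rng(spec.seed)
    records = []
    scaffold_lens = []
    contig_lens = []
    gap_lens = []
    counts = np.zeros(4, dtype=np.int64)  # A C G T

    for i in range(1, spec.n_scaffolds + 1):
        n_gaps = int(rng.poisson(spec.gaps_per_scaffold_mean))
        n_contigs = n_gaps + 1
        clens = np.maximum(1, rng.lognormal(
            spec.contig_len_log_mean, spec.contig_len_log_sigma,
            n_contigs).astype(np.int64))
        glens = []
        for _ in range(n_gaps):
            if rng.random() < spec.unknown_gap_fraction:
                glens.append(spec.unknown_gap_placeholder)
            else:
                glens.append(max(1, int(rng.lognormal(
                    spec.gap_len_log_mean, spec.gap_len_log_sigma))))
        lead = (max(1, int(rng.lognormal(spec.gap_len_log_mean,
                                         spec.gap_len_log_sigma)))
                if rng.random() < spec.terminal_gap_prob else 0)
        trail = (max(1, int(rng.lognormal(spec.gap_len_log_mean,
                                          spec.gap_len_log_sigma)))
                 if rng.random() < spec.terminal_gap_prob else 0)

        parts = []
        if lead:
            parts.append(b"N" * lead)
            gap_lens.append(lead)
        for j, clen in enumerate(clens):
            arr = _random_sequence(rng, int(clen), spec.gc)
            counts += np.bincount(
                np.searchsorted(_BASES, arr), minlength=4)
            parts.append(arr.tobytes())
            contig_lens.append(int(clen))
            if j < n_gaps:
                parts.append(b"N" * glens[j])
                gap_lens.append(glens[j])
        if trail:
            parts.append(b"N" * trail)
            gap_lens.append(trail)
        seqb = b"".join(parts)
        scaffold_lens.append(len(seqb))
        records.append((f"scaffold_{i}", seqb))

    out = []
    w = spec.line_width
    for name, seqb in records:
        out.append(f">{name}\n")
        s = seqb.decode()
        out.append("\n".join(s[k:k + w] for k in range(0, len(s), w)) + "\n")
    fasta = "".join(out)

    truth = StatsReport()
    truth.n_scaffolds = len(scaffold_lens)
    truth.n_contigs = len(contig_lens)
    truth.n_gaps = len(gap_lens)
    truth.n_unknown_gaps = 0  # FASTA renders all gaps as sized
    truth.total_scaffold_len = sum(scaffold_lens)
    truth.total_contig_len = sum(contig_lens)
    truth.total_gap_len = sum(gap_lens)
    truth.largest_scaffold = max(scaffold_lens) if scaffold_lens else 0
    truth.largest_contig = max(contig_lens) if contig_lens else 0
    truth.largest_gap = max(gap_lens) if gap_lens else 0
    if scaffold_lens:
        truth.avg_scaffold_len = round(
            truth.total_scaffold_len / len(scaffold_lens), 2)
        truth.scaffold_n50, truth.scaffold_l50 = _naive_nx(
            scaffold_lens, 50, truth.total_scaffold_len)
        truth.scaffold_aun = _naive_aun(scaffold_lens)
    if contig_lens:
        truth.avg_contig_len = round(
            truth.total_contig_len / len(contig_lens), 2)
        truth.contig_n50, truth.contig_l50 = _naive_nx(
            contig_lens, 50, truth.total_contig_len)
        truth.contig_aun = _naive_aun(contig_lens)
    if gap_lens:
        truth.avg_gap_len = round(truth.total_gap_len / len(gap_lens), 2)
        truth.gap_aun = _naive_aun(gap_lens)
    a, c, g, t = (int(v) for v in counts)
    truth.base_counts = {"A": a, "C": c, "G": g, "T": t, "N": 0, "other": 0}
    truth.gc_content = round(100.0 * (g + c) / (a + c + g + t), 2) \
        if (a + c + g + t) else None
    truth.soft_masked = 0
    truth.graph_segments = truth.n_contigs
    truth.graph_edges = 0
    truth.graph_gaps = truth.n_gaps
    truth.graph_paths = truth.n_scaffolds
    truth.graph_components = truth.n_scaffolds
    return fasta, truth


# ---------------------------------------------------------------------------
# Random SAK scripts (for conservation and inverse-law testing)
# ---------------------------------------------------------------------------

def random_sak_script(assembly, rng, n_instructions: int = 10) -> str:
    """Build a random but always-executable SAK script for an assembly.

    Instructions are chosen among those applicable to the evolving
    assembly state (the script is grown by executing each candidate), so
    the result always runs end to end.
    """
    from . import sak as _sak

    asm = assembly.copy()
    lines = []
    counter = [0]

    def fresh(base):
        counter[0] += 1
        return f"{base}_{counter[0]}"

    def candidates():
        cands = []
        paths = list(asm.paths.values())
        seg_paths = [p for p in paths if p.elements
                     and p.elements[0].kind is ElementKind.SEGMENT
                     and p.elements[-1].kind is ElementKind.SEGMENT]
        if len(seg_paths) >= 2:
            a, b = [seg_paths[k] for k in
                    rng.choice(len(seg_paths), 2, replace=False)]
            gl = rng.choice(["*", str(int(rng.integers(0, 500)))])
            cands.append(f"JOIN {a.name}{rng.choice(['+', '-'])} "
                         f"{b.name}{rng.choice(['+', '-'])} {gl} "
                         f"{fresh('join')}")
        splittable = []
        for p in paths:
            els = p.elements
            for k in range(len(els) - 2):
                if (els[k].kind is ElementKind.SEGMENT
                        and els[k + 1].kind is ElementKind.GAP
                        and els[k + 2].kind is ElementKind.SEGMENT):
                    splittable.append(
                        (asm.segments[els[k].uid].name,
                         asm.segments[els[k + 2].uid].name))
        if splittable:
            s1, s2 = splittable[int(rng.integers(len(splittable)))]
            cands.append(f"SPLIT {s1} {s2}")
        segs = [s for s in asm.segments.values()
                if asm.path_of_segment(s.uid) is not None]
        if segs:
            s = segs[int(rng.integers(len(segs)))]
            cands.append(f"EXCISE {s.name} {int(rng.integers(0, 300))}")
            cands.append(f"REMOVE {s.name}")
            cands.append(f"INVERT {s.name}")
        if paths:
            p = paths[int(rng.integers(len(paths)))]
            total = asm.path_length(p)
            if total >= 2:
                a = int(rng.integers(0, total - 1))
                b = int(rng.integers(a + 1, total + 1))
                cands.append(f"ERASE {p.name} {a}-{b}")
            cands.append(f"RVCP {p.name}")
            cands.append(f"TRIM_NS {p.name}")
            cands.append(f"RENAME {p.name} {fresh('ren')}")
        return cands

    for _ in range(n_instructions):
        cands = candidates()
        if not cands:
            break
        line = cands[int(rng.integers(len(cands)))]
        try:
            asm, _log = _sak.execute(asm, line)
        except _sak.SakExecutionError:
            continue  # e.g. JOIN hitting a terminal-gap end; skip
        lines.append(line)
    return "\n".join(lines) + ("\n" if lines else "")
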