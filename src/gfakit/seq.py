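"""Low-level nucleotide sequence helpers.

Sequences are plain Python strings over the IUPAC nucleotide alphabet
(upper- or lowercase). Case is semantically meaningful (lowercase =
soft-masked) and is preserved by every operation here.
"""

from __future__ import annotations

import re

# IUPAC nucleotide one-letter codes, including N and U.
IUPAC = "ACGTUNRYSWKMBDHV"
VALID_CHARS = frozenset(IUPAC + IUPAC.lower())

_COMPLEMENT = str.maketrans(
    "ACGTUNRYSWKMBDHVacgtunryswkmbdhv",
    "TGCAANYRSWMKVHDBtgcaanyrswmkvhdb",
)

_NRUN = re.compile(r"[Nn]+")


def revcomp(seq: str) -> str:
    """Reverse complement, preserving case; N maps to N."""
    return seq.translate(_COMPLEMENT)[::-1]


def first_invalid_char(seq: str) -> int:
    """Index of the first character outside the IUPAC set, or -1."""
    for i, c in enumerate(seq):
        if c not in VALID_CHARS:
            return i
    return -1


def split_at_n_runs(seq: str) -> tuple[list[tuple[int, int]], list[tuple[int, int]]]:
    """Split a scaffold string at maximal runs of N/n.

    Returns (contig_spans, gap_spans) as 0-based half-open intervals on
    ``seq``. Any run of >= 1 N separates contigs; leading/trailing runs
    become terminal gap spans. A string of only Ns yields one gap span and
    no contig spans.
    """
    gap_spans = [m.span() for m in _NRUN.finditer(seq)]
    contig_spans = []
    pos = 0
    for start, end in gap_spans:
        if start > pos:
            contig_spans.append((pos, start))
        pos = end
    if pos < len(seq):
        contig_spans.append((pos, len(seq)))
    return contig_spans, gap_spans


def homopolymer_compress(seq: str) -> tuple[str, list[int]]:
    """Collapse each maximal run of one base to a single base.

    Run detection is case-insensitive; the first base's case is kept.
    Returns (compressed, run_lengths) with sum(run_lengths) == len(seq).
    """
    if not seq:
        return "", []
    out = []
    runs = []
    prev = seq[0]
    run = 1
    for c in seq[1:]:
        if c.upper() == prev.upper():
            run += 1
        else:
            out.append(prev)
            runs.append(run)
            prev = c
            run = 1
    out.append(prev)
    runs.append(run)
    return "".join(out), runs


def homopolymer_decompress(seq: str, runs: list[int]) -> str:
    """Exact inverse of :func:`homopolymer_compress`."""
    if len(seq) != len(runs):
        raise ValueError(
            f"track length {len(runs)} does not match compressed length {len(seq)}"
        )
    return "".join(c * n for c, n in zip(seq, runs))
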