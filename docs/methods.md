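# Methods

## The assembly model

gfakit represents an assembly the way GFA2 does, regardless of the input
format:

* **Segment** — a contig: name, optional sequence (IUPAC nucleotide
  codes, case preserved; lowercase = soft-masked), optional per-base
  qualities, length, tags.
* **Gap** — a junction of unknown sequence between two segment *ends*,
  with a sized distance (≥ 0; 0 models abutting contigs) or an unknown
  distance. A *terminal* gap is attached on one side only and models the
  leading/trailing `N`s of a scaffold.
* **OverlapEdge** — a GFA L/E record between two segment ends.
* **Path** — one scaffold: an ordered, oriented walk that strictly
  alternates SEGMENT and GAP elements. Abutting contigs are joined by an
  explicit 0-length gap rather than a special adjacency; this buys one
  uniform conservation law (scaffold length = Σ segment lengths + Σ gap
  lengths) and keeps every edit a local list operation.

Segment ends use HEAD (5′ in + orientation) and TAIL (3′). The
bidirected graph is an adjacency list keyed by segment end; each
gap/overlap is a single undirected edge listed on both attached ends
(terminal gaps once). The forward/backward traversal directions of a
junction are recovered from which end an edge attaches to, so no double
bookkeeping is needed.

Traversal is plain DFS with deterministic tie-breaks: components start
from the lowest segment uid, neighbors in insertion order. A component
in which every end has internal degree ≤ 1 linearizes to a unique
end-to-end order; branching or cyclic components are flagged and — when
paths must be synthesized for path-less GFA input — decomposed into
singleton paths with a warning. The tool manipulates linear scaffolds
only; resolving branching structure is out of scope.

## Format handling

Formats are detected from content (gzip magic bytes, then the first
meaningful character; GFA1 vs GFA2 by the header `VN` tag, line-type
evidence, or S-line shape). FASTA/FASTQ records split at every maximal
run of ≥ 1 `N` — the strict contig definition; there is no minimum gap
size. Readers stream record by record; GFA readers additionally keep an
unresolved-reference table so gap/edge/path lines may precede their
segments.

Conversion choices where the standards leave room:

* Unknown-length gaps emit 100 `N`s on linearization (the NCBI/AGP "U"
  convention); configurable via `--unknown-gap-size`. The statistics
  report counts unknown gaps at the same placeholder and reports their
  count separately so either convention can be reconstructed.
* GFA2 cannot express one-sided gaps, so a terminal gap's open side is
  written as `*` in the G line — a small dialect extension this package
  both writes and reads.
* GFA1 has no gap lines at all. On GFA1 output, gaps are collapsed from
  the P member list and their lengths recorded in a reserved `gl:Z:` tag
  (`lead,g1,…,gn,trail`; `*` = unknown, `.` = absent), so a
  GFA1 → model → GFA2 round trip restores them. Foreign GFA1 P lines
  without the tag get 0-length gaps between members.
* Qualities ride through GFA in a reserved `ql:Z:` segment tag; FASTQ
  gap bases are written with quality `!` (no base call). Quality
  characters over an N run are discarded with the run on input.
* Coordinates: BED is 0-based half-open, AGP 1-based inclusive,
  everything internal 0-based half-open. AGP gap rows use
  `scaffold/yes/unspecified` for type/linkage/evidence; zero-length gaps
  produce no AGP/BED row (both formats require non-empty intervals) but
  remain in the model and in GFA output.

## Statistics

Nx/Lx use the "at least x%" convention with the first qualifying prefix
of the descending-sorted lengths — stated explicitly because outputs
differ at exact halves (e.g. lengths [4, 4] give N50 = 4, L50 = 1). auN
is Σ L²/Σ L. GC% is computed over A+C+G+T only; N and the other IUPAC
ambiguity codes are tallied separately and excluded from the
denominator. Gap `N`s are lengths, not base calls, and never enter base
counts. Floats print with 2 decimals in a fixed field order so reports
are byte-stable.

## The SAK

Scripts are parsed all-or-nothing and executed transactionally: the
input assembly is deep-copied, instructions apply strictly in order, and
any failure aborts the whole run. Later instructions see earlier
effects, so the change log (which records each raw instruction) replays
exactly.

Verb semantics worth stating:

* `JOIN a± b± [gap|*] [name]` — a `-` suffix reverse-complements that
  scaffold before joining; the join is always right-end-of-first to
  left-end-of-second. Joining at an end that carries a terminal gap is
  an error (`TRIM_NS` first); this keeps the alternation invariant
  instead of silently stacking gaps.
* `SPLIT s1 s2` deletes the gap between adjacent contigs; the pieces are
  named `<scaffold>.1` and `<scaffold>.2`.
* `EXCISE s [gap|*]` replaces contig + flanking gaps with one gap
  (default unknown) and keeps the contig as a singleton scaffold;
  `REMOVE` deletes it instead.
* `ERASE scaffold start-end` deletes a 0-based half-open range. A cut
  strictly inside one contig leaves two pieces joined by a 0-length gap;
  fully covered contigs are deleted; partially covered gaps shrink, and
  touching gap remnants merge. Truncated contigs are renamed
  `<name>.1`/`<name>.2`. Coordinates treat unknown gaps at the
  placeholder, and merging converts an unknown gap to a sized one —
  coordinates on a linearized scaffold cannot do otherwise.
* `RVCP` on a scaffold reverses the walk and flips orientations (stored
  sequences untouched); on a contig it flips the stored bases, and if
  the contig sits inside a multi-contig scaffold its orientation flag is
  flipped too so the scaffold sequence is invariant. `INVERT` flips only
  the orientation flag — that is the edit that changes the scaffold.

After every structural edit the gap end-attachments of the affected path
are recomputed from its element list, which keeps the graph view
consistent without per-verb bookkeeping.

## Selection, sorting, homopolymers

Selection composes in a fixed order: include-names (kept in list order)
→ exclude-names → include-intervals → exclude-intervals. Interval
extraction reuses ERASE on the flanks and names the result
`name:start-end` (0-based half-open); an interval covering only gap
bases yields an explicit pure-gap record with a warning. Exclude
intervals apply sequentially against current coordinates. Unknown names
warn by default and fail under `--strict`. Note that selection keeps
only scaffolds; segments outside every path are dropped with them.

Sorting is stable and permutes scaffold order only. NAME uses natural
order (numeric substrings compared numerically). CUSTOM_LIST places
listed names first, unlisted after in input order.

Homopolymer compression collapses each maximal same-base run
(case-insensitively, keeping the first base's case) and records run
lengths in a sidecar TSV (`segment<TAB>len,len,…`) — no standard format
exists for the track. Decompression is the exact inverse whenever each
run is case-uniform; a run mixing case (a soft-mask boundary inside a
homopolymer) reconstructs with the first base's case, since run lengths
alone cannot encode per-base case. Per-base qualities are dropped on
compression for the same reason. Gaps are untouched.

## The synthetic-data generator

`gfakit.fixtures.generate_fixture` emulates a scaled-down draft
assembly: log-normal contig lengths (median 20 kb, σ = 0.8 — a heavy
right tail like real contig-length distributions), Poisson(3) gaps per
scaffold, log-normal gap lengths (median 500 bp), 10% of gaps of unknown
size, 5% chance of a terminal gap at either scaffold end, GC 41%
(mammalian-like), 20 scaffolds by default. It returns FASTA plus a
ground-truth report computed from the generation bookkeeping with an
independent naive N50/auN implementation, so the generator doubles as a
statistics oracle. Because linear FASTA cannot distinguish sized from
unknown gaps, unknown gaps are rendered at the 100-N placeholder and
book-kept as sized; GFA fixtures with genuinely unknown gaps are derived
by conversion.

What the generator does **not** emulate: real base-level structure
(repeats, heterozygosity, coverage-driven contig breaks), overlap edges,
branching graph components, soft-masked regions, or ambiguity codes.
Passing tests therefore demonstrate bookkeeping correctness — length
accounting, coordinate arithmetic, graph topology, format round trips —
not biological plausibility of any edit.

Tests and the acceptance script run the generator at reduced sizes
(4 scaffolds × ~300 bp contigs for the many-replicate properties; ~1, 2,
4 and 8 Mbp for the scaling check, whose log-log slope asserts the
single-pass design without asserting wall-clock times). These sizes are
the package's own choice of problem scale; every property they check is
size-independent.

## Numerical and degenerate-input choices

* Empty assembly: all-zero report, GC and averages absent (`NA`).
* `nx` raises on non-positive reference totals; NGx is absent when x% of
  the genome size exceeds the assembly span.
* uids are dense integers in encounter order, per element class, stable
  across edits; names are the user-facing handles and must be unique per
  class. Generated names (`.1`/`.2` pieces, replacement gaps) are
  uniquified against the existing namespace.
* Determinism: the pipeline has no stochastic step; all randomness lives
  in the fixture generator behind one integer seed.

## Known limitations

* Cyclic/circular paths are not supported; cycles are flagged as
  branching components.
* GFA2 fragment (F) and set (U) lines, and any unknown line type, are
  preserved verbatim but not interpreted.
* GFA1 export of gapped scaffolds is lossy by the standard; losslessness
  relies on the reserved `gl` tag that only this package understands.
* ERASE through a segment without a stored sequence (`*` in GFA) is an
  error — there are no bases to truncate.
* Reference-based metrics (NA50, misassembly counts), k-mer completeness
  and masking edits are out of scope.
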