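# gfakit

Assembly summary statistics, FASTA/FASTQ/GFA interconversion and
graph-based sequence manipulation — for genome assemblers and curators
who need one tool that reads whatever an assembly pipeline produced,
reports its contiguity, and lets them edit scaffolds safely.

## What it does

Any input — FASTA, FASTQ, GFA1 or GFA2, plain or gzipped — is stored in
one GFA2-like in-memory model: **segments** (contigs), **gaps** (sized or
unknown), **overlap edges** and **paths** (scaffolds). In a FASTA record,
every maximal run of `N` becomes a gap splitting the record into
segments; leading/trailing runs become *terminal* gaps attached on one
side only. From the model gfakit builds a bidirected graph over segment
ends (one node per segment, one edge per gap/overlap) and walks it with
DFS, which makes format conversion, statistics and editing three views of
the same object.

Statistics follow the standard definitions. For lengths $L_1 \ge L_2 \ge
\dots$ and a reference total $T$ (the assembly span for N50, an expected
genome size for NG50):

$$\mathrm{N}x = L_k,\quad k = \min\Big\{j : \sum_{i\le j} L_i \ge
\tfrac{x}{100}\,T\Big\},\qquad \mathrm{L}x = k,\qquad
\mathrm{auN} = \frac{\sum_i L_i^2}{\sum_i L_i}.$$

Ties at exact halves use the "at least half" convention. Reports cover
the scaffold, contig and gap tiers plus base composition, GC%,
soft-masked bases and graph counts, with the identity
`total_scaffold_len = total_contig_len + total_gap_len` (unknown gaps at
the 100 bp placeholder).

Editing is scripted through the SAK ("swiss army knife"): a plain-text,
one-instruction-per-line language executed transactionally against the
graph — `JOIN`, `SPLIT`, `EXCISE`, `REMOVE`, `ERASE`, `RVCP`, `INVERT`,
`TRIM_NS`, `RENAME` — with a change log that replays to reproduce the
edit. Pre-processing covers include/exclude by name list or BED interval,
sorting (natural name order, length, custom list) and homopolymer
compression/decompression with a run-length sidecar.

## Worked example

Summarize a small synthetic assembly (3 scaffolds, 19 contigs):

```sh
$ gfakit demo.fa | head -12
# scaffolds: 3
Total scaffold length: 375544
Average scaffold length: 125181.33
Scaffold N50: 219097
Scaffold L50: 1
Scaffold NG50: NA
Scaffold LG50: NA
Scaffold auN: 160417.97
Largest scaffold: 219097
# contigs: 19
Total contig length: 366936
Average contig length: 19312.42
```

Half the assembly span lives in a single 219 kb scaffold (L50 = 1); the
auN of 160 kb summarizes the whole Nx curve rather than the 50% point.

Split a scaffold at its gap and write the result back to FASTA — the
report updates and the change log records what happened:

```sh
$ printf '>sc1\nACGNNNTTG\n' > toy.fa
$ printf 'SPLIT sc1.ctg1 sc1.ctg2\n' > edit.sak
$ gfakit toy.fa --sak edit.sak --out-format fasta -o out.fa 2>log.tsv
# scaffolds: 2
...
$ cat log.tsv
index  instruction              effect                                   created      deleted
1      SPLIT sc1.ctg1 sc1.ctg2  split sc1 between sc1.ctg1 and sc1.ctg2  sc1.1,sc1.2  sc1,sc1.gap1
```

The 9 bp scaffold `ACGNNNTTG` (two 3 bp contigs around a 3 bp gap)
becomes two gapless scaffolds `ACG` and `TTG`; total contig length (6 bp)
is conserved, the 3 bp of gap vanish with the dropped edge.

Conversion is a flag: `--out-format gfa2|gfa|fasta|fastq|agp|bed|sizes`,
gzip inferred from a `.gz` suffix on `-o`. The same operations are
available as a library (`gfakit.io`, `gfakit.stats`, `gfakit.sak`,
`gfakit.transform`, `gfakit.fixtures`).

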