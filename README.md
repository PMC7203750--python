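# seqcollapse

Exact, memory-bounded collapsing of redundant sequencing reads — and the
inverse operation for alignment files.

High-coverage NGS libraries (RNA-seq, small RNA, amplicons, WGS) contain
enormous numbers of byte-identical reads. Aligning each copy separately
wastes most of the mapping time on work already done. `seqcollapse`
replaces every group of identical reads (or identical mate pairs) with one
representative **tag** carrying its occurrence count and an average
consensus quality string; after aligning the much smaller tag file, the
`expand` step replicates each alignment record by its count, so downstream
tools see exactly the multiplicity the raw sample would have produced.

Collapsing is *exact*: two reads merge only if their sequences are
byte-identical (paired reads: both mates identical). Nothing is hashed,
trimmed, case-folded or discarded — reads containing `N` are kept.

## The model

For a sample of reads $r_1,\dots,r_n$, the collapser computes the multiset
of unique keys $\{(k, c_k)\}$ where $c_k = |\{i : \mathrm{key}(r_i) = k\}|$,
emitted in byte-lexicographic key order. The key is the sequence itself
(single-end) or `mate1 + 0x01 + mate2` (paired-end, including interleaved
and joined-mates layouts). Averaged qualities are exact: per-position Phred
values are accumulated as integer sums and divided at output time, rounding
half up.

The whole computation runs under a user RAM budget via external sorting.
A probe of $T_{size}$ reads with measured footprint $T_{RAM}$ gives the
chunk capacity

$$C_{size} = \alpha \cdot C_{RAM} \cdot T_{size} / T_{RAM},$$

with safety factor $\alpha = 0.8$ by default. Chunks of $C_{size}$ reads
are sorted, locally collapsed and written as $M$ sorted runs; a buffered
k-way merge (at most $\lfloor C_{size}/M \rfloor$ tags buffered per run)
then emits globally unique tags. The figure of merit is the **gain**

$$\mathrm{Gain}\% = (1 - \mathrm{Collapsed}/\mathrm{Raw}) \cdot 100$$

for read counts, file sizes or run times. Multi-sample mode collapses a
set of samples jointly and writes an occurrence table (tag × sample count
matrix) from which per-sample redundancy can be restored after alignment.

## Worked example

```bash
$ seqcollapse synth -o demo --n-unique 5 --law constant --law-param 4 --seed 7
wrote 20 reads over 5 unique tags
demo.fastq
demo.truth.tsv

$ seqcollapse collapse --input demo.fastq --output demo.tagq --format tagq --max-ram 1G
collapsed 20 reads -> 5 tags (75.0% read gain, 1 runs)

$ head -2 demo.tagq
AAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAA	4	EDBCCDEFEFDCEDFECDBCDDCDFEEEEFCBEDDB
AAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAC	4	CDDEDFEDDEEDDDEEEEDDECDDCDFDFCDDEBCE
```

The synthetic sample has 5 unique 36-mers, each duplicated 4 times; the
collapser reduces 20 reads to 5 tags — a 75.0% read gain. Each `tagq` line
is `sequence<TAB>count<TAB>average quality`. With `--format fastq` the
count rides in the header (`@demo.0_4`), ready for any aligner; after
alignment, `seqcollapse expand --input hits.sam --output full.sam`
replicates each record by its count.

Multi-sample collapsing (`--input s1.fq --input s2.fq ...`) additionally
writes `<output>.occ.tsv` with per-sample counts;
`seqcollapse expand --table <output>.occ.tsv --out-dir per_sample/` routes
the right number of copies back into each sample.

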