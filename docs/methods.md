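# Methods

## Collapsing model

Read identity is byte equality of sequences. The collapse key of a
single-end read is its sequence; a mate pair's key is
`mate1 + 0x01 + mate2`. The separator byte 0x01 is lexicographically
smaller than every ASCII letter, so paired keys have a well-defined total
order in which a shorter mate-1 sorts before any of its extensions, and the
separator can never occur inside a sequence. Joined-mates input (both mates
concatenated in one read with a fixed break-point *b*) is keyed identically
to the pair `(seq[:b], seq[b:])`, so the two representations collapse
together.

Deliberate consequences of "exact":

- **No case normalization.** `acgt` and `ACGT` are different tags.
  Folding case would be irreversible; users who want it can upper-case
  upstream.
- **`N`-containing reads are kept** and collapse like any others. Tools
  that silently drop reads with unknown bases lose data; we do not.
- **Variable-length reads never merge** (byte equality implies equal
  length); a strict prefix sorts before its extensions.

## Quality averaging

Each tag accumulates an exact integer vector of per-position Phred sums
(one vector per mate). Merging two tags adds counts and sums elementwise,
so averaging is associative and immune to drift regardless of the order in
which runs meet. On output the per-position value is
`(2*sum + count) // (2*count)` — the arithmetic mean rounded half up,
computed in integers — clamped to [0, 93] and encoded Phred+33. Averaging
n copies of one quality string returns that string unchanged for every n.
Round-half-up was chosen because no rounding rule is canonical for averaged
Phred scores; it is simple, exact in integer arithmetic, and stated here so
the output is reproducible by inspection.

## Memory-bounded external sort

The pipeline never holds more than a budgeted number of read units in RAM:

1. **Probe.** The first min(10 000, all) units are read and their
   serialized footprint summed (key bytes + 8 bytes per accumulated quality
   position + 64 bytes bookkeeping per unit). This yields `t_size`/`t_ram`
   without a second pass over the file.
2. **Plan.** `c_size = max(1, floor(alpha * c_ram * t_size / t_ram))`.
   `alpha` (default 0.8, user-overridable) is a safety factor absorbing
   container overhead not captured by the serialized footprint; the
   floor-at-1 guard means even a budget below one read's footprint
   completes, degenerating to one-read chunks.
3. **Sort phase.** Chunks of `c_size` units are sorted by key and
   *locally collapsed* (equal neighbours merged) before being written as a
   run. Local collapsing is part of the contract, not an optimization: it
   guarantees runs contain strictly increasing keys, which the merge phase
   verifies as an integrity check.
4. **Merge phase.** The M runs are merged with at most
   `floor(c_size / M)` tags buffered per run (floored at one tag when
   M > c_size, where the total bound degrades gracefully from `c_size` to M
   buffered tags). A binary heap over the buffered run heads replaces a
   literal repeated selection-sort scan; the emitted stream — globally
   sorted, globally unique, counts merged across runs — is identical, and
   that stream is the contract.

Output is byte-identical across chunk sizes, repeated runs and thread
counts (the `--threads` flag exists for interface parity; sorting is
single-threaded and the flag provably does not affect output). Temporary
runs use a private length-prefixed binary record format, are never exposed,
and are deleted on success; partial outputs are removed on failure.

SAM/BAM input is collapsed on the stored SEQ/QUAL fields verbatim; records
with SEQ `*` are rejected, and FLAG-based orientation is ignored (a read
stored reverse-complemented by an aligner is a different byte string and a
different tag).

## Output dialects

- **fasta/fastq**: headers `<stem>.<rank>_<count>` with `rank` the 0-based
  output ordinal; the count is the decimal suffix after the *last*
  underscore, which survives aligners that truncate names at whitespace.
  Paired tags go to two synchronized `_1`/`_2` mate files with identical
  headers, directly feedable to paired-end aligners.
- **tag**: `sequence<TAB>count` (paired: `mate1<TAB>mate2<TAB>count`).
- **tagq**: tag plus the averaged quality string(s) appended.
- **splitting**: with `--split-bytes` the writer starts a new numbered file
  (`out.000.tag`, `out.001.tag`, ...) before a record would exceed the
  budget; records are never split, so concatenating the parts reproduces
  the unsplit file byte-for-byte.
- **occurrence table** (multi-sample): TSV with header
  `id<TAB>sequence<TAB><sample names...>`, one row per tag in output order;
  paired sequences join mates with `|`. Row sums equal the tag's total
  count; column sums equal each sample's read count.

## Expansion

The expander parses the count from each alignment record's name and writes
the record that many times, consecutively, touching no mapping field
(FLAG, RNAME, POS, MAPQ, CIGAR, SEQ, QUAL are copied verbatim). Replicas
get unique names — count suffix removed, `.r<k>` appended — because many
downstream tools assume QNAME uniqueness. Multi-mapped reads need no
special handling: every record bearing a count is replicated, so whatever
placement policy the aligner used (random assignment, first position,
all-secondary) is preserved unchanged. Multi-sample expansion looks each
name up in the occurrence table and routes `counts[tag, sample]` copies
into that sample's file; a zero count omits the record. Strict mode fails
on unparsable or unknown names; lenient mode treats an unparsable name as
count 1 with a warning, for files whose aligner rewrote read names.
Original per-read qualities are not restored — they live only in the
uncollapsed input.

## Synthetic samples and what they show

The generator emits FASTQ with exactly known duplication: `n_unique`
distinct sequences by enumerative base-4 encoding of 0..n-1 (distinct by
construction), copy numbers from a constant, geometric or Zipf law (Zipf
draws capped at 1000 copies to bound sample sizes under heavy tails),
per-copy qualities jittered independently around a base Phred of 35 ± 3
(clamped to [2, 41], a typical Illumina range) so quality averaging is
exercised nontrivially, and a seeded shuffle so the sorter faces unsorted
input. Gzip members are written with a zeroed timestamp, making same-seed
output byte-identical.

What it does not emulate: sequencing errors, adapters, quality-by-cycle
decay, or realistic genomic sequence composition. Tests passing on these
samples demonstrate the collapsing arithmetic and bookkeeping are exact for
any input — which is the whole claim of an exact collapser — but say
nothing about biological interpretation of real libraries.

## Problem sizes in the test suite

The suite validates the oracle-equivalence property on 200 randomized
samples (reads in the low hundreds each; SE, PE and interleaved; all three
duplication laws) with chunk capacity forced to {1, 2, 3, 5, n, n+1},
chosen so the full suite runs in well under a minute while still forcing
every merge topology from one-read runs to a single in-memory chunk.
Correctness is size-independent by construction: the engine's behaviour
depends on the data only through key comparisons, which these sizes cover
exhaustively at small scale.

## Known limitations

- Quality encodings other than Phred+33 are not interpreted (bytes are
  still collapsed correctly; averages would be offset).
- CRAM is unsupported; BAM is supported through the pysam codec.
- Collapsing aligned SAM does not canonicalize reverse-complemented
  storage; collapse before alignment if strand-agnostic identity matters.
- Only average quality consensus is offered (not max/sum policies).
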