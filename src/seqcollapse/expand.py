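"""Restore redundancy in alignments produced from collapsed reads.

Aligners see one record per unique tag; the tag's occurrence count rides in
the read name (``<stem>.<rank>_<count>``).  The expander replicates every
alignment record by its count — so downstream tools see the multiplicity the
raw sample would have produced — without touching any mapping field.  In
multi-sample mode the per-sample occurrence table routes the right number of
copies into each sample's output.

Replicas get unique names: the count suffix is removed and a per-copy
``.r<k>`` suffix appended, since duplicate QNAMEs upset many downstream
tools.  Multi-mapped reads are handled trivially: every record bearing a
count is replicated, so whichever placement policy the aligner used is
preserved — the expander never chooses loci.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pysam

from .core import FormatError

__all__ = [
    "OccurrenceTable",
    "parse_count",
    "strip_count",
    "expand_records",
    "expand_alignments",
    "expand_multi",
]

logger = logging.getLogger(__name__)


def parse_count(read_name: str, strict: bool = True) -> int:
    """Extract the occurrence count: the decimal suffix after the last '_'.

    In lenient mode an unparsable name counts as 1 (with a warning), for
    files whose aligner rewrote the read names.
    """
    base, sep, suffix = read_name.rpartition("_")
    if sep and suffix.isdigit() and int(suffix) >= 1:
        return int(suffix)
    if strict:
        raise FormatError(
            f"read name {read_name!r} carries no count suffix "
            "(expected '..._<count>')"
        )
    logger.warning("read name %r has no count suffix; assuming count 1", read_name)
    return 1


def strip_count(read_name: str) -> str:
    """Read name with the count suffix removed (identity if none)."""
    base, sep, suffix = read_name.rpartition("_")
    if sep and suffix.isdigit() and int(suffix) >= 1:
        return base
    return read_name


@dataclass
class OccurrenceTable:
    """Tag-by-sample count matrix from multi-sample collapsing.

    TSV layout: header ``id<TAB>sequence<TAB><sample names...>``, one row per
    tag in output order; paired sequences join mates with '|'.
    """

    samples: list[str]
    rows: list[tuple[str, str, np.ndarray]]

    def __post_init__(self) -> None:
        self._by_id: dict[str, np.ndarray] | None = None
        for tag_id, _, counts in self.rows:
            if len(counts) != len(self.samples):
                raise FormatError(
                    f"row {tag_id!r}: {len(counts)} counts for "
                    f"{len(self.samples)} samples"
                )

    def counts_for(self, tag_id: str) -> np.ndarray | None:
        if self._by_id is None:
            self._by_id = {tid: c for tid, _, c in self.rows}
        return self._by_id.get(tag_id)

    def write_tsv(self, path: str | os.PathLike) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            fh.write("id\tsequence\t" + "\t".join(self.samples) + "\n")
            for tag_id, seq, counts in self.rows:
                fh.write(tag_id + "\t" + seq + "\t"
                         + "\t".join(str(int(c)) for c in counts) + "\n")
        return path

    @classmethod
    def read_tsv(cls, path: str | os.PathLike) -> "OccurrenceTable":
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            if len(header) < 3 or header[0] != "id" or header[1] != "sequence":
                raise FormatError(f"{path}: not an occurrence table")
            samples = header[2:]
            rows = []
            for ln, line in enumerate(fh, start=2):
                fields = line.rstrip("\n").split("\t")
                if len(fields) != len(header):
                    raise FormatError(f"{path}: line {ln}: wrong column count")
                counts = np.array([int(x) for x in fields[2:]], dtype=np.int64)
                rows.append((fields[0], fields[1], counts))
        return cls(samples=samples, rows=rows)


def _replicas(
    rec: pysam.AlignedSegment,
    count: int,
    header: pysam.AlignmentHeader,
) -> Iterator[pysam.AlignedSegment]:
    base = strip_count(rec.query_name)
    text = rec.to_string()
    for k in range(1, count + 1):
        copy = pysam.AlignedSegment.fromstring(text, header)
        copy.query_name = f"{base}.r{k}"
        yield copy


def expand_records(
    records: Iterable[pysam.AlignedSegment],
    header: pysam.AlignmentHeader,
    mode: str = "strict",
) -> Iterator[pysam.AlignedSegment]:
    """Yield each record ``parse_count(name)`` times, consecutively, with
    unique per-copy names; every other field is copied verbatim."""
    strict = mode == "strict"
    for rec in records:
        count = parse_count(rec.query_name, strict=strict)
        yield from _replicas(rec, count, header)


def expand_alignments(
    in_path: str | os.PathLike,
    out_path: str | os.PathLike,
    mode: str = "strict",
) -> int:
    """Expand a SAM/BAM file in place of its collapsed redundancy; returns
    the number of records written."""
    from .seqio import read_alignments, write_alignments

    with read_alignments(in_path) as aln:
        header = aln.header
        return write_alignments(
            expand_records(aln.fetch(until_eof=True), header, mode=mode),
            out_path,
            header,
        )


def expand_multi(
    in_path: str | os.PathLike,
    table: OccurrenceTable,
    out_dir: str | os.PathLike,
    mode: str = "strict",
) -> dict[str, Path]:
    """Split one aligned, collapsed SAM/BAM back into per-sample expanded
    files using the occurrence table; a zero count omits the record from
    that sample.  Returns sample name -> written path."""
    from .seqio import read_alignments

    in_path = Path(in_path)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ext = ".bam" if in_path.suffix == ".bam" else ".sam"
    strict = mode == "strict"

    with read_alignments(in_path) as aln:
        header = aln.header
        mode_w = "wb" if ext == ".bam" else "w"
        writers = {
            s: pysam.AlignmentFile(str(out_dir / f"{s}{ext}"), mode_w, header=header)
            for s in table.samples
        }
        try:
            for rec in aln.fetch(until_eof=True):
                counts = table.counts_for(rec.query_name)
                if counts is None:
                    if strict:
                        raise FormatError(
                            f"read name {rec.query_name!r} not found in the "
                            "occurrence table"
                        )
                    logger.warning(
                        "read name %r not in occurrence table; skipped",
                        rec.query_name,
                    )
                    continue
                for s, c in zip(table.samples, counts):
                    for copy in _replicas(rec, int(c), header):
                        writers[s].write(copy)
        finally:
            for w in writers.values():
                w.close()
    return {s: out_dir / f"{s}{ext}" for s in table.samples}
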