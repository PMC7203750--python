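"""Readers and writers for every supported read layout and output format.

Input: FASTA/FASTQ (optionally gzipped) and SAM/BAM, in single-end,
two-file paired, interleaved-paired or joined-mates layouts.  Output: the
four collapsed formats — fasta, fastq, tag, tagq — with occurrence counts
carried in headers (fasta/fastq) or in a TSV column (tag/tagq), plus
byte-budgeted output splitting.

Header grammar for counts: ``<stem>.<rank>_<count>`` where ``rank`` is the
0-based ordinal of the tag in the sorted output and ``count`` the decimal
occurrence count after the LAST underscore.  This survives aligners that
truncate names at whitespace and is what the expander parses back.

TAG is ``sequence<TAB>count`` (paired: ``mate1<TAB>mate2<TAB>count``);
TAGQ appends the averaged quality string(s): ``sequence<TAB>count<TAB>qual``
(paired: ``mate1<TAB>mate2<TAB>count<TAB>qual1<TAB>qual2``).
"""

from __future__ import annotations

import gzip
import itertools
import os
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Iterable, Iterator

import pysam
from Bio.SeqIO.FastaIO import SimpleFastaParser
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .core import FormatError, ReadRecord, Tag, average_quality

__all__ = [
    "SampleSpec",
    "read_units",
    "write_tags",
    "tag_name",
    "read_alignments",
    "write_alignments",
    "detect_format",
]

FORMATS = ("fastq", "fasta", "sam", "bam")
LAYOUTS = ("single", "paired_files", "interleaved", "joined")
OUTPUT_FORMATS = ("fasta", "fastq", "tag", "tagq")

_EXT_FORMAT = {
    ".fa": "fasta",
    ".fasta": "fasta",
    ".fna": "fasta",
    ".fq": "fastq",
    ".fastq": "fastq",
    ".sam": "sam",
    ".bam": "bam",
    ".tag": "tag",
    ".tagq": "tagq",
}


def detect_format(path: str | os.PathLike) -> str:
    """Guess a format from the file extension (``.gz`` stripped first)."""
    p = Path(path)
    suffixes = p.suffixes
    if suffixes and suffixes[-1] == ".gz":
        suffixes = suffixes[:-1]
    if suffixes and suffixes[-1] in _EXT_FORMAT:
        return _EXT_FORMAT[suffixes[-1]]
    raise FormatError(f"cannot detect format of {p.name!r}; pass an explicit format")


def _is_gzip(path: str | os.PathLike) -> bool:
    return str(path).endswith(".gz")


def _open_text(path: str | os.PathLike, mode: str = "rt") -> IO[str]:
    if _is_gzip(path):
        return gzip.open(path, mode)
    return open(path, mode)


@dataclass(frozen=True)
class SampleSpec:
    """One input sample: path(s), format, layout and an optional display name."""

    paths: tuple[str, ...]
    format: str
    layout: str = "single"
    breakpoint: int | None = None
    name: str | None = None

    def __post_init__(self) -> None:
        if self.format not in FORMATS:
            raise FormatError(f"unknown input format {self.format!r}")
        if self.layout not in LAYOUTS:
            raise FormatError(f"unknown layout {self.layout!r}")
        n = len(self.paths)
        if self.layout == "paired_files" and n != 2:
            raise FormatError("paired_files layout needs exactly two paths")
        if self.layout != "paired_files" and n != 1:
            raise FormatError(f"layout {self.layout!r} needs exactly one path")
        if self.layout == "joined" and (self.breakpoint is None or self.breakpoint <= 0):
            raise FormatError("joined layout needs a positive breakpoint")

    @property
    def is_paired(self) -> bool:
        return self.layout in ("paired_files", "interleaved", "joined")

    @property
    def sample_name(self) -> str:
        if self.name:
            return self.name
        stem = Path(self.paths[0]).name
        for _ in range(3):  # peel .gz and the format extension
            stem_path = Path(stem)
            if stem_path.suffix:
                stem = stem_path.stem
            else:
                break
        return stem

    @classmethod
    def from_paths(
        cls,
        paths: Iterable[str | os.PathLike],
        format: str | None = None,
        layout: str | None = None,
        breakpoint: int | None = None,
        name: str | None = None,
    ) -> "SampleSpec":
        """Build a spec with extension-based format detection (explicit wins)."""
        paths = tuple(str(p) for p in paths)
        fmt = format or detect_format(paths[0])
        if layout is None:
            layout = "paired_files" if len(paths) == 2 else "single"
            if breakpoint is not None:
                layout = "joined"
        return cls(paths=paths, format=fmt, layout=layout,
                   breakpoint=breakpoint, name=name)


def _fastq_records(path: str, mate: str) -> Iterator[ReadRecord]:
    with _open_text(path) as fh:
        it = FastqGeneralIterator(fh)
        i = 0
        while True:
            try:
                title, seq, qual = next(it)
            except StopIteration:
                return
            except ValueError as exc:
                raise FormatError(f"{path}: malformed FASTQ at record {i}: {exc}") from exc
            if len(seq) != len(qual):
                raise FormatError(
                    f"{path}: record {i} ({title.split()[0]!r}): sequence/quality "
                    "length mismatch"
                )
            yield ReadRecord(id=title.split()[0], seq=seq, qual=qual, mate=mate)
            i += 1


def _fasta_records(path: str, mate: str) -> Iterator[ReadRecord]:
    with _open_text(path) as fh:
        for title, seq in SimpleFastaParser(fh):
            yield ReadRecord(id=title.split()[0], seq=seq, mate=mate)


def _sam_records(path: str, fmt: str, mate: str) -> Iterator[ReadRecord]:
    mode = "rb" if fmt == "bam" else "r"
    with pysam.AlignmentFile(path, mode, check_sq=False) as fh:
        for i, rec in enumerate(fh.fetch(until_eof=True)):
            seq = rec.query_sequence
            if seq is None:
                raise FormatError(
                    f"{path}: record {i} ({rec.query_name!r}) has SEQ '*'; "
                    "sequence-less records cannot be collapsed"
                )
            qual = None
            if rec.query_qualities is not None:
                qual = pysam.qualities_to_qualitystring(rec.query_qualities)
            yield ReadRecord(id=rec.query_name, seq=seq, qual=qual, mate=mate)


def _records(path: str, fmt: str, mate: str = "single") -> Iterator[ReadRecord]:
    if fmt == "fastq":
        return _fastq_records(path, mate)
    if fmt == "fasta":
        return _fasta_records(path, mate)
    if fmt in ("sam", "bam"):
        return _sam_records(path, fmt, mate)
    raise FormatError(f"unreadable format {fmt!r}")


def read_units(spec: SampleSpec) -> Iterator[tuple[ReadRecord, ReadRecord | None]]:
    """Yield read units — single records or mate pairs — in file order.

    Interleaved files pair records (2i, 2i+1); two-file layouts pair the i-th
    record of each file; joined-mates records are yielded whole (the collapse
    key applies the breakpoint).  Gzip input is decoded transparently.
    """
    if spec.layout == "single" or spec.layout == "joined":
        for rec in _records(spec.paths[0], spec.format):
            yield rec, None
    elif spec.layout == "interleaved":
        it = _records(spec.paths[0], spec.format, mate="mate1")
        while True:
            try:
                r1 = next(it)
            except StopIteration:
                return
            try:
                r2 = next(it)
            except StopIteration:
                raise FormatError(
                    f"{spec.paths[0]}: odd record count in interleaved file; "
                    f"trailing read {r1.id!r} has no mate"
                ) from None
            yield r1, ReadRecord(id=r2.id, seq=r2.seq, qual=r2.qual, mate="mate2")
    elif spec.layout == "paired_files":
        it1 = _records(spec.paths[0], spec.format, mate="mate1")
        it2 = _records(spec.paths[1], spec.format, mate="mate2")
        for r1, r2 in itertools.zip_longest(it1, it2):
            if r1 is None or r2 is None:
                lonely = r2 if r1 is None else r1
                raise FormatError(
                    f"paired files {spec.paths[0]} / {spec.paths[1]} have unequal "
                    f"record counts (unmatched read {lonely.id!r})"
                )
            yield r1, r2
    else:  # pragma: no cover - guarded by SampleSpec
        raise FormatError(f"unknown layout {spec.layout!r}")


def tag_name(stem: str, rank: int, count: int) -> str:
    """Header name of an output tag: ``<stem>.<rank>_<count>``."""
    return f"{stem}.{rank}_{count}"


def _output_stem(out_path: Path) -> str:
    name = out_path.name
    if name.endswith(".gz"):
        name = name[:-3]
    return Path(name).stem or name


class _SplitWriter:
    """Byte-budgeted writer: rolls to a new numbered file before a record
    would push the current file past ``split_bytes``; never splits a record."""

    def __init__(self, path: Path, split_bytes: int | None):
        self.path = path
        self.split_bytes = split_bytes
        self.index = 0
        self.written = 0
        self.fh: IO[bytes] | None = None
        self.paths: list[Path] = []

    def _part_path(self) -> Path:
        if self.split_bytes is None:
            return self.path
        name = self.path.name
        gz = name.endswith(".gz")
        if gz:
            name = name[:-3]
        p = Path(name)
        part = f"{p.stem}.{self.index:03d}{p.suffix}" + (".gz" if gz else "")
        return self.path.parent / part

    def _open(self) -> None:
        path = self._part_path()
        self.fh = gzip.open(path, "wb") if _is_gzip(path) else open(path, "wb")
        self.paths.append(path)
        self.written = 0

    def would_roll(self, n_bytes: int) -> bool:
        return (
            self.split_bytes is not None
            and self.fh is not None
            and self.written > 0
            and self.written + n_bytes > self.split_bytes
        )

    def roll(self) -> None:
        if self.fh is not None:
            self.fh.close()
            self.index += 1
            self.fh = None

    def write(self, data: bytes) -> None:
        if self.fh is None:
            self._open()
        self.fh.write(data)
        self.written += len(data)

    def close(self) -> None:
        if self.fh is None:
            self._open()  # materialize an (empty) output even with no tags
        self.fh.close()
        self.fh = None

    def abort(self) -> None:
        if self.fh is not None:
            self.fh.close()
            self.fh = None
        for p in self.paths:
            try:
                os.unlink(p)
            except OSError:
                pass


def _mate_paths(out_path: Path) -> tuple[Path, Path]:
    name = out_path.name
    gz = ".gz" if name.endswith(".gz") else ""
    if gz:
        name = name[:-3]
    p = Path(name)
    return (
        out_path.parent / f"{p.stem}_1{p.suffix}{gz}",
        out_path.parent / f"{p.stem}_2{p.suffix}{gz}",
    )


def _format_record(
    t: Tag, name: str, fmt: str
) -> tuple[bytes, ...]:
    """Serialize one tag; paired fasta/fastq yield one chunk per mate file."""
    seqs = t.mate_seqs
    if fmt in ("fastq", "tagq"):
        quals = average_quality(t)
    if fmt == "fasta":
        return tuple(f">{name}\n{s}\n".encode("ascii") for s in seqs)
    if fmt == "fastq":
        return tuple(
            f"@{name}\n{s}\n+\n{q}\n".encode("ascii") for s, q in zip(seqs, quals)
        )
    if fmt == "tag":
        return ("\t".join(seqs).encode("ascii") + f"\t{t.count}\n".encode("ascii"),)
    if fmt == "tagq":
        line = "\t".join(seqs) + f"\t{t.count}\t" + "\t".join(quals) + "\n"
        return (line.encode("ascii"),)
    raise FormatError(f"unknown output format {fmt!r}")


def write_tags(
    tags: Iterable[Tag],
    out_path: str | os.PathLike,
    format: str = "tag",
    split_bytes: int | None = None,
    stem: str | None = None,
    on_tag=None,
) -> list[Path]:
    """Write a sorted tag stream; returns the paths written, in order.

    Paired tags go to two synchronized ``_1``/``_2`` mate files for
    fasta/fastq, or to tab-joined columns for tag/tagq.  ``on_tag(rank, name,
    tag)``, if given, is invoked per tag as it is written (used to build the
    multi-sample occurrence table in one pass).
    """
    if format not in OUTPUT_FORMATS:
        raise FormatError(f"unknown output format {format!r}")
    out_path = Path(out_path)
    stem = stem if stem is not None else _output_stem(out_path)
    needs_qual = format in ("fastq", "tagq")

    writers: list[_SplitWriter] | None = None
    try:
        rank = 0
        for t in tags:
            if needs_qual and t.qual_sum is None:
                raise FormatError(
                    f"output format {format!r} needs qualities but tag {rank} "
                    "carries none; choose fasta or tag instead"
                )
            chunks = _format_record(t, tag_name(stem, rank, t.count), format)
            if writers is None:
                if len(chunks) == 2 and format in ("fasta", "fastq"):
                    writers = [_SplitWriter(p, split_bytes) for p in _mate_paths(out_path)]
                else:
                    writers = [_SplitWriter(out_path, split_bytes)]
            if len(chunks) != len(writers):
                raise FormatError("mixed single/paired tags in one output stream")
            # mate files roll together so record ranks stay aligned
            if any(w.would_roll(len(c)) for w, c in zip(writers, chunks)):
                for w in writers:
                    w.roll()
            for w, c in zip(writers, chunks):
                w.write(c)
            if on_tag is not None:
                on_tag(rank, tag_name(stem, rank, t.count), t)
            rank += 1
        if writers is None:  # empty input: well-formed empty output
            writers = [_SplitWriter(out_path, split_bytes)]
        for w in writers:
            w.close()
    except BaseException:
        if writers is not None:
            for w in writers:
                w.abort()
        raise
    paths: list[Path] = []
    for w in writers:
        paths.extend(w.paths)
    return paths


def read_alignments(path: str | os.PathLike) -> pysam.AlignmentFile:
    """Open a SAM/BAM alignment file for reading (header required)."""
    fmt = detect_format(path)
    if fmt not in ("sam", "bam"):
        raise FormatError(f"{path}: not an alignment file")
    return pysam.AlignmentFile(str(path), "rb" if fmt == "bam" else "r", check_sq=False)


def write_alignments(
    records: Iterable[pysam.AlignedSegment],
    path: str | os.PathLike,
    header: pysam.AlignmentHeader,
) -> int:
    """Write SAM/BAM records under the given header; returns records written."""
    fmt = detect_format(path)
    mode = "wb" if fmt == "bam" else "w"
    n = 0
    with pysam.AlignmentFile(str(path), mode, header=header) as out:
        for rec in records:
            out.write(rec)
            n += 1
    return n
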