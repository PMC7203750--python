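"""Shared helpers: tiny FASTQ/FASTA writers and the in-memory collapse oracle."""

from __future__ import annotations

from collections import Counter
from pathlib import Path


def write_fastq(path, records) -> Path:
    """records: iterable of (name, seq, qual)."""
    path = Path(path)
    with open(path, "w") as fh:
        for name, seq, qual in records:
            fh.write(f"@{name}\n{seq}\n+\n{qual}\n")
    return path


def write_fasta(path, records) -> Path:
    """records: iterable of (name, seq)."""
    path = Path(path)
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n{seq}\n")
    return path


def oracle_collapse(keys) -> list[tuple[bytes, int]]:
    """Reference collapser: associative counting then a single in-memory sort.

    Independent of the external-sort path: no chunking, no runs, no merging.
    """
    counts = Counter(keys)
    return sorted(counts.items())


def read_tag_lines(path) -> list[tuple[bytes, int]]:
    """Parse a tag-format file back to (key, count); mates re-joined with the
    separator byte so the result is comparable to collapse keys."""
    from seqcollapse.core import MATE_SEPARATOR

    out = []
    with open(path, "rb") as fh:
        for line in fh:
            fields = line.rstrip(b"\n").split(b"\t")
            key = MATE_SEPARATOR.join(fields[:-1])
            out.append((key, int(fields[-1])))
    return out
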