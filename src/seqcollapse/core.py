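"""Core data model for exact read collapsing.

Two reads (or mate pairs) are "the same" exactly when their sequences are
byte-identical; no case normalization, no N-handling, no approximate keys.
A collapsed unique read is a :class:`Tag`: its key, its occurrence count and,
optionally, an exact per-position sum of the Phred qualities of every
contributing read, from which an average consensus quality is derived on
output.  Chunk-size arithmetic for the external sort lives in
:class:`ChunkPlan`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PHRED_OFFSET",
    "PHRED_MAX",
    "MATE_SEPARATOR",
    "FormatError",
    "ReadRecord",
    "Tag",
    "ChunkPlan",
    "make_key",
    "merge_tags",
    "average_quality",
]

PHRED_OFFSET = 33
#: highest encodable Phred value ('~' == chr(33 + 93))
PHRED_MAX = 93

#: Byte separating mate-1 from mate-2 inside a paired-end collapse key.
#: 0x01 sorts below every ASCII letter, so a shorter mate-1 sorts before any
#: of its extensions and paired keys have a well-defined total order.
MATE_SEPARATOR = b"\x01"


class FormatError(ValueError):
    """Malformed or inconsistent input (bad quality string, bad breakpoint, ...)."""


@dataclass(frozen=True)
class ReadRecord:
    """One sequenced read: identifier, bases and optional Phred+33 qualities.

    ``id`` is the name token only (anything after the first whitespace in a
    FASTQ/FASTA header is dropped by the readers).  ``mate`` is ``"single"``,
    ``"mate1"`` or ``"mate2"``.
    """

    id: str
    seq: str
    qual: str | None = None
    mate: str = "single"

    def __post_init__(self) -> None:
        if self.qual is not None:
            if len(self.qual) != len(self.seq):
                raise FormatError(
                    f"read {self.id!r}: quality length {len(self.qual)} "
                    f"!= sequence length {len(self.seq)}"
                )
            for ch in self.qual:
                if not (33 <= ord(ch) <= 126):
                    raise FormatError(
                        f"read {self.id!r}: quality character {ch!r} outside "
                        "printable Phred+33 range"
                    )
        if self.mate not in ("single", "mate1", "mate2"):
            raise ValueError(f"invalid mate label {self.mate!r}")


def make_key(
    r1: ReadRecord,
    r2: ReadRecord | None = None,
    breakpoint: int | None = None,
) -> bytes:
    """Build the byte string on which read identity and sort order are defined.

    Single-end: the sequence verbatim.  Paired-end: mate-1 bytes, the
    :data:`MATE_SEPARATOR` byte, mate-2 bytes.  Joined-mates input (both mates
    concatenated in one read with a fixed break-point) produces exactly the
    paired key of ``(seq[:breakpoint], seq[breakpoint:])``.
    """
    if r2 is not None and breakpoint is not None:
        raise ValueError("give either a second mate or a breakpoint, not both")
    if breakpoint is not None:
        if not 0 < breakpoint < len(r1.seq):
            raise FormatError(
                f"read {r1.id!r}: breakpoint {breakpoint} not inside read of "
                f"length {len(r1.seq)}"
            )
        return (
            r1.seq[:breakpoint].encode("ascii")
            + MATE_SEPARATOR
            + r1.seq[breakpoint:].encode("ascii")
        )
    if r2 is not None:
        if r1.mate == "mate2" or r2.mate == "mate1":
            raise FormatError(
                f"inconsistent mate labels for pair ({r1.id!r}, {r2.id!r})"
            )
        return r1.seq.encode("ascii") + MATE_SEPARATOR + r2.seq.encode("ascii")
    return r1.seq.encode("ascii")


@dataclass
class Tag:
    """A collapsed unique read: key, occurrence count, accumulated qualities.

    ``qual_sum`` holds one integer vector per mate (exact running sums, so
    incremental merging never drifts); ``sample_counts`` is set only in
    multi-sample mode and always sums to ``count``.
    """

    key: bytes
    count: int = 1
    qual_sum: tuple[np.ndarray, ...] | None = None
    sample_counts: np.ndarray | None = None

    @property
    def is_paired(self) -> bool:
        return MATE_SEPARATOR in self.key

    @property
    def mate_seqs(self) -> tuple[str, ...]:
        return tuple(p.decode("ascii") for p in self.key.split(MATE_SEPARATOR))

    def validate(self) -> None:
        if self.count < 1:
            raise ValueError("tag count must be >= 1")
        if self.qual_sum is not None:
            lengths = tuple(len(p) for p in self.key.split(MATE_SEPARATOR))
            got = tuple(len(q) for q in self.qual_sum)
            if got != lengths:
                raise ValueError(
                    f"qual_sum lengths {got} do not match mate lengths {lengths}"
                )
        if self.sample_counts is not None and int(self.sample_counts.sum()) != self.count:
            raise ValueError("sample_counts must sum to count")


def tag_from_unit(
    r1: ReadRecord,
    r2: ReadRecord | None = None,
    breakpoint: int | None = None,
    keep_quality: bool = True,
    n_samples: int | None = None,
    sample_index: int = 0,
) -> Tag:
    """Turn one read unit (a read or a mate pair) into a count-1 Tag."""
    key = make_key(r1, r2, breakpoint)
    qual_sum = None
    if keep_quality and r1.qual is not None:
        if breakpoint is not None:
            parts = (r1.qual[:breakpoint], r1.qual[breakpoint:])
        elif r2 is not None:
            if r2.qual is None:
                raise FormatError(
                    f"pair ({r1.id!r}, {r2.id!r}): only one mate carries quality"
                )
            parts = (r1.qual, r2.qual)
        else:
            parts = (r1.qual,)
        qual_sum = tuple(
            np.frombuffer(p.encode("ascii"), dtype=np.uint8).astype(np.int64)
            - PHRED_OFFSET
            for p in parts
        )
    sample_counts = None
    if n_samples is not None:
        sample_counts = np.zeros(n_samples, dtype=np.int64)
        sample_counts[sample_index] = 1
    return Tag(key=key, count=1, qual_sum=qual_sum, sample_counts=sample_counts)


def merge_tags(a: Tag, b: Tag) -> Tag:
    """Merge two tags with equal keys: counts add, quality sums add elementwise."""
    if a.key != b.key:
        raise AssertionError("merge_tags called on tags with different keys")
    if (a.qual_sum is None) != (b.qual_sum is None):
        raise FormatError("cannot merge a quality-bearing tag with a quality-less one")
    qual_sum = None
    if a.qual_sum is not None:
        qual_sum = tuple(x + y for x, y in zip(a.qual_sum, b.qual_sum, strict=True))
    sample_counts = None
    if a.sample_counts is not None and b.sample_counts is not None:
        sample_counts = a.sample_counts + b.sample_counts
    return Tag(
        key=a.key,
        count=a.count + b.count,
        qual_sum=qual_sum,
        sample_counts=sample_counts,
    )


def average_quality(t: Tag) -> tuple[str, ...]:
    """Average consensus quality of a tag, one Phred+33 string per mate.

    Per position the Phred value is the arithmetic mean of the contributing
    reads' values, rounded half up ((2*sum + count) // (2*count), exact in
    integers) and clamped to [0, 93].
    """
    if t.qual_sum is None:
        raise FormatError("tag carries no quality information")
    out = []
    for sums in t.qual_sum:
        vals = (2 * sums + t.count) // (2 * t.count)
        vals = np.clip(vals, 0, PHRED_MAX)
        out.append((vals + PHRED_OFFSET).astype(np.uint8).tobytes().decode("ascii"))
    return tuple(out)


@dataclass
class ChunkPlan:
    """Memory-budget arithmetic of the external sort.

    From a probe of ``t_size`` read units with measured serialized footprint
    ``t_ram`` bytes, the number of units that fit in the user budget ``c_ram``
    is ``c_size = max(1, floor(alpha * c_ram * t_size / t_ram))`` where
    ``alpha`` in (0, 1] is an empirical safety factor for container overheads.
    ``m`` is the number of sorted runs actually produced.
    """

    t_size: int
    t_ram: int
    c_ram: int
    alpha: float
    c_size: int = field(init=False)
    m: int = 0

    def __post_init__(self) -> None:
        if self.c_ram <= 0:
            raise ValueError("RAM budget must be positive")
        if not 0 < self.alpha <= 1:
            raise ValueError("alpha must be in (0, 1]")
        if self.t_size <= 0 or self.t_ram <= 0:
            raise ValueError("probe must be nonempty")
        self.c_size = max(
            1, math.floor(self.alpha * self.c_ram * self.t_size / self.t_ram)
        )

    @classmethod
    def forced(cls, c_size: int) -> "ChunkPlan":
        """A plan with an explicitly imposed chunk capacity (testing, tuning)."""
        plan = cls(t_size=1, t_ram=1, c_ram=1, alpha=1.0)
        plan.c_size = max(1, int(c_size))
        return plan
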