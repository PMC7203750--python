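"""Memory-bounded external sort + merge–collapse engine.

The collapser never holds more than a budgeted number of read units in RAM.
Phase 1 (sort): the input stream is cut into chunks of at most ``c_size``
units; each chunk is sorted by collapse key, locally collapsed (equal
neighbours merged) and written to a temporary sorted run on disk.  Phase 2
(merge): the heads of all ``M`` runs are buffered — at most
``floor(c_size / M)`` tags per run, floored at one — and a k-way merge over
the run heads emits globally sorted, globally unique tags, merging equal
keys across runs as they meet.  The chunk capacity comes from a probe of the
input: ``c_size = alpha * c_ram * t_size / t_ram``.

Single- and multi-sample drivers wire this engine to the readers and
writers; multi-sample collapsing additionally emits a per-sample occurrence
table that the expander uses to restore per-sample redundancy.
"""

from __future__ import annotations

import itertools
import json
import struct
import tempfile
from collections import deque
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np

from .core import ChunkPlan, FormatError, Tag, merge_tags, tag_from_unit
from .expand import OccurrenceTable
from .seqio import SampleSpec, read_units, write_tags

__all__ = [
    "RunFile",
    "CollapseStats",
    "MemoryMeter",
    "estimate_chunk_size",
    "sort_phase",
    "merge_collapse",
    "collapse_single",
    "collapse_multi",
    "gain",
    "PROBE_SIZE",
    "DEFAULT_ALPHA",
]

#: number of leading read units probed to estimate per-unit memory footprint
PROBE_SIZE = 10_000
DEFAULT_ALPHA = 0.8
DEFAULT_RAM = 1 << 30

# serialized per-unit bookkeeping overhead assumed on top of payload bytes
_UNIT_OVERHEAD = 64


@dataclass
class RunFile:
    """One temporary sorted run: locally collapsed tags, strictly increasing keys."""

    path: Path
    n_tags: int
    sorted: bool = True


@dataclass
class CollapseStats:
    reads_in: int = 0
    tags_out: int = 0
    runs: int = 0
    per_sample_reads: dict[str, int] | None = None


class MemoryMeter:
    """Instrumentation hook recording peak residency of the two phases."""

    def __init__(self) -> None:
        self.max_sort_units = 0
        self.max_merge_tags = 0

    def sort_units(self, n: int) -> None:
        if n > self.max_sort_units:
            self.max_sort_units = n

    def merge_tags_buffered(self, n: int) -> None:
        if n > self.max_merge_tags:
            self.max_merge_tags = n


def tag_footprint(t: Tag) -> int:
    """Deterministic serialized in-memory footprint of one unit tag, in bytes."""
    n = len(t.key) + _UNIT_OVERHEAD
    if t.qual_sum is not None:
        n += 8 * sum(len(q) for q in t.qual_sum)
    if t.sample_counts is not None:
        n += 8 * len(t.sample_counts)
    return n


def estimate_chunk_size(
    sample_probe: Sequence[Tag], c_ram: int, alpha: float = DEFAULT_ALPHA
) -> ChunkPlan:
    """Measure the probe's footprint and derive the chunk capacity."""
    if not sample_probe:
        raise ValueError("probe is empty")
    t_ram = sum(tag_footprint(t) for t in sample_probe)
    return ChunkPlan(t_size=len(sample_probe), t_ram=t_ram, c_ram=c_ram, alpha=alpha)


# ---------------------------------------------------------------------------
# run serialization: private length-prefixed binary records
# ---------------------------------------------------------------------------

_HDR = struct.Struct("<IQB")  # key length, count, flags
_U32 = struct.Struct("<I")
_U8 = struct.Struct("<B")
_F_QUAL = 1
_F_SAMPLES = 2


def _write_tag(fh, t: Tag) -> None:
    flags = 0
    if t.qual_sum is not None:
        flags |= _F_QUAL
    if t.sample_counts is not None:
        flags |= _F_SAMPLES
    fh.write(_HDR.pack(len(t.key), t.count, flags))
    fh.write(t.key)
    if t.qual_sum is not None:
        fh.write(_U8.pack(len(t.qual_sum)))
        for q in t.qual_sum:
            fh.write(_U32.pack(len(q)))
            fh.write(np.ascontiguousarray(q, dtype="<i8").tobytes())
    if t.sample_counts is not None:
        fh.write(_U32.pack(len(t.sample_counts)))
        fh.write(np.ascontiguousarray(t.sample_counts, dtype="<i8").tobytes())


def _read_tag(fh) -> Tag | None:
    hdr = fh.read(_HDR.size)
    if not hdr:
        return None
    key_len, count, flags = _HDR.unpack(hdr)
    key = fh.read(key_len)
    qual_sum = None
    if flags & _F_QUAL:
        (n_mates,) = _U8.unpack(fh.read(1))
        parts = []
        for _ in range(n_mates):
            (n,) = _U32.unpack(fh.read(4))
            parts.append(np.frombuffer(fh.read(8 * n), dtype="<i8").astype(np.int64))
        qual_sum = tuple(parts)
    sample_counts = None
    if flags & _F_SAMPLES:
        (n,) = _U32.unpack(fh.read(4))
        sample_counts = np.frombuffer(fh.read(8 * n), dtype="<i8").astype(np.int64)
    return Tag(key=key, count=count, qual_sum=qual_sum, sample_counts=sample_counts)


# ---------------------------------------------------------------------------
# phase 1: sorted, locally collapsed runs
# ---------------------------------------------------------------------------


def _local_collapse(sorted_tags: list[Tag]) -> Iterator[Tag]:
    """Merge equal-key neighbours of an already sorted tag list."""
    it = iter(sorted_tags)
    cur = next(it, None)
    for t in it:
        if t.key == cur.key:
            cur = merge_tags(cur, t)
        else:
            yield cur
            cur = t
    if cur is not None:
        yield cur


def sort_phase(
    unit_tags: Iterable[Tag],
    plan: ChunkPlan,
    tmpdir: str | Path,
    meter: MemoryMeter | None = None,
) -> list[RunFile]:
    """Cut the unit stream into chunks of ``plan.c_size``, sort and collapse
    each, and write one run file per chunk.  Sets ``plan.m``."""
    tmpdir = Path(tmpdir)
    # fail before consuming input if the temp location is unusable
    probe = tmpdir / ".write-probe"
    probe.touch()
    probe.unlink()

    runs: list[RunFile] = []
    buf: list[Tag] = []

    def flush() -> None:
        buf.sort(key=lambda t: t.key)
        path = tmpdir / f"run{len(runs):05d}.bin"
        n = 0
        with open(path, "wb") as fh:
            for t in _local_collapse(buf):
                _write_tag(fh, t)
                n += 1
        runs.append(RunFile(path=path, n_tags=n))
        buf.clear()

    for t in unit_tags:
        buf.append(t)
        if meter is not None:
            meter.sort_units(len(buf))
        if len(buf) >= plan.c_size:
            flush()
    if buf:
        flush()
    plan.m = len(runs)
    return runs


# ---------------------------------------------------------------------------
# phase 2: buffered k-way merge–collapse
# ---------------------------------------------------------------------------


class _Shared:
    __slots__ = ("n",)

    def __init__(self) -> None:
        self.n = 0


class _RunReader:
    """Buffered reader over one run; refills its buffer from disk when drained
    and checks that keys never decrease within the run."""

    def __init__(self, run: RunFile, bufsize: int, shared: _Shared,
                 meter: MemoryMeter | None):
        self.run = run
        self.bufsize = bufsize
        self.shared = shared
        self.meter = meter
        self.fh = open(run.path, "rb")
        self.buf: deque[Tag] = deque()
        self.exhausted = False
        self.last_key: bytes | None = None
        self._refill()

    def _refill(self) -> None:
        if self.exhausted:
            return
        n = 0
        while n < self.bufsize:
            t = _read_tag(self.fh)
            if t is None:
                self.exhausted = True
                self.fh.close()
                break
            if self.last_key is not None and t.key <= self.last_key:
                raise FormatError(
                    f"run {self.run.path.name}: keys not strictly increasing"
                )
            self.last_key = t.key
            self.buf.append(t)
            n += 1
        self.shared.n += n
        if self.meter is not None:
            self.meter.merge_tags_buffered(self.shared.n)

    def peek(self) -> Tag | None:
        if not self.buf and not self.exhausted:
            self._refill()
        return self.buf[0] if self.buf else None

    def pop(self) -> Tag:
        t = self.buf.popleft()
        self.shared.n -= 1
        return t


def merge_collapse(
    runs: list[RunFile],
    plan: ChunkPlan,
    meter: MemoryMeter | None = None,
) -> Iterator[Tag]:
    """k-way merge over run heads, merging equal keys across runs.

    Per-run buffers hold at most ``floor(c_size / M)`` tags (floored at one
    when ``M > c_size``, in which case the bound degrades gracefully to M
    buffered tags).  A priority queue over the buffered heads replaces the
    literal selection-sort scan; the emitted stream is identical.
    """
    import heapq

    m = len(runs)
    if m == 0:
        return
    bufsize = max(1, plan.c_size // m)
    shared = _Shared()
    readers = [_RunReader(r, bufsize, shared, meter) for r in runs]

    heap: list[tuple[bytes, int]] = []
    for i, rd in enumerate(readers):
        head = rd.peek()
        if head is not None:
            heap.append((head.key, i))
    heapq.heapify(heap)

    while heap:
        key, i = heapq.heappop(heap)
        tag = readers[i].pop()
        nxt = readers[i].peek()
        if nxt is not None:
            heapq.heappush(heap, (nxt.key, i))
        # equal keys can only come from other runs (runs are locally collapsed)
        while heap and heap[0][0] == key:
            _, j = heapq.heappop(heap)
            tag = merge_tags(tag, readers[j].pop())
            nxt = readers[j].peek()
            if nxt is not None:
                heapq.heappush(heap, (nxt.key, j))
        yield tag


# ---------------------------------------------------------------------------
# drivers
# ---------------------------------------------------------------------------


def _write_report(out: str | Path, plan: ChunkPlan | None, stats: CollapseStats) -> Path:
    path = Path(f"{out}.stats.jsonl")
    with open(path, "w") as fh:
        if plan is not None:
            fh.write(json.dumps({
                "event": "chunk_plan",
                "t_size": plan.t_size, "t_ram": plan.t_ram,
                "c_ram": plan.c_ram, "alpha": plan.alpha,
                "c_size": plan.c_size, "m": plan.m,
            }) + "\n")
        rec = {
            "event": "collapse_stats",
            "reads_in": stats.reads_in,
            "tags_out": stats.tags_out,
            "runs": stats.runs,
        }
        if stats.per_sample_reads is not None:
            rec["per_sample_reads"] = stats.per_sample_reads
        if stats.reads_in:
            rec["read_gain_pct"] = gain(stats.reads_in, stats.tags_out)
        fh.write(json.dumps(rec) + "\n")
    return path


def _unit_tag_stream(
    spec: SampleSpec,
    keep_quality: bool,
    counter: dict,
    n_samples: int | None = None,
    sample_index: int = 0,
    sample_name: str | None = None,
) -> Iterator[Tag]:
    bp = spec.breakpoint if spec.layout == "joined" else None
    for r1, r2 in read_units(spec):
        counter["n"] += 1
        if sample_name is not None:
            counter["per_sample"][sample_name] += 1
        yield tag_from_unit(
            r1, r2, breakpoint=bp, keep_quality=keep_quality,
            n_samples=n_samples, sample_index=sample_index,
        )


def _check_quality_feasible(specs: Sequence[SampleSpec], format: str) -> None:
    if format in ("fastq", "tagq"):
        for s in specs:
            if s.format == "fasta":
                raise FormatError(
                    f"output format {format!r} needs qualities but {s.paths[0]} "
                    "is FASTA; choose fasta or tag output"
                )


def _run_pipeline(
    stream: Iterator[Tag],
    out: str | Path,
    format: str,
    c_ram: int,
    alpha: float,
    split_bytes: int | None,
    tmpdir: str | Path | None,
    chunk_size: int | None,
    meter: MemoryMeter | None,
    on_tag=None,
    stem: str | None = None,
) -> tuple[ChunkPlan | None, int]:
    """probe -> plan -> sort runs -> merge -> write; returns (plan, tags_out)."""
    probe = list(itertools.islice(stream, PROBE_SIZE))
    if not probe:
        write_tags(iter(()), out, format=format, split_bytes=split_bytes, stem=stem)
        return None, 0
    if chunk_size is not None:
        plan = ChunkPlan.forced(chunk_size)
    else:
        plan = estimate_chunk_size(probe, c_ram, alpha)
    n_out = 0

    def counting(rank: int, name: str, t: Tag) -> None:
        nonlocal n_out
        n_out = rank + 1
        if on_tag is not None:
            on_tag(rank, name, t)

    with tempfile.TemporaryDirectory(prefix="seqcollapse-", dir=tmpdir) as td:
        runs = sort_phase(itertools.chain(probe, stream), plan, td, meter=meter)
        tags = merge_collapse(runs, plan, meter=meter)
        write_tags(tags, out, format=format, split_bytes=split_bytes,
                   stem=stem, on_tag=counting)
    return plan, n_out


def collapse_single(
    spec: SampleSpec,
    out: str | Path,
    format: str = "tag",
    c_ram: int = DEFAULT_RAM,
    alpha: float = DEFAULT_ALPHA,
    split_bytes: int | None = None,
    tmpdir: str | Path | None = None,
    chunk_size: int | None = None,
    threads: int = 1,
    meter: MemoryMeter | None = None,
) -> CollapseStats:
    """Collapse one sample end to end; returns the run statistics.

    ``chunk_size`` forces the chunk capacity, bypassing the probe (testing /
    tuning).  ``threads`` is accepted for interface parity; output is
    identical for every value.  Qualities are carried only when the output
    format keeps them (fastq/tagq) — pay for what you use.
    """
    _check_quality_feasible([spec], format)
    keep_quality = format in ("fastq", "tagq")
    counter = {"n": 0}
    stream = _unit_tag_stream(spec, keep_quality, counter)
    plan, tags_out = _run_pipeline(
        stream, out, format, c_ram, alpha, split_bytes, tmpdir, chunk_size, meter
    )
    stats = CollapseStats(
        reads_in=counter["n"], tags_out=tags_out, runs=plan.m if plan else 0
    )
    _write_report(out, plan, stats)
    return stats


def _dedupe_names(specs: Sequence[SampleSpec]) -> list[str]:
    names: list[str] = []
    seen: dict[str, int] = {}
    for s in specs:
        base = s.sample_name
        k = seen.get(base, 0)
        seen[base] = k + 1
        names.append(base if k == 0 else f"{base}.{k}")
    return names


def collapse_multi(
    specs: Sequence[SampleSpec],
    out: str | Path,
    format: str = "tag",
    c_ram: int = DEFAULT_RAM,
    alpha: float = DEFAULT_ALPHA,
    tmpdir: str | Path | None = None,
    chunk_size: int | None = None,
    table_out: str | Path | None = None,
    threads: int = 1,
    meter: MemoryMeter | None = None,
) -> tuple[CollapseStats, OccurrenceTable]:
    """Collapse several samples jointly into one output plus an occurrence
    table whose rows align with the output tag order; each tag's total count
    equals the row sum of its per-sample counts."""
    if len(specs) < 2:
        raise ValueError("multi-sample collapsing needs at least two samples")
    pairedness = {s.is_paired for s in specs}
    if len(pairedness) > 1:
        raise FormatError("cannot mix single-end and paired-end samples")
    _check_quality_feasible(specs, format)
    keep_quality = format in ("fastq", "tagq")

    names = _dedupe_names(specs)
    counter = {"n": 0, "per_sample": {n: 0 for n in names}}
    stream = itertools.chain.from_iterable(
        _unit_tag_stream(s, keep_quality, counter, n_samples=len(specs),
                         sample_index=i, sample_name=names[i])
        for i, s in enumerate(specs)
    )

    rows: list[tuple[str, str, np.ndarray]] = []

    def on_tag(rank: int, name: str, t: Tag) -> None:
        rows.append((name, "|".join(t.mate_seqs), t.sample_counts.copy()))

    plan, tags_out = _run_pipeline(
        stream, out, format, c_ram, alpha, None, tmpdir, chunk_size, meter,
        on_tag=on_tag,
    )
    table = OccurrenceTable(samples=names, rows=rows)
    table.write_tsv(table_out if table_out is not None else f"{out}.occ.tsv")
    stats = CollapseStats(
        reads_in=counter["n"], tags_out=tags_out,
        runs=plan.m if plan else 0, per_sample_reads=counter["per_sample"],
    )
    _write_report(out, plan, stats)
    return stats, table


def gain(raw: float, collapsed: float) -> float:
    """Percent reduction (1 - collapsed/raw) * 100; the figure of merit for
    read counts, file sizes and run times alike."""
    if raw <= 0:
        raise ValueError("raw quantity must be positive")
    return (1.0 - collapsed / raw) * 100.0
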