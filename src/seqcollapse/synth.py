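"""Deterministic synthetic reads with controlled duplication and ground truth.

Distinct sequences are produced by enumerative base-4 encoding of the
integers 0..n_unique-1 (no rejection sampling, so distinctness is by
construction).  Per-sequence copy numbers follow a chosen duplication law;
copies share the sequence but get independently jittered qualities so
quality-averaging code paths are exercised nontrivially.  Reads are shuffled
after duplication so the sort/merge phases face unsorted input.  The same
seed always yields byte-identical files (gzip members are written with a
zeroed timestamp).
"""

from __future__ import annotations

import gzip
import os
from dataclasses import dataclass
from pathlib import Path
from typing import IO

import numpy as np

from .core import MATE_SEPARATOR

__all__ = ["DuplicationModel", "generate_sample"]

_BASES = "ACGT"
#: cap on per-tag copies under the heavy-tailed zipf law, to bound sample size
_ZIPF_CAP = 1000


@dataclass(frozen=True)
class DuplicationModel:
    """Parameters of one synthetic sample.

    ``law`` is ``constant`` (every sequence appears ``law_param`` times),
    ``geometric`` (copy numbers ~ Geometric(law_param), support >= 1) or
    ``zipf`` (copy numbers ~ Zipf(law_param), capped at 1000).
    ``qual_mu``/``qual_jitter``: each copy's per-base Phred value is
    ``qual_mu`` plus an integer in [-jitter, +jitter], clamped to [2, 41].
    """

    n_unique: int
    law: str = "constant"
    law_param: float = 4
    read_len: int = 36
    layout: str = "single"  # single | paired | interleaved
    qual_mu: int = 35
    qual_jitter: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_unique < 1:
            raise ValueError("n_unique must be >= 1")
        if self.law not in ("constant", "geometric", "zipf"):
            raise ValueError(f"unknown duplication law {self.law!r}")
        if self.layout not in ("single", "paired", "interleaved"):
            raise ValueError(f"unknown layout {self.layout!r}")
        if 4 ** self.read_len < self.n_unique:
            raise ValueError(
                f"read_len {self.read_len} too short to encode "
                f"{self.n_unique} distinct sequences"
            )


def _encode(i: int, read_len: int) -> str:
    out = []
    for _ in range(read_len):
        out.append(_BASES[i & 3])
        i >>= 2
    return "".join(reversed(out))


def _counts(model: DuplicationModel, rng: np.random.Generator) -> np.ndarray:
    n = model.n_unique
    if model.law == "constant":
        return np.full(n, max(1, int(model.law_param)), dtype=np.int64)
    if model.law == "geometric":
        return rng.geometric(model.law_param, size=n).astype(np.int64)
    return np.minimum(rng.zipf(model.law_param, size=n), _ZIPF_CAP).astype(np.int64)


def _qual_string(model: DuplicationModel, rng: np.random.Generator, n: int) -> str:
    vals = model.qual_mu + rng.integers(
        -model.qual_jitter, model.qual_jitter + 1, size=n
    )
    vals = np.clip(vals, 2, 41)
    return (vals + 33).astype(np.uint8).tobytes().decode("ascii")


def _open_out(path: Path) -> IO[str]:
    if str(path).endswith(".gz"):
        # fixed mtime and no original-name field keep output byte-reproducible
        import io
        return io.TextIOWrapper(
            gzip.GzipFile(filename="", mode="wb", fileobj=open(path, "wb"), mtime=0)
        )
    return open(path, "w")


def generate_sample(
    model: DuplicationModel,
    out_prefix: str | os.PathLike,
    compress: bool = False,
) -> tuple[list[Path], dict[bytes, int]]:
    """Write FASTQ file(s) plus a ground-truth TSV; returns (paths, truth).

    Truth maps each collapse key (sequence, or mate1 + separator + mate2) to
    its emitted copy number; it is also written as ``<prefix>.truth.tsv``
    with tab-separated mates.
    """
    rng = np.random.default_rng(model.seed)
    out_prefix = Path(out_prefix)
    paired = model.layout in ("paired", "interleaved")

    seqs1 = [_encode(i, model.read_len) for i in range(model.n_unique)]
    seqs2 = (
        [_encode(model.n_unique - 1 - i, model.read_len)[::-1]
         for i in range(model.n_unique)]
        if paired else None
    )
    counts = _counts(model, rng)

    truth: dict[bytes, int] = {}
    units: list[int] = []
    for i in range(model.n_unique):
        key = seqs1[i].encode("ascii")
        if paired:
            key += MATE_SEPARATOR + seqs2[i].encode("ascii")
        truth[key] = int(counts[i])
        units.extend([i] * int(counts[i]))
    order = rng.permutation(len(units))

    gz = ".gz" if compress else ""
    if model.layout == "paired":
        paths = [Path(f"{out_prefix}_1.fastq{gz}"), Path(f"{out_prefix}_2.fastq{gz}")]
        outs = [_open_out(p) for p in paths]
    else:
        paths = [Path(f"{out_prefix}.fastq{gz}")]
        outs = [_open_out(paths[0])]

    try:
        for serial, idx in enumerate(order):
            i = units[idx]
            name = f"r{serial}.u{i}"
            q1 = _qual_string(model, rng, model.read_len)
            if not paired:
                outs[0].write(f"@{name}\n{seqs1[i]}\n+\n{q1}\n")
                continue
            q2 = _qual_string(model, rng, model.read_len)
            if model.layout == "paired":
                outs[0].write(f"@{name}/1\n{seqs1[i]}\n+\n{q1}\n")
                outs[1].write(f"@{name}/2\n{seqs2[i]}\n+\n{q2}\n")
            else:  # interleaved: mate1 in even records, mate2 in odd
                outs[0].write(f"@{name}/1\n{seqs1[i]}\n+\n{q1}\n")
                outs[0].write(f"@{name}/2\n{seqs2[i]}\n+\n{q2}\n")
    finally:
        for fh in outs:
            fh.close()

    truth_path = Path(f"{out_prefix}.truth.tsv")
    with open(truth_path, "w") as fh:
        for i in range(model.n_unique):
            if paired:
                fh.write(f"{seqs1[i]}\t{seqs2[i]}\t{int(counts[i])}\n")
            else:
                fh.write(f"{seqs1[i]}\t{int(counts[i])}\n")
    return paths + [truth_path], truth
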