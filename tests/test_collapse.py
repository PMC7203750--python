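"""External sort + merge–collapse engine, drivers and the gain metric."""

import itertools
from collections import Counter

import pytest

from conftest import oracle_collapse, read_tag_lines, write_fastq

from seqcollapse.collapse import (
    CollapseStats,
    MemoryMeter,
    _write_tag,
    collapse_multi,
    collapse_single,
    estimate_chunk_size,
    gain,
    merge_collapse,
    sort_phase,
    tag_footprint,
)
from seqcollapse.core import ChunkPlan, FormatError, ReadRecord, Tag, tag_from_unit
from seqcollapse.seqio import SampleSpec


def _unit_tags(seqs):
    return [tag_from_unit(ReadRecord(f"r{i}", s)) for i, s in enumerate(seqs)]


def _fastq_sample(tmp_path, seqs, name="a.fastq"):
    recs = [(f"r{i}", s, "I" * len(s)) for i, s in enumerate(seqs)]
    return SampleSpec.from_paths([write_fastq(tmp_path / name, recs)])


class TestEstimate:
    def test_probe_footprint_feeds_the_plan(self):
        probe = _unit_tags(["ACGT"] * 10)
        t_ram = sum(tag_footprint(t) for t in probe)
        plan = estimate_chunk_size(probe, c_ram=t_ram, alpha=1.0)
        assert (plan.t_size, plan.t_ram, plan.c_size) == (10, t_ram, 10)

    def test_tight_budget_floors_at_one(self):
        plan = estimate_chunk_size(_unit_tags(["ACGT"]), c_ram=1, alpha=0.5)
        assert plan.c_size == 1


class TestSortPhase:
    def test_seven_reads_in_chunks_of_three_make_three_runs(self, tmp_path):
        plan = ChunkPlan.forced(3)
        runs = sort_phase(_unit_tags(["A"] * 7), plan, tmp_path)
        assert len(runs) == 3 and plan.m == 3
        assert [r.n_tags for r in runs] == [1, 1, 1]  # locally collapsed

    def test_chunk_is_sorted_and_locally_collapsed(self, tmp_path):
        plan = ChunkPlan.forced(3)
        runs = sort_phase(_unit_tags(["TT", "AA", "TT"]), plan, tmp_path)
        tags = list(merge_collapse(runs, plan))
        assert [(t.key, t.count) for t in tags] == [(b"AA", 1), (b"TT", 2)]

    def test_unwritable_tmpdir_fails_before_consuming_input(self, tmp_path):
        consumed = []

        def stream():
            consumed.append(1)
            yield _unit_tags(["A"])[0]

        with pytest.raises(OSError):
            sort_phase(stream(), ChunkPlan.forced(2), tmp_path / "missing" / "dir")
        assert not consumed


class TestMergeCollapse:
    def test_equal_keys_across_runs_are_merged(self, tmp_path):
        plan = ChunkPlan.forced(2)
        runs = sort_phase(_unit_tags(["AA", "AA", "AA", "CC"]), plan, tmp_path)
        assert len(runs) == 2
        tags = list(merge_collapse(runs, plan))
        assert [(t.key, t.count) for t in tags] == [(b"AA", 3), (b"CC", 1)]

    def test_single_run_passes_through(self, tmp_path):
        plan = ChunkPlan.forced(10)
        runs = sort_phase(_unit_tags(["CC", "AA"]), plan, tmp_path)
        assert [(t.key, t.count) for t in merge_collapse(runs, plan)] == \
               [(b"AA", 1), (b"CC", 1)]

    def test_zero_runs_is_an_empty_stream(self):
        assert list(merge_collapse([], ChunkPlan.forced(5))) == []

    def test_unsorted_run_raises_integrity_error(self, tmp_path):
        path = tmp_path / "run00000.bin"
        with open(path, "wb") as fh:
            _write_tag(fh, Tag(b"CC", 1))
            _write_tag(fh, Tag(b"AA", 1))
        from seqcollapse.collapse import RunFile
        runs = [RunFile(path=path, n_tags=2)]
        with pytest.raises(FormatError, match="run00000"):
            list(merge_collapse(runs, ChunkPlan.forced(4)))


class TestCollapseSingle:
    def test_counts_and_lexicographic_order(self, tmp_path):
        spec = _fastq_sample(tmp_path, ["ACGT", "ACGT", "GGGG", "ACGT"])
        stats = collapse_single(spec, tmp_path / "out.tag", chunk_size=2)
        assert read_tag_lines(tmp_path / "out.tag") == [(b"ACGT", 3), (b"GGGG", 1)]
        assert (stats.reads_in, stats.tags_out, stats.runs) == (4, 2, 2)

    def test_all_unique_input_keeps_every_read(self, tmp_path):
        seqs = ["AAAA", "CCCC", "GGGG", "TTTT"]
        spec = _fastq_sample(tmp_path, seqs)
        collapse_single(spec, tmp_path / "out.tag", chunk_size=3)
        assert read_tag_lines(tmp_path / "out.tag") == \
            [(s.encode(), 1) for s in sorted(seqs)]

    def test_n_copies_collapse_to_one_tag_with_own_quality(self, tmp_path):
        spec = _fastq_sample(tmp_path, ["ACGT"] * 6)
        collapse_single(spec, tmp_path / "out.tagq", format="tagq", chunk_size=2)
        assert (tmp_path / "out.tagq").read_text() == "ACGT\t6\tIIII\n"

    def test_empty_input_yields_wellformed_empty_output(self, tmp_path):
        spec = _fastq_sample(tmp_path, [])
        stats = collapse_single(spec, tmp_path / "out.tag")
        assert (tmp_path / "out.tag").read_bytes() == b""
        assert (stats.reads_in, stats.tags_out, stats.runs) == (0, 0, 0)

    def test_fasta_input_cannot_feed_quality_output(self, tmp_path):
        from conftest import write_fasta
        path = write_fasta(tmp_path / "a.fasta", [("r", "ACGT")])
        with pytest.raises(FormatError):
            collapse_single(SampleSpec.from_paths([path]),
                            tmp_path / "out.tagq", format="tagq")

    def test_stats_report_written(self, tmp_path):
        import json
        spec = _fastq_sample(tmp_path, ["AA", "AA"])
        collapse_single(spec, tmp_path / "out.tag", chunk_size=1)
        lines = [json.loads(l) for l in
                 (tmp_path / "out.tag.stats.jsonl").read_text().splitlines()]
        assert lines[0]["event"] == "chunk_plan" and lines[0]["c_size"] == 1
        assert lines[1]["reads_in"] == 2 and lines[1]["tags_out"] == 1

    def test_joined_mates_collapse_like_split_pairs(self, tmp_path):
        spec = SampleSpec.from_paths(
            [write_fastq(tmp_path / "j.fastq",
                         [("r0", "ACGTTTAA", "IIIIIIII"),
                          ("r1", "ACGTTTAA", "IIIIIIII"),
                          ("r2", "ACGTGGGG", "IIIIIIII")])],
            layout="joined", breakpoint=4)
        collapse_single(spec, tmp_path / "out.tag", chunk_size=2)
        assert read_tag_lines(tmp_path / "out.tag") == \
            [(b"ACGT\x01GGGG", 1), (b"ACGT\x01TTAA", 2)]

    def test_output_bytes_identical_across_chunk_sizes_and_threads(self, tmp_path):
        seqs = ["ACGT", "TTTT", "ACGT", "AAAA", "TTTT", "ACGT", "CCCC"]
        outs = []
        for i, (cs, threads) in enumerate([(1, 1), (3, 1), (100, 4), (3, 8)]):
            spec = _fastq_sample(tmp_path, seqs, name=f"in{i}.fastq")
            out = tmp_path / f"out{i}.tagq"
            collapse_single(spec, out, format="tagq", chunk_size=cs,
                            threads=threads)
            outs.append(out.read_bytes())
        assert len(set(outs)) == 1


class TestCollapseMulti:
    def test_occurrence_table_rows_align_with_output(self, tmp_path):
        s1 = _fastq_sample(tmp_path, ["AA", "AA"], name="s1.fastq")
        s2 = _fastq_sample(tmp_path, ["AA", "CC"], name="s2.fastq")
        stats, table = collapse_multi([s1, s2], tmp_path / "ms.tag", chunk_size=2)
        assert read_tag_lines(tmp_path / "ms.tag") == [(b"AA", 3), (b"CC", 1)]
        assert table.samples == ["s1", "s2"]
        assert [(tid.split(".")[1], c.tolist()) for tid, _, c in table.rows] == \
            [("0_3", [2, 1]), ("1_1", [0, 1])]
        assert stats.per_sample_reads == {"s1": 2, "s2": 2}

    def test_identical_samples_get_symmetric_counts(self, tmp_path):
        s1 = _fastq_sample(tmp_path, ["AC", "GT", "AC"], name="t1.fastq")
        s2 = _fastq_sample(tmp_path, ["AC", "GT", "AC"], name="t2.fastq")
        _, table = collapse_multi([s1, s2], tmp_path / "ms.tag", chunk_size=1)
        for _, _, counts in table.rows:
            assert counts[0] == counts[1]

    def test_disjoint_single_read_samples_make_a_permutation_matrix(self, tmp_path):
        specs = [_fastq_sample(tmp_path, [s], name=f"p{i}.fastq")
                 for i, s in enumerate(["GG", "AA", "CC"])]
        _, table = collapse_multi(specs, tmp_path / "ms.tag", chunk_size=1)
        import numpy as np
        mat = np.array([c for _, _, c in table.rows])
        assert mat.sum() == 3 and (mat.sum(axis=0) == 1).all() \
            and (mat.sum(axis=1) == 1).all()

    def test_mixed_layouts_rejected_upfront(self, tmp_path):
        se = _fastq_sample(tmp_path, ["AA"], name="se.fastq")
        pe_path = write_fastq(tmp_path / "pe.fastq",
                              [("r0", "AA", "II"), ("r1", "CC", "II")])
        pe = SampleSpec.from_paths([pe_path], layout="interleaved")
        with pytest.raises(FormatError, match="mix"):
            collapse_multi([se, pe], tmp_path / "ms.tag")

    def test_fewer_than_two_samples_rejected(self, tmp_path):
        s1 = _fastq_sample(tmp_path, ["AA"])
        with pytest.raises(ValueError):
            collapse_multi([s1], tmp_path / "ms.tag")

    def test_duplicate_sample_names_deduplicated(self, tmp_path):
        (tmp_path / "d1").mkdir(); (tmp_path / "d2").mkdir()
        s1 = _fastq_sample(tmp_path / "d1", ["AA"], name="x.fastq")
        s2 = _fastq_sample(tmp_path / "d2", ["CC"], name="x.fastq")
        _, table = collapse_multi([s1, s2], tmp_path / "ms.tag", chunk_size=1)
        assert table.samples == ["x", "x.1"]

    def test_ss_then_aggregate_equals_ms(self, tmp_path):
        samples = [["ACGT", "TTAA", "ACGT"], ["TTAA", "GGGG"],
                   ["ACGT", "GGGG", "GGGG"]]
        specs = [_fastq_sample(tmp_path, seqs, name=f"agg{i}.fastq")
                 for i, seqs in enumerate(samples)]
        agg = Counter()
        for i, spec in enumerate(specs):
            collapse_single(spec, tmp_path / f"ss{i}.tag", chunk_size=2)
            agg.update(dict(read_tag_lines(tmp_path / f"ss{i}.tag")))
        collapse_multi(specs, tmp_path / "ms.tag", chunk_size=2)
        assert dict(read_tag_lines(tmp_path / "ms.tag")) == dict(agg)


class TestOracleEquivalence:
    @pytest.mark.parametrize("c_size", [1, 2, 3, 5, 9, 10])
    def test_matches_in_memory_oracle(self, tmp_path, c_size):
        seqs = ["TT", "AA", "TT", "CG", "AA", "TT", "NN", "aa", "CG"]
        spec = _fastq_sample(tmp_path, seqs, name=f"o{c_size}.fastq")
        collapse_single(spec, tmp_path / f"o{c_size}.tag", chunk_size=c_size)
        expected = oracle_collapse([s.encode() for s in seqs])
        assert read_tag_lines(tmp_path / f"o{c_size}.tag") == expected


class TestMemoryContract:
    def test_sort_and_merge_residency_bounded(self, tmp_path):
        seqs = [f"{a}{b}" for a, b in
                itertools.product("ACGT", repeat=2)] * 3  # 48 reads
        for c_size in (2, 5, 7):
            meter = MemoryMeter()
            spec = _fastq_sample(tmp_path, seqs, name=f"m{c_size}.fastq")
            collapse_single(spec, tmp_path / f"m{c_size}.tag",
                            chunk_size=c_size, meter=meter)
            m = -(-len(seqs) // c_size)
            assert meter.max_sort_units <= c_size
            assert meter.max_merge_tags <= max(c_size, m)


class TestGain:
    def test_identity_has_zero_gain(self):
        assert gain(7.0, 7.0) == 0.0

    def test_negative_gain_reported_as_is(self):
        assert gain(100, 150) == -50.0

    def test_zero_raw_rejected(self):
        with pytest.raises(ValueError):
            gain(0, 5)
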