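"""The map-shuffle-reduce executor: grouping, sortedness, determinism."""

from __future__ import annotations

import random

import pytest

from pepsearch.mapreduce import (
    JobError,
    JobSpec,
    KeyValue,
    Runner,
    default_partitioner,
    identity_mapper,
)
from oracles import group_reduce


def summing_reducer(key, values):
    return [KeyValue(key, sum(values))]


def word_split_mapper(record):
    return [KeyValue(word, 1) for word in record.split()]


def first_value_reducer(key, values):
    return [KeyValue(key, values[0])]


def probe_reducer(key, values):
    # emits the key so the caller can reconstruct each reducer's key stream
    return [KeyValue(key, list(values))]


def failing_mapper(record):
    if record == "bad":
        raise ValueError("boom")
    return [KeyValue(record, 1)]


def failing_kv_mapper(record):
    key, value = record
    if key == "bad":
        raise ValueError("boom")
    return [KeyValue(key, value)]


def test_identity_sum_grouping():
    spec = JobSpec(mapper=identity_mapper, reducer=summing_reducer)
    out = Runner().run_job(spec, [("a", 1), ("b", 2), ("a", 3)])
    assert set(out) == {("a", 4), ("b", 2)}


def test_empty_input_gives_empty_output():
    spec = JobSpec(mapper=identity_mapper, reducer=summing_reducer)
    assert Runner().run_job(spec, []) == []


@pytest.mark.parametrize("n_reducers", [1, 4])
@pytest.mark.parametrize("backend", ["serial", "multiprocess"])
def test_random_pairs_match_dict_oracle(backend, n_reducers):
    """1000 random pairs: output multiset identical across backends and
    reducer counts, and equal to a dictionary group-and-reduce oracle."""
    rng = random.Random(7)
    pairs = [(f"k{rng.randrange(50)}", rng.randrange(1000)) for _ in range(1000)]
    spec = JobSpec(mapper=identity_mapper, reducer=summing_reducer, n_reducers=n_reducers)
    out = Runner(backend=backend).run_job(spec, pairs)
    assert sorted(out) == sorted(group_reduce(pairs, summing_reducer))


def test_output_identical_across_backends_and_reducer_counts():
    rng = random.Random(11)
    pairs = [(f"k{rng.randrange(30)}", rng.randrange(100)) for _ in range(500)]
    results = []
    for backend in ("serial", "multiprocess"):
        for n in (1, 4):
            spec = JobSpec(mapper=identity_mapper, reducer=summing_reducer, n_reducers=n)
            results.append(Runner(backend=backend).run_job(spec, pairs))
    assert all(r == results[0] for r in results[1:])


def test_sortedness_within_each_reducer_stream():
    """A probe records key arrival order; every stream must be ascending,
    and every key must appear in exactly one stream with all its values."""
    rng = random.Random(3)
    pairs = [(f"key{rng.randrange(40):02d}", rng.random()) for _ in range(400)]
    n = 4
    spec = JobSpec(mapper=identity_mapper, reducer=probe_reducer, n_reducers=n)
    out = Runner().run_job(spec, pairs)
    streams: dict[int, list] = {i: [] for i in range(n)}
    for key, values in out:
        streams[default_partitioner(key, n)].append((key, values))
    seen_keys = []
    for idx, stream in streams.items():
        keys = [k for k, _ in stream]
        assert keys == sorted(keys), f"reducer {idx} saw keys out of order"
        seen_keys.extend(keys)
    # complete grouping: each key exactly once overall, with all its values
    assert sorted(seen_keys) == sorted({k for k, _ in pairs})
    expected = {}
    for k, v in pairs:
        expected.setdefault(k, []).append(v)
    got = {k: v for k, v in out}
    assert {k: sorted(v) for k, v in got.items()} == {
        k: sorted(v) for k, v in expected.items()
    }


def test_partition_stability():
    for key in ["a", "b", ("x", 3), 17, b"raw"]:
        assert default_partitioner(key, 4) == default_partitioner(key, 4)
        assert 0 <= default_partitioner(key, 4) < 4


def test_non_orderable_key_rejected_at_emit():
    spec = JobSpec(mapper=lambda r: [KeyValue({"k": 1}, r)], reducer=first_value_reducer)
    with pytest.raises(JobError, match="non-orderable"):
        Runner().run_job(spec, [1])


def test_mapper_failure_identifies_record():
    spec = JobSpec(mapper=failing_mapper, reducer=summing_reducer)
    with pytest.raises(JobError, match=r"record #1.*'bad'"):
        Runner().run_job(spec, ["ok", "bad"])


def test_chain_of_identities_equals_single_job():
    pairs = [("a", 1), ("b", 2), ("a", 3)]
    runner = Runner()
    chained = runner.chain_jobs(
        [
            JobSpec(mapper=identity_mapper, reducer=probe_reducer_flatten),
            JobSpec(mapper=identity_mapper, reducer=probe_reducer_flatten),
        ],
        pairs,
    )
    single = runner.run_job(
        JobSpec(mapper=identity_mapper, reducer=probe_reducer_flatten), pairs
    )
    assert chained == single


def probe_reducer_flatten(key, values):
    return [KeyValue(key, v) for v in values]


def test_chain_word_count():
    spec1 = JobSpec(mapper=word_split_mapper, reducer=probe_reducer_flatten)
    spec2 = JobSpec(mapper=identity_mapper, reducer=summing_reducer)
    out = Runner().chain_jobs([spec1, spec2], ["a b a"])
    assert set(out) == {("a", 2), ("b", 1)}


def test_random_chain_matches_sequential_oracle():
    rng = random.Random(19)
    pairs = [(f"k{rng.randrange(12)}", rng.randrange(9)) for _ in range(200)]
    specs = [
        JobSpec(mapper=identity_mapper, reducer=summing_reducer, n_reducers=3),
        JobSpec(mapper=identity_mapper, reducer=probe_reducer_flatten, n_reducers=2),
        JobSpec(mapper=identity_mapper, reducer=summing_reducer, n_reducers=4),
    ]
    out = Runner().chain_jobs(specs, pairs)
    expected = pairs
    for reducer in (summing_reducer, probe_reducer_flatten, summing_reducer):
        expected = group_reduce(expected, reducer)
    assert sorted(out) == sorted((k, v) for k, v in expected)


def test_chain_failure_reports_stage():
    specs = [
        JobSpec(mapper=identity_mapper, reducer=first_value_reducer),
        JobSpec(mapper=failing_kv_mapper, reducer=summing_reducer),
    ]
    with pytest.raises(JobError, match="stage 1"):
        Runner().chain_jobs(specs, [("bad", 1)])


def test_spill_to_disk_preserves_results(tmp_path):
    rng = random.Random(23)
    pairs = [(f"k{rng.randrange(20)}", rng.randrange(50)) for _ in range(300)]
    spec = JobSpec(mapper=identity_mapper, reducer=summing_reducer, n_reducers=2)
    spilled = Runner(spill_threshold=10, temp_dir=str(tmp_path)).run_job(spec, pairs)
    in_memory = Runner().run_job(spec, pairs)
    assert spilled == in_memory
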