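"""A minimal, generic map-shuffle-reduce executor.

Two contracts the search algorithm depends on are honored exactly:

1. **Grouping** — all values emitted under one key are delivered to exactly
   one reducer invocation, on the reducer index chosen by the partitioner.
2. **Sortedness** — within each reducer's invocation stream, keys arrive in
   ascending order.

Two backends are provided: ``serial`` (in-process) and ``multiprocess``
(a fork-based process pool).  Both funnel through the same shuffle code and
produce byte-identical results; the final output of :meth:`Runner.run_job`
is additionally sorted by key so results are also identical across
``n_reducers`` settings.

There is no speculative execution and no retry: a mapper or reducer
exception aborts the job with the failing record or key identified.
"""

from __future__ import annotations

import base64
import logging
import multiprocessing
import os
import pickle
import tempfile
from dataclasses import dataclass, field
from typing import Any, Callable, Iterable, NamedTuple, Sequence

log = logging.getLogger(__name__)


class KeyValue(NamedTuple):
    key: Any
    value: Any


class JobError(RuntimeError):
    """A map or reduce task failed; the job is aborted."""


_ORDERABLE_SCALARS = (str, int, float, bytes, bool)


def check_key(key: Any) -> None:
    """Reject keys without a deterministic total order at emit time."""
    if isinstance(key, tuple):
        for part in key:
            check_key(part)
        return
    if not isinstance(key, _ORDERABLE_SCALARS):
        raise JobError(f"non-orderable key of type {type(key).__name__}: {key!r}")


def _key_bytes(key: Any) -> bytes:
    # repr is deterministic for the allowed key types (str/int/float/bytes/
    # bool and tuples thereof) and independent of PYTHONHASHSEED.
    return repr(key).encode()


def default_partitioner(key: Any, n_reducers: int) -> int:
    """Stable hash of the serialized key modulo n_reducers.

    Uses a fixed (non per-process-randomized) hash so partitioning is
    reproducible across runs and processes.
    """
    import hashlib

    digest = hashlib.blake2b(_key_bytes(key), digest_size=8).digest()
    return int.from_bytes(digest, "big") % n_reducers


Mapper = Callable[[Any], Iterable[KeyValue]]
Reducer = Callable[[Any, list[Any]], Iterable[KeyValue]]


@dataclass(frozen=True)
class JobSpec:
    """One MapReduce job: a mapper, a reducer, and the partitioning scheme."""

    mapper: Mapper
    reducer: Reducer
    n_reducers: int = 1
    partitioner: Callable[[Any, int], int] = default_partitioner
    name: str = "job"

    def __post_init__(self) -> None:
        if self.n_reducers < 1:
            raise ValueError("n_reducers must be >= 1")


# ---------------------------------------------------------------------------
# worker helpers (module-level so they pickle for the process pool)

def _map_chunk(args: tuple[Mapper, int, list[Any]]) -> list[list[KeyValue]]:
    mapper, offset, records = args
    out: list[list[KeyValue]] = []
    for i, record in enumerate(records):
        try:
            emitted = list(mapper(record))
        except JobError:
            raise
        except Exception as exc:  # noqa: BLE001 - report the failing record
            raise JobError(
                f"mapper failed on record #{offset + i} ({_describe(record)}): {exc}"
            ) from exc
        for kv in emitted:
            check_key(kv[0])
        out.append([KeyValue(*kv) for kv in emitted])
    return out


def _reduce_partition(args: tuple[Reducer, list[KeyValue]]) -> list[KeyValue]:
    reducer, pairs = args
    pairs.sort(key=lambda kv: kv.key)  # stable: preserves emission order per key
    out: list[KeyValue] = []
    i = 0
    while i < len(pairs):
        key = pairs[i].key
        j = i
        while j < len(pairs) and pairs[j].key == key:
            j += 1
        values = [kv.value for kv in pairs[i:j]]
        try:
            emitted = list(reducer(key, values))
        except JobError:
            raise
        except Exception as exc:  # noqa: BLE001
            raise JobError(f"reducer failed on key {key!r}: {exc}") from exc
        for kv in emitted:
            check_key(kv[0])
        out.extend(KeyValue(*kv) for kv in emitted)
        i = j
    return out


def _describe(record: Any) -> str:
    text = repr(record)
    return text if len(text) <= 120 else text[:117] + "..."


# ---------------------------------------------------------------------------

@dataclass
class Runner:
    """Executes JobSpecs on the chosen backend.

    ``spill_threshold``: when the shuffle holds more than this many
    intermediate pairs, each partition is spilled to a line-delimited temp
    file (one base64-pickled pair per line) and re-read at reduce time.
    """

    backend: str = "serial"
    n_workers: int = 2
    spill_threshold: int = 200_000
    temp_dir: str | None = None

    def __post_init__(self) -> None:
        if self.backend not in ("serial", "multiprocess"):
            raise ValueError(f"backend must be serial|multiprocess, got {self.backend!r}")

    # -- phases -------------------------------------------------------------

    def _map_phase(self, spec: JobSpec, inputs: Sequence[Any]) -> list[KeyValue]:
        records = list(inputs)
        if not records:
            return []
        if self.backend == "multiprocess" and len(records) > 1:
            chunk = max(1, (len(records) + self.n_workers - 1) // self.n_workers)
            tasks = [
                (spec.mapper, off, records[off : off + chunk])
                for off in range(0, len(records), chunk)
            ]
            with multiprocessing.get_context("fork").Pool(self.n_workers) as pool:
                chunks = pool.map(_map_chunk, tasks)
            per_record = [emitted for c in chunks for emitted in c]
        else:
            per_record = _map_chunk((spec.mapper, 0, records))
        return [kv for emitted in per_record for kv in emitted]

    def _shuffle(self, spec: JobSpec, pairs: list[KeyValue]) -> list[list[KeyValue]]:
        partitions: list[list[KeyValue]] = [[] for _ in range(spec.n_reducers)]
        for kv in pairs:
            partitions[spec.partitioner(kv.key, spec.n_reducers)].append(kv)
        if len(pairs) > self.spill_threshold:
            partitions = [self._spill_and_reload(p) for p in partitions]
        return partitions

    def _spill_and_reload(self, partition: list[KeyValue]) -> list[KeyValue]:
        fd, path = tempfile.mkstemp(suffix=".shuffle", dir=self.temp_dir)
        try:
            with os.fdopen(fd, "wb") as fh:
                for kv in partition:
                    fh.write(base64.b64encode(pickle.dumps(tuple(kv), protocol=4)))
                    fh.write(b"\n")
            reloaded: list[KeyValue] = []
            with open(path, "rb") as fh:
                for line in fh:
                    key, value = pickle.loads(base64.b64decode(line.rstrip(b"\n")))
                    reloaded.append(KeyValue(key, value))
            return reloaded
        finally:
            os.unlink(path)

    def _reduce_phase(self, spec: JobSpec, partitions: list[list[KeyValue]]) -> list[KeyValue]:
        tasks = [(spec.reducer, p) for p in partitions]
        if self.backend == "multiprocess" and len(partitions) > 1:
            with multiprocessing.get_context("fork").Pool(
                min(self.n_workers, len(partitions))
            ) as pool:
                outs = pool.map(_reduce_partition, tasks)
        else:
            outs = [_reduce_partition(t) for t in tasks]
        return [kv for out in outs for kv in out]

    # -- public API ----------------------------------------------------------

    def run_job(self, spec: JobSpec, inputs: Sequence[Any]) -> list[KeyValue]:
        """Run one map-shuffle-reduce job.

        Output is the multiset union of all reducer emissions, sorted by key
        (ties broken by the serialized value) so the result is byte-identical
        across backends and across ``n_reducers`` settings.
        """
        mapped = self._map_phase(spec, inputs)
        log.info("%s: %d input records -> %d mapped pairs", spec.name, len(list(inputs)), len(mapped))
        partitions = self._shuffle(spec, mapped)
        reduced = self._reduce_phase(spec, partitions)
        log.info("%s: %d reduced pairs", spec.name, len(reduced))
        reduced.sort(key=lambda kv: (kv.key, pickle.dumps(kv.value, protocol=4)))
        return reduced

    def chain_jobs(self, specs: Sequence[JobSpec], inputs: Sequence[Any]) -> list[KeyValue]:
        """Run jobs in sequence; the output pairs of job *i* are the input
        records of job *i+1*.  Any failure aborts the chain, reporting the
        stage index."""
        if not specs:
            raise ValueError("chain_jobs requires at least one JobSpec")
        data: Sequence[Any] = inputs
        for stage, spec in enumerate(specs):
            try:
                data = self.run_job(spec, data)
            except JobError as exc:
                raise JobError(f"chain aborted at stage {stage} ({spec.name}): {exc}") from exc
        return list(data)


def identity_mapper(record: Any) -> list[KeyValue]:
    """Pass a KeyValue (or 2-tuple) record through unchanged."""
    key, value = record
    return [KeyValue(key, value)]
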