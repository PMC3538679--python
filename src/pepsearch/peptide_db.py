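"""The reusable m/z-binned peptide database.

Built once from a FASTA collection, the database answers a single query:
*given an m/z bin, return every candidate (modified) peptide in it*.  The
build is a two-job map-reduce chain:

* **Job 1** maps each protein to its digested, modification-expanded
  peptides keyed by the canonical modified-sequence string, with the
  protein id as value.  The reducer sees each unique peptide exactly once
  (duplicate keys collapse in the shuffle), unions the source protein ids,
  and re-emits the peptide keyed by its m/z bin.
* **Job 2** stores each bin — split into fixed-size chunks when it exceeds
  ``split_limit``, so no single scoring task holds an unbounded peptide
  list — and records the per-bin counts in a catalog.

The bin coordinate is the singly-protonated (z=1-equivalent) m/z; one
canonical axis serves every precursor charge.  Bin width defaults to 1 Da.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator

from .config import SearchConfig
from .digestion import ProteinRecord, digest, read_fasta
from .mapreduce import JobError, JobSpec, KeyValue, Runner, identity_mapper
from .masses import (
    ModifiedPeptide,
    UnknownResidueError,
    enumerate_mod_states,
    mod_state_key,
    parse_mod_state_key,
    peptide_neutral_mass,
)

log = logging.getLogger(__name__)

FORMAT_VERSION = 1
CATALOG_FILE = "catalog.tsv"
META_FILE = "meta.json"


class DatabaseIntegrityError(RuntimeError):
    """The on-disk store is inconsistent with its catalog."""


def bin_key_for_mass(neutral_mass: float, config: SearchConfig) -> int:
    """Integer bin of a peptide: floor of its z=1-equivalent m/z at bin width."""
    return int((neutral_mass + config.table.proton_mass) / config.bin_width)


# ---------------------------------------------------------------------------
# Job 1: digest + modify + dedupe

@dataclass(frozen=True)
class DigestMapper:
    """protein -> (canonical modified-sequence key, protein id) pairs."""

    config: SearchConfig

    def __call__(self, protein: ProteinRecord) -> list[KeyValue]:
        cfg = self.config
        out: list[KeyValue] = []
        rejected = 0
        for pep_seq, _missed in digest(
            protein, cfg.enzyme, cfg.min_peptide_length, cfg.max_peptide_length
        ):
            try:
                peptide_neutral_mass(pep_seq, (), cfg.table)
            except UnknownResidueError:
                rejected += 1
                continue
            for state in enumerate_mod_states(pep_seq, cfg.modifications):
                out.append(KeyValue(mod_state_key(pep_seq, state), protein.id))
        if rejected:
            log.info(
                "protein %s: dropped %d peptide(s) with nonstandard residues",
                protein.id,
                rejected,
            )
        return out


@dataclass(frozen=True)
class DedupeReducer:
    """Unique peptide key + its protein ids -> (bin key, ModifiedPeptide)."""

    config: SearchConfig

    def __call__(self, key: str, protein_ids: list[str]) -> list[KeyValue]:
        sequence, state = parse_mod_state_key(key)
        peptide = ModifiedPeptide.create(
            sequence, state, protein_ids, table=self.config.table
        )
        return [KeyValue(bin_key_for_mass(peptide.neutral_mass, self.config), peptide)]


# ---------------------------------------------------------------------------
# Job 2: persist bins

def _split_path(db_dir: Path, bin_key: int, split: int) -> Path:
    return db_dir / f"bin_{bin_key:08d}_{split:04d}.json"


@dataclass(frozen=True)
class StoreReducer:
    """Persist one bin (possibly as several splits) and emit its count."""

    db_dir: str
    split_limit: int

    def __call__(self, bin_key: int, peptides: list[ModifiedPeptide]) -> list[KeyValue]:
        ordered = sorted(peptides, key=lambda p: p.key)
        n_splits = max(1, math.ceil(len(ordered) / self.split_limit))
        try:
            for split in range(n_splits):
                chunk = ordered[split * self.split_limit : (split + 1) * self.split_limit]
                payload = {
                    "bin": bin_key,
                    "split": split,
                    "peptides": [p.to_json_obj() for p in chunk],
                }
                path = _split_path(Path(self.db_dir), bin_key, split)
                with open(path, "w") as fh:
                    json.dump(payload, fh, sort_keys=True, separators=(",", ":"))
        except OSError as exc:
            raise JobError(f"failed to store bin {bin_key}: {exc}") from exc
        return [KeyValue(bin_key, (len(ordered), n_splits))]


# ---------------------------------------------------------------------------

def build_database(
    fasta_path: str | Path,
    config: SearchConfig,
    out_dir: str | Path,
    runner: Runner | None = None,
) -> "PeptideDatabase":
    """Run the two-job build chain and persist the database to ``out_dir``.

    Rebuilding from the same FASTA + config yields byte-identical files.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for stale in out.glob("bin_*.json"):
        stale.unlink()
    runner = runner or Runner(
        backend=config.backend, spill_threshold=config.spill_threshold
    )
    proteins = list(read_fasta(fasta_path))

    job1 = JobSpec(
        mapper=DigestMapper(config),
        reducer=DedupeReducer(config),
        n_reducers=config.n_reducers,
        name="digest-dedupe",
    )
    job2 = JobSpec(
        mapper=identity_mapper,
        reducer=StoreReducer(str(out), config.split_limit),
        n_reducers=config.n_reducers,
        name="bin-store",
    )
    counts = runner.chain_jobs([job1, job2], proteins)

    catalog = sorted((kv.key, kv.value[0], kv.value[1]) for kv in counts)
    with open(out / CATALOG_FILE, "w") as fh:
        for bin_key, count, n_splits in catalog:
            fh.write(f"{bin_key}\t{count}\t{n_splits}\n")
    meta = {
        "format_version": FORMAT_VERSION,
        "config_hash": config.db_config_hash(),
        "bin_width": config.bin_width,
        "split_limit": config.split_limit,
        "n_proteins": len(proteins),
        "n_peptides": sum(c for _, c, _ in catalog),
    }
    with open(out / META_FILE, "w") as fh:
        json.dump(meta, fh, sort_keys=True, indent=1)
        fh.write("\n")
    log.info(
        "built database: %d proteins -> %d unique modified peptides in %d bins",
        len(proteins),
        meta["n_peptides"],
        len(catalog),
    )
    return PeptideDatabase(out)


class PeptideDatabase:
    """Read-only handle on a built database directory."""

    def __init__(self, db_dir: str | Path):
        self.db_dir = Path(db_dir)
        with open(self.db_dir / META_FILE) as fh:
            self.meta = json.load(fh)
        self.catalog: dict[int, tuple[int, int]] = {}
        with open(self.db_dir / CATALOG_FILE) as fh:
            for line in fh:
                bin_key, count, n_splits = line.split("\t")
                self.catalog[int(bin_key)] = (int(count), int(n_splits))

    @property
    def config_hash(self) -> str:
        return self.meta["config_hash"]

    @property
    def bin_width(self) -> float:
        return float(self.meta["bin_width"])

    @property
    def total_peptides(self) -> int:
        return sum(count for count, _ in self.catalog.values())

    def n_splits(self, bin_key: int) -> int:
        entry = self.catalog.get(bin_key)
        return entry[1] if entry else 0

    def read_split(self, bin_key: int, split: int) -> list[ModifiedPeptide]:
        path = _split_path(self.db_dir, bin_key, split)
        try:
            with open(path) as fh:
                payload = json.load(fh)
        except FileNotFoundError:
            raise DatabaseIntegrityError(
                f"catalog lists bin {bin_key} split {split} but {path.name} is missing"
            ) from None
        except json.JSONDecodeError as exc:
            raise DatabaseIntegrityError(f"corrupted split file {path.name}: {exc}") from exc
        if payload.get("bin") != bin_key or payload.get("split") != split:
            raise DatabaseIntegrityError(f"split file {path.name} header mismatch")
        return [ModifiedPeptide.from_json_obj(obj) for obj in payload["peptides"]]

    def query_bin(self, bin_key: int) -> list[ModifiedPeptide]:
        """All peptides of a bin, splits concatenated in stored order.

        A missing key returns an empty list; a file/catalog mismatch raises
        :class:`DatabaseIntegrityError`.
        """
        entry = self.catalog.get(bin_key)
        if entry is None:
            return []
        count, n_splits = entry
        peptides: list[ModifiedPeptide] = []
        for split in range(n_splits):
            peptides.extend(self.read_split(bin_key, split))
        if len(peptides) != count:
            raise DatabaseIntegrityError(
                f"bin {bin_key}: catalog says {count} peptides, store holds {len(peptides)}"
            )
        return peptides

    def iter_peptides(self) -> Iterator[ModifiedPeptide]:
        for bin_key in sorted(self.catalog):
            yield from self.query_bin(bin_key)

    def dump_catalog_tsv(self) -> str:
        """Catalog as TSV text: bin_key <TAB> count."""
        lines = [f"{k}\t{v[0]}" for k, v in sorted(self.catalog.items())]
        return "\n".join(lines) + "\n"
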