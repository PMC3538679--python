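"""The three-job search pipeline.

* **Job 1** routes each (charge-resolved, preprocessed) spectrum to every
  database bin split overlapping its precursor tolerance window and scores
  it there against the split's peptides — the bin is a coarse filter, the
  precursor tolerance check is exact.  Partial per-scan results leave the
  reducer keyed by scan id, serialized as XML fragments.
* **Job 2** combines all partial results of one scan (across bins, splits
  and unknown-charge copies) into a single ranked, truncated list.
* **Job 3** runs on a single reducer, so the consolidated X!Tandem-style
  document is written once, with scans in ascending (natural) scan-id
  order for free thanks to the sorted-key guarantee.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from .config import SearchConfig
from .mapreduce import JobSpec, KeyValue, Runner, identity_mapper
from .masses import mz1_equivalent
from .peptide_db import PeptideDatabase
from .scoring import ProcessedSpectrum, generate_theoretical, kscore, preprocess
from .spectra import MeasuredSpectrum, expand_unknown_charge, read_mgf
from .xml_io import (
    ScanResult,
    ScoredMatch,
    merge_partials,
    partial_from_xml,
    partial_to_xml,
    rank_matches,
    scan_group_element,
    write_results,
)
from lxml import etree

log = logging.getLogger(__name__)


class ConfigMismatchError(RuntimeError):
    """The database was built under a different enzyme/mods configuration."""


def natural_scan_key(scan_id: str) -> tuple:
    """Natural-number-aware, totally ordered sort key for scan ids.

    Digit runs compare numerically, text runs lexically; the tag element
    keeps tuple comparison well-typed across mixed chunks.
    """
    parts = []
    for chunk in re.split(r"(\d+)", scan_id):
        if not chunk:
            continue
        if chunk.isdigit():
            parts.append((0, int(chunk), ""))
        else:
            parts.append((1, 0, chunk))
    return tuple(parts)


def assign_bins(m1: float, precursor_tolerance: float, bin_width: float) -> list[int]:
    """Keys of every bin overlapping [m1 - tol, m1 + tol] on the z=1 axis."""
    lo = int((m1 - precursor_tolerance) / bin_width)
    hi = int((m1 + precursor_tolerance) / bin_width)
    return list(range(lo, hi + 1))


def tolerance_da(config: SearchConfig, m1: float) -> float:
    """Precursor tolerance in Da at the given z=1-equivalent m/z."""
    if config.precursor_tolerance_unit == "ppm":
        return m1 * config.precursor_tolerance * 1e-6
    return config.precursor_tolerance


@dataclass(frozen=True)
class RoutedSpectrum:
    """A spectrum copy prepared for scoring: preprocessed once in the mapper."""

    scan_id: str         # parent scan id (charge suffix stripped)
    copy_id: str
    charge: int
    m1: float            # measured z=1-equivalent precursor m/z
    processed: ProcessedSpectrum


# ---------------------------------------------------------------------------
# Job 1: route + score

@dataclass(frozen=True)
class RouteMapper:
    """spectrum -> ((bin_key, split), RoutedSpectrum) for each overlapping split."""

    config: SearchConfig
    catalog: dict  # bin_key -> (count, n_splits)

    def __call__(self, spectrum: MeasuredSpectrum) -> list[KeyValue]:
        cfg = self.config
        m1 = mz1_equivalent(spectrum.precursor_mz, spectrum.charge, cfg.table)
        routed = RoutedSpectrum(
            scan_id=spectrum.parent_scan_id,
            copy_id=spectrum.scan_id,
            charge=spectrum.charge,
            m1=m1,
            processed=preprocess(spectrum.peaks, spectrum.precursor_mz, cfg.scoring),
        )
        out = []
        for bin_key in assign_bins(m1, tolerance_da(cfg, m1), cfg.bin_width):
            entry = self.catalog.get(bin_key)
            if entry is None:
                continue
            for split in range(entry[1]):
                out.append(KeyValue((bin_key, split), routed))
        return out


@dataclass(frozen=True)
class BinScoreReducer:
    """Score every routed spectrum against one bin split.

    Emits (natural scan key, partial-result XML) pairs; the scan id itself
    rides inside the fragment.
    """

    config: SearchConfig
    db_dir: str

    def __call__(self, key: tuple[int, int], routed: list[RoutedSpectrum]) -> list[KeyValue]:
        bin_key, split = key
        db = PeptideDatabase(self.db_dir)
        peptides = db.read_split(bin_key, split)
        out = []
        for spec in routed:
            tol = tolerance_da(self.config, spec.m1)
            candidates = [p for p in peptides if abs(p.mz1(self.config.table) - spec.m1) <= tol]
            matches = []
            scores = []
            for peptide in candidates:
                theoreticals = [generate_theoretical(peptide, 1, self.config.table)]
                if spec.charge >= self.config.scoring.double_fragment_min_precursor_z:
                    theoreticals.append(generate_theoretical(peptide, 2, self.config.table))
                score = 0.0
                matched = 0
                total_ions = 0
                for theo in theoreticals:
                    s, m, stats = kscore(spec.processed, theo, params=self.config.scoring)
                    score += s
                    matched += m
                    total_ions += stats["total_ions"]
                scores.append(score)
                matches.append(
                    ScoredMatch(
                        peptide=peptide,
                        score=score,
                        matched_count=matched,
                        total_ions=total_ions,
                        charge=spec.charge,
                        measured_mz1=spec.m1,
                    )
                )
            partial = ScanResult(
                scan_id=spec.scan_id,
                matches=rank_matches(matches, self.config.top_k),
                candidates_scored=len(candidates),
                scores=tuple(sorted(scores)),
            )
            out.append(KeyValue(natural_scan_key(spec.scan_id), partial_to_xml(partial)))
        return out


# ---------------------------------------------------------------------------
# Job 2: combine per scan

@dataclass(frozen=True)
class CombineReducer:
    config: SearchConfig

    def __call__(self, key: tuple, partial_xmls: list[str]) -> list[KeyValue]:
        merged = merge_partials(
            (partial_from_xml(x) for x in partial_xmls), self.config.top_k
        )
        return [KeyValue(key, partial_to_xml(merged))]


# ---------------------------------------------------------------------------
# Job 3: consolidate (single reducer)

@dataclass(frozen=True)
class ConsolidateReducer:
    def __call__(self, key: tuple, scan_xmls: list[str]) -> list[KeyValue]:
        out = []
        for x in scan_xmls:
            result = partial_from_xml(x)
            fragment = etree.tostring(scan_group_element(result), encoding="unicode")
            out.append(KeyValue(key, fragment))
        return out


# ---------------------------------------------------------------------------

def run_search(
    db_dir: str | Path,
    spectra_path: str | Path,
    config: SearchConfig,
    out_path: str | Path,
    runner: Runner | None = None,
) -> Path:
    """Execute the three-job chain and write the consolidated output file."""
    db = PeptideDatabase(db_dir)
    if db.config_hash != config.db_config_hash():
        raise ConfigMismatchError(
            f"database {db_dir} was built with config hash {db.config_hash}, "
            f"search config hashes to {config.db_config_hash()}; rebuild the "
            "database or align enzyme/modification/length/bin settings"
        )
    spectra: list[MeasuredSpectrum] = []
    for s in read_mgf(spectra_path, min_peaks=config.min_peaks):
        spectra.extend(expand_unknown_charge(s, config.charges))
    results = search_spectra(db, spectra, config, runner)
    label = f"models from '{Path(spectra_path).name}'"
    write_results(out_path, (kv.value for kv in results), label)
    log.info("search complete: %d scan group(s) written to %s", len(results), out_path)
    return Path(out_path)


def search_spectra(
    db: PeptideDatabase,
    spectra: Sequence[MeasuredSpectrum],
    config: SearchConfig,
    runner: Runner | None = None,
) -> list[KeyValue]:
    """The three-job chain on already-loaded spectra; returns the final
    (natural scan key, group XML fragment) pairs in ascending scan order."""
    runner = runner or Runner(
        backend=config.backend, spill_threshold=config.spill_threshold
    )
    job1 = JobSpec(
        mapper=RouteMapper(config, db.catalog),
        reducer=BinScoreReducer(config, str(db.db_dir)),
        n_reducers=config.n_reducers,
        name="bin-score",
    )
    job2 = JobSpec(
        mapper=identity_mapper,
        reducer=CombineReducer(config),
        n_reducers=config.n_reducers,
        name="combine-scan",
    )
    job3 = JobSpec(
        mapper=identity_mapper,
        reducer=ConsolidateReducer(),
        n_reducers=1,  # a single reducer so all output lands in one file
        name="consolidate",
    )
    return runner.chain_jobs([job1, job2, job3], list(spectra))


def collect_scan_results(final_pairs: Iterable[KeyValue]) -> list[ScanResult]:
    """Convenience: parse the final group fragments back to ScanResults."""
    from .xml_io import read_results
    import tempfile, os

    fd, path = tempfile.mkstemp(suffix=".xml")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write('<?xml version="1.0" encoding="UTF-8"?>\n<bioml label="tmp">\n')
            for kv in final_pairs:
                fh.write(kv.value)
                fh.write("\n")
            fh.write("</bioml>\n")
        return read_results(path)
    finally:
        os.unlink(path)
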