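"""Reading and writing measured MS/MS spectra (MGF primary, mzML optional).

Whatever the source format, spectra are validated into the same
:class:`MeasuredSpectrum` contract: peaks sorted ascending by m/z,
non-positive intensities dropped, and a minimum peak count enforced.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence

from pyteomics import mgf as _mgf

log = logging.getLogger(__name__)

#: separator used when an unknown-charge scan is expanded into per-charge copies
CHARGE_SUFFIX = "#z"


@dataclass(frozen=True)
class MeasuredSpectrum:
    """One MS/MS scan: precursor m/z + charge, sorted peak list, scan id."""

    scan_id: str
    precursor_mz: float
    charge: int | None
    peaks: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        if self.precursor_mz <= 0:
            raise ValueError(f"precursor m/z must be positive, got {self.precursor_mz}")

    @property
    def parent_scan_id(self) -> str:
        """Scan id with any charge-expansion suffix removed."""
        return re.sub(rf"{CHARGE_SUFFIX}\d+$", "", self.scan_id)


def _clean_peaks(mzs: Sequence[float], intensities: Sequence[float]) -> tuple[tuple[float, float], ...]:
    peaks = [(float(m), float(i)) for m, i in zip(mzs, intensities) if i > 0]
    peaks.sort()
    return tuple(peaks)


def read_mgf(
    path: str | Path,
    min_peaks: int = 5,
    strict: bool = False,
) -> Iterator[MeasuredSpectrum]:
    """Stream spectra from an MGF file, one record at a time.

    PEPMASS is interpreted as the precursor m/z (first numeric token; a
    second intensity token is ignored).  The scan id is TITLE, falling back
    to a running index.  Malformed or too-sparse blocks are skipped with a
    logged warning (``strict=True`` aborts instead).
    """
    skipped = 0
    with _mgf.MGF(str(path)) as reader:
        for index, entry in enumerate(reader):
            try:
                spectrum = _spectrum_from_mgf_entry(entry, index, min_peaks)
            except Exception as exc:  # noqa: BLE001 - malformed block policy
                if strict:
                    raise ValueError(f"malformed MGF block #{index}: {exc}") from exc
                skipped += 1
                log.warning("skipping MGF block #%d: %s", index, exc)
                continue
            if spectrum is None:
                skipped += 1
                continue
            yield spectrum
    if skipped:
        log.info("read_mgf: skipped %d block(s)", skipped)


def _spectrum_from_mgf_entry(entry: dict, index: int, min_peaks: int) -> MeasuredSpectrum | None:
    params = entry.get("params", {})
    title = str(params.get("title", "")).strip() or f"index={index}"
    pepmass = params.get("pepmass")
    if pepmass is None:
        raise ValueError("missing PEPMASS")
    precursor_mz = float(pepmass[0] if isinstance(pepmass, (tuple, list)) else pepmass)
    charge = None
    if "charge" in params:
        raw = params["charge"]
        first = raw[0] if isinstance(raw, (tuple, list)) else raw
        charge = int(first)
    peaks = _clean_peaks(entry.get("m/z array", ()), entry.get("intensity array", ()))
    if len(peaks) < min_peaks:
        log.warning("skipping %s: only %d peak(s) after filtering", title, len(peaks))
        return None
    return MeasuredSpectrum(scan_id=title, precursor_mz=precursor_mz, charge=charge, peaks=peaks)


def read_mzml(path: str | Path, min_peaks: int = 5) -> Iterator[MeasuredSpectrum]:
    """Read MS2 spectra from mzML (optional path; delegates parsing to pyteomics)."""
    from pyteomics import mzml as _mzml

    with _mzml.MzML(str(path)) as reader:
        for entry in reader:
            if entry.get("ms level") != 2:
                continue
            try:
                precursor = entry["precursorList"]["precursor"][0]
                ion = precursor["selectedIonList"]["selectedIon"][0]
                mz = float(ion["selected ion m/z"])
                charge = int(ion["charge state"]) if "charge state" in ion else None
            except (KeyError, IndexError) as exc:
                log.warning("skipping mzML spectrum without precursor info: %s", exc)
                continue
            peaks = _clean_peaks(entry.get("m/z array", ()), entry.get("intensity array", ()))
            if len(peaks) < min_peaks:
                continue
            yield MeasuredSpectrum(
                scan_id=str(entry.get("id", entry.get("index", ""))),
                precursor_mz=mz,
                charge=charge,
                peaks=peaks,
            )


def expand_unknown_charge(
    spectrum: MeasuredSpectrum, charge_range: Sequence[int] = (2, 3)
) -> list[MeasuredSpectrum]:
    """Give unknown-charge scans one concrete copy per candidate charge.

    Copies get a deterministic ``#z<charge>`` suffix; the per-scan combine
    step merges them back under the parent scan id, keeping the best PSMs
    across charges.
    """
    if spectrum.charge is not None:
        return [spectrum]
    if not charge_range:
        raise ValueError("charge_range must be non-empty for unknown-charge spectra")
    return [
        replace(spectrum, scan_id=f"{spectrum.scan_id}{CHARGE_SUFFIX}{z}", charge=int(z))
        for z in charge_range
    ]


def write_mgf(spectra: Iterable[MeasuredSpectrum], path: str | Path) -> None:
    """Write spectra as MGF with deterministic formatting (repr floats)."""
    with open(path, "w") as fh:
        for s in spectra:
            fh.write("BEGIN IONS\n")
            fh.write(f"TITLE={s.scan_id}\n")
            fh.write(f"PEPMASS={s.precursor_mz!r}\n")
            if s.charge is not None:
                fh.write(f"CHARGE={s.charge}+\n")
            for mz, intensity in s.peaks:
                fh.write(f"{mz!r} {intensity!r}\n")
            fh.write("END IONS\n")
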