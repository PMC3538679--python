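"""Deterministic synthetic data: FASTA protein sets and MGF spectra with
known ground truth, so the whole engine is testable without any download.

Proteins are uniform-random sequences with the K/R frequency boosted so
tryptic peptides of length 6–20 are common.  Spectra place peaks at every
singly-charged b/y fragment position of a chosen database peptide, with
intensities from a simple uniform model, plus optional random noise peaks.
Noise peaks avoid ±fragment_tolerance of the true fragment positions, so
noise-free (and non-colliding-noise) recovery is a clean assertion; an
adversarial mode permits collisions.
"""

from __future__ import annotations

import csv
import math
import random
from dataclasses import dataclass
from pathlib import Path

from .config import SearchConfig
from .digestion import ProteinRecord, digest
from .masses import ModifiedPeptide, enumerate_mod_states, precursor_mz
from .scoring import generate_theoretical
from .spectra import MeasuredSpectrum, write_mgf

#: sampling weights; K and R are boosted above the uniform 1/20 so tryptic
#: peptides land mostly in the 6–20 residue range
_AA = "ACDEFGHIKLMNPQRSTVWY"
_WEIGHTS = [3.0 if aa in "KR" else 1.0 for aa in _AA]


@dataclass(frozen=True)
class GroundTruthEntry:
    scan_id: str
    peptide_key: str
    protein_ids: tuple[str, ...]
    charge: int
    n_noise: int


@dataclass(frozen=True)
class Fixture:
    fasta_path: Path
    mgf_path: Path
    truth_path: Path
    proteins: tuple[ProteinRecord, ...]
    truth: dict[str, GroundTruthEntry]


def make_fasta(
    out_path: str | Path,
    n_proteins: int = 20,
    length_range: tuple[int, int] = (200, 400),
    seed: int = 1,
) -> list[ProteinRecord]:
    """Write a synthetic FASTA file; deterministic for a fixed seed."""
    if n_proteins < 1:
        raise ValueError("n_proteins must be >= 1")
    rng = random.Random(seed)
    records = []
    for i in range(n_proteins):
        length = rng.randint(*length_range)
        seq = "".join(rng.choices(_AA, weights=_WEIGHTS, k=length))
        records.append(
            ProteinRecord(id=f"SYN{i + 1:04d}", description="synthetic protein", sequence=seq)
        )
    with open(out_path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id} {rec.description}\n")
            for off in range(0, len(rec.sequence), 60):
                fh.write(rec.sequence[off : off + 60] + "\n")
    return records


def unique_peptides(proteins: list[ProteinRecord], config: SearchConfig) -> list[ModifiedPeptide]:
    """Digest + modification-expand all proteins, deduplicated by key."""
    by_key: dict[str, set[str]] = {}
    seqs: dict[str, tuple[str, tuple]] = {}
    for protein in proteins:
        for pep_seq, _missed in digest(
            protein, config.enzyme, config.min_peptide_length, config.max_peptide_length
        ):
            for state in enumerate_mod_states(pep_seq, config.modifications):
                peptide = ModifiedPeptide.create(pep_seq, state, (), table=config.table)
                by_key.setdefault(peptide.key, set()).add(protein.id)
                seqs[peptide.key] = (pep_seq, state)
    out = []
    for key in sorted(by_key):
        seq, state = seqs[key]
        out.append(ModifiedPeptide.create(seq, state, by_key[key], table=config.table))
    return out


def _is_ambiguous(
    peptide: ModifiedPeptide,
    candidates: list[ModifiedPeptide],
    config: SearchConfig,
) -> bool:
    """True when a same-tolerance competitor mimics every fragment of
    ``peptide`` within the fragment tolerance (e.g. an I/L or K/Q variant),
    which would make rank-1 recovery a coin toss."""
    tol = config.precursor_tolerance
    ftol = config.scoring.fragment_tolerance
    own = sorted(mz for _t, _i, mz in generate_theoretical(peptide, 1, config.table).fragment_mzs)
    for other in candidates:
        if other.key == peptide.key:
            continue
        if abs(other.mz1(config.table) - peptide.mz1(config.table)) > tol:
            continue
        frags = sorted(
            mz for _t, _i, mz in generate_theoretical(other, 1, config.table).fragment_mzs
        )
        if all(min(abs(f - o) for o in own) <= ftol for f in frags):
            return True
    return False


def make_spectra(
    peptides: list[ModifiedPeptide],
    out_mgf: str | Path,
    truth_path: str | Path,
    charges: tuple[int, ...] = (1, 2),
    noise_fraction: float = 0.0,
    intensity_range: tuple[float, float] = (40.0, 100.0),
    seed: int = 1,
    config: SearchConfig | None = None,
    allow_collisions: bool = False,
) -> dict[str, GroundTruthEntry]:
    """Synthesize one MS/MS spectrum per peptide, plus a ground-truth TSV.

    Each spectrum has a peak at every singly-charged b/y fragment m/z with a
    uniform random intensity, ``ceil(noise_fraction x n_fragments)`` noise
    peaks in the observed m/z range (avoiding true fragment positions unless
    ``allow_collisions``), and a precursor computed from the mass model.
    Fully deterministic per seed.
    """
    if not peptides:
        raise ValueError("make_spectra requires at least one peptide")
    cfg = config or SearchConfig()
    rng = random.Random(seed)
    ftol = cfg.scoring.fragment_tolerance
    spectra = []
    truth: dict[str, GroundTruthEntry] = {}
    for i, peptide in enumerate(peptides):
        scan_id = f"scan{i + 1:05d}"
        charge = rng.choice(list(charges))
        frag_mzs = [mz for _t, _i, mz in generate_theoretical(peptide, 1, cfg.table).fragment_mzs]
        peaks = [(mz, rng.uniform(*intensity_range)) for mz in frag_mzs]
        n_noise = math.ceil(noise_fraction * len(frag_mzs))
        lo, hi = min(frag_mzs), max(frag_mzs)
        added = 0
        while added < n_noise:
            mz = rng.uniform(lo, hi)
            if not allow_collisions and any(abs(mz - f) <= ftol + 0.05 for f in frag_mzs):
                continue
            peaks.append((mz, rng.uniform(*intensity_range)))
            added += 1
        spectra.append(
            MeasuredSpectrum(
                scan_id=scan_id,
                precursor_mz=precursor_mz(peptide.neutral_mass, charge, cfg.table),
                charge=charge,
                peaks=tuple(sorted(peaks)),
            )
        )
        truth[scan_id] = GroundTruthEntry(
            scan_id=scan_id,
            peptide_key=peptide.key,
            protein_ids=peptide.protein_ids,
            charge=charge,
            n_noise=n_noise,
        )
    write_mgf(spectra, out_mgf)
    with open(truth_path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["scan_id", "peptide_key", "protein_ids", "charge", "n_noise"])
        for scan_id in sorted(truth):
            e = truth[scan_id]
            writer.writerow(
                [e.scan_id, e.peptide_key, ",".join(e.protein_ids), e.charge, e.n_noise]
            )
    return truth


def read_ground_truth(path: str | Path) -> dict[str, GroundTruthEntry]:
    truth = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            truth[row["scan_id"]] = GroundTruthEntry(
                scan_id=row["scan_id"],
                peptide_key=row["peptide_key"],
                protein_ids=tuple(row["protein_ids"].split(",")),
                charge=int(row["charge"]),
                n_noise=int(row["n_noise"]),
            )
    return truth


def generate_fixture(
    out_dir: str | Path,
    seed: int = 1,
    noise_fraction: float = 0.0,
    n_proteins: int = 20,
    n_spectra: int = 50,
    length_range: tuple[int, int] = (200, 400),
    charges: tuple[int, ...] = (1, 2),
    config: SearchConfig | None = None,
) -> Fixture:
    """The standard end-to-end fixture: FASTA + MGF + ground-truth TSV.

    Truth peptides are drawn (deterministically per seed) from the database
    peptides of length 7–25, skipping any with a same-tolerance competitor
    that mimics their full fragment set.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = config or SearchConfig()
    fasta_path = out / "proteins.fasta"
    proteins = make_fasta(fasta_path, n_proteins, length_range, seed)
    candidates = unique_peptides(proteins, cfg)
    pool = [p for p in candidates if 7 <= len(p.sequence) <= 25]
    rng = random.Random(seed + 104729)
    rng.shuffle(pool)
    chosen: list[ModifiedPeptide] = []
    for peptide in pool:
        if len(chosen) == n_spectra:
            break
        if not _is_ambiguous(peptide, candidates, cfg):
            chosen.append(peptide)
    if len(chosen) < n_spectra:
        raise ValueError(
            f"only {len(chosen)} unambiguous peptides available; "
            "increase n_proteins or lower n_spectra"
        )
    chosen.sort(key=lambda p: p.key)
    mgf_path = out / ("spectra.mgf" if noise_fraction == 0 else f"spectra_noise{noise_fraction:g}.mgf")
    truth_path = out / (mgf_path.stem + "_truth.tsv")
    truth = make_spectra(
        chosen,
        mgf_path,
        truth_path,
        charges=charges,
        noise_fraction=noise_fraction,
        seed=seed,
        config=cfg,
    )
    return Fixture(
        fasta_path=fasta_path,
        mgf_path=mgf_path,
        truth_path=truth_path,
        proteins=tuple(proteins),
        truth=truth,
    )
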