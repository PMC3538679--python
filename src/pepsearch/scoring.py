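"""K-score-style spectrum scoring.

The score is a normalized dot product between a preprocessed measured
spectrum and the theoretical b/y fragment positions of a candidate peptide.
Preprocessing (precursor exclusion, square-root intensity compression,
per-window max normalization, fragment binning) makes the score robust to
absolute intensity scale and to dense noise, in the COMET/K-score family
tradition.  The constants are fixed, documented defaults and are all
configurable, so the scoring core is testable independently of their
exact values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable

from .masses import DEFAULT_MASS_TABLE, MassTable, ModifiedPeptide


@dataclass(frozen=True)
class ScoringParams:
    n_windows: int = 10
    window_cap: float = 50.0
    fragment_bin_width: float = 1.0005  # Da; COMET-family fragment bin
    fragment_tolerance: float = 0.4     # Da
    precursor_exclusion: float = 2.0    # Da around the precursor m/z
    # singly-charged b/y always; doubly-charged fragments added when the
    # precursor charge is >= this value
    double_fragment_min_precursor_z: int = 3


@dataclass(frozen=True)
class TheoreticalSpectrum:
    """b/y fragment positions generated for one candidate peptide."""

    peptide: ModifiedPeptide
    fragment_charge: int
    fragment_mzs: tuple[tuple[str, int, float], ...]  # (ion type, index, m/z)


@dataclass(frozen=True)
class ProcessedSpectrum:
    """A measured spectrum after K-score preprocessing.

    ``binned_intensity`` maps fragment-bin index (floor(m/z / bin width))
    to the normalized intensity retained for that bin.
    """

    binned_intensity: dict[int, float] = field(default_factory=dict)
    mz_range: tuple[float, float] = (0.0, 0.0)
    total_intensity: float = 0.0


def generate_theoretical(
    peptide: ModifiedPeptide,
    fragment_charge: int = 1,
    table: MassTable = DEFAULT_MASS_TABLE,
) -> TheoreticalSpectrum:
    """b1..b(n-1) and y1..y(n-1) fragment m/z values for ``peptide``.

    b_i carries the first i residues (+ their mods) plus a proton; y_i the
    last i residues plus water and a proton.  For fragment charge z the
    neutral fragment mass gains z protons and is divided by z.
    """
    seq = peptide.sequence
    n = len(seq)
    if n < 2:
        raise ValueError("peptide must have length >= 2 to fragment")
    if fragment_charge < 1:
        raise ValueError("fragment charge must be >= 1")
    delta_at = [0.0] * (n + 1)
    for pos, delta in peptide.mod_state:
        delta_at[pos] += delta

    rm = table.residue_mass
    z = fragment_charge
    frags: list[tuple[str, int, float]] = []
    prefix = 0.0
    for i in range(1, n):
        prefix += rm[seq[i - 1]] + delta_at[i]
        frags.append(("b", i, (prefix + z * table.proton_mass) / z))
    suffix = 0.0
    for i in range(1, n):
        suffix += rm[seq[n - i]] + delta_at[n - i + 1]
        frags.append(("y", i, (suffix + table.water_mass + z * table.proton_mass) / z))
    return TheoreticalSpectrum(peptide=peptide, fragment_charge=z, fragment_mzs=tuple(frags))


def preprocess(
    peaks: Iterable[tuple[float, float]],
    precursor_mz: float,
    params: ScoringParams = ScoringParams(),
) -> ProcessedSpectrum:
    """K-score spectrum normalization.

    1. drop peaks within ±``precursor_exclusion`` of the precursor m/z;
    2. compress intensities with a square root;
    3. split the observed m/z range into ``n_windows`` equal windows and
       scale each non-empty window so its maximum equals ``window_cap``;
    4. collapse peaks into fragment bins, keeping the maximum per bin.
    """
    kept = [
        (mz, math.sqrt(intensity))
        for mz, intensity in peaks
        if abs(mz - precursor_mz) > params.precursor_exclusion and intensity > 0
    ]
    if not kept:
        return ProcessedSpectrum()
    kept.sort()
    low = kept[0][0]
    high = kept[-1][0]
    span = high - low
    nw = max(1, params.n_windows)

    def window_of(mz: float) -> int:
        if span <= 0:
            return 0
        return min(int((mz - low) / span * nw), nw - 1)

    window_max = [0.0] * nw
    for mz, inten in kept:
        w = window_of(mz)
        if inten > window_max[w]:
            window_max[w] = inten

    bins: dict[int, float] = {}
    total = 0.0
    for mz, inten in kept:
        scale = params.window_cap / window_max[window_of(mz)]
        value = inten * scale
        b = int(mz / params.fragment_bin_width)
        if value > bins.get(b, 0.0):
            bins[b] = value
    total = sum(bins.values())
    return ProcessedSpectrum(binned_intensity=bins, mz_range=(low, high), total_intensity=total)


def kscore(
    processed: ProcessedSpectrum,
    theoretical: TheoreticalSpectrum,
    fragment_tolerance: float | None = None,
    params: ScoringParams = ScoringParams(),
) -> tuple[float, int, dict]:
    """Dot product of matched peak intensities after normalization.

    Each theoretical fragment (taken greedily in b1.., y1.. order) credits
    the maximum processed intensity among the bins overlapping
    [m/z − tol, m/z + tol]; each processed bin is creditable at most once,
    keeping the score a true dot product.  Returns
    (score, matched_count, stats).
    """
    tol = params.fragment_tolerance if fragment_tolerance is None else fragment_tolerance
    bins = processed.binned_intensity
    width = params.fragment_bin_width
    used: set[int] = set()
    score = 0.0
    matched = 0
    if bins:
        for _ion, _idx, mz in theoretical.fragment_mzs:
            lo_bin = int((mz - tol) / width)
            hi_bin = int((mz + tol) / width)
            best_bin = None
            best = 0.0
            for b in range(lo_bin, hi_bin + 1):
                v = bins.get(b, 0.0)
                if b not in used and v > best:
                    best = v
                    best_bin = b
            if best_bin is not None:
                used.add(best_bin)
                score += best
                matched += 1
    stats = {
        "total_ions": len(theoretical.fragment_mzs),
        "matched_ions": matched,
        "total_intensity": processed.total_intensity,
    }
    return score, matched, stats
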