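"""In-silico enzymatic digestion of proteins into candidate peptides.

The enzyme is a generic cleave-after / blocked-by-next rule; trypsin
(cleave after K/R, blocked by a following P) is the default.  Digestion
enumerates fragments spanning up to ``max_missed_cleavages`` internal
sites, and in semitryptic mode additionally every fragment with exactly
one enzymatic terminus (the X!Tandem convention for "semi").
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator

from pyteomics import fasta as _fasta

log = logging.getLogger(__name__)

TRYPTIC = "tryptic"
SEMITRYPTIC = "semitryptic"


@dataclass(frozen=True)
class EnzymeRule:
    cleave_after: frozenset[str] = frozenset("KR")
    block_if_next: frozenset[str] = frozenset("P")
    max_missed_cleavages: int = 1
    mode: str = TRYPTIC

    def __post_init__(self) -> None:
        if self.mode not in (TRYPTIC, SEMITRYPTIC):
            raise ValueError(f"mode must be tryptic|semitryptic, got {self.mode!r}")
        if self.max_missed_cleavages < 0:
            raise ValueError("max_missed_cleavages must be >= 0")


TRYPSIN = EnzymeRule()


@dataclass(frozen=True)
class ProteinRecord:
    id: str
    description: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"empty sequence for protein {self.id!r}")


def cleavage_sites(sequence: str, rule: EnzymeRule = TRYPSIN) -> list[int]:
    """0-based indices ``i`` such that the bond after ``sequence[i]`` is cut.

    A site at the last residue coincides with the protein end (which is
    always a fragment boundary regardless).
    """
    sites = []
    n = len(sequence)
    for i, aa in enumerate(sequence):
        if aa in rule.cleave_after and (i + 1 >= n or sequence[i + 1] not in rule.block_if_next):
            sites.append(i)
    return sites


def digest(
    protein: ProteinRecord,
    rule: EnzymeRule = TRYPSIN,
    min_length: int = 6,
    max_length: int = 50,
) -> list[tuple[str, int]]:
    """Peptides of ``protein`` as (sequence, missed_cleavage_count) pairs.

    Fully tryptic fragments span consecutive cleavage boundaries and at most
    ``rule.max_missed_cleavages`` internal sites; semitryptic mode adds every
    sub-fragment keeping at least one enzymatic terminus.  Output order is
    deterministic: by start position, then end position.  Length filters are
    applied last (pass ``min_length=1`` and a large ``max_length`` to disable).
    """
    seq = protein.sequence
    n = len(seq)
    sites = cleavage_sites(seq, rule)
    # Fragment boundaries: start-of-protein, after each site, end-of-protein.
    bounds = sorted({0, n} | {i + 1 for i in sites})
    internal = [b for b in bounds if 0 < b < n]

    out: list[tuple[int, int, int]] = []  # (start, end, missed)
    m = rule.max_missed_cleavages
    for bi, start in enumerate(bounds[:-1]):
        for missed, end in enumerate(bounds[bi + 1 : bi + 2 + m]):
            out.append((start, end, missed))

    if rule.mode == SEMITRYPTIC:
        seen = {(s, e) for s, e, _ in out}
        internal_set = set(internal)
        starts = set(bounds[:-1])
        ends = set(bounds[1:])
        semi: list[tuple[int, int, int]] = []
        for s, e, _ in out:
            # trim from the right: keep the enzymatic N-terminus
            for e2 in range(s + 1, e):
                missed = sum(1 for b in internal_set if s < b < e2)
                if missed <= m and (s, e2) not in seen and e2 not in ends:
                    semi.append((s, e2, missed))
            # trim from the left: keep the enzymatic C-terminus
            for s2 in range(s + 1, e):
                missed = sum(1 for b in internal_set if s2 < b < e)
                if missed <= m and (s2, e) not in seen and s2 not in starts:
                    semi.append((s2, e, missed))
        dedup = {}
        for s, e, missed in out + semi:
            dedup.setdefault((s, e), missed)
        out = [(s, e, missed) for (s, e), missed in dedup.items()]

    out.sort(key=lambda t: (t[0], t[1]))
    return [
        (seq[s:e], missed)
        for s, e, missed in out
        if min_length <= e - s <= max_length
    ]


def read_fasta(path: str | Path) -> Iterator[ProteinRecord]:
    """Stream ProteinRecords from a multi-record FASTA file.

    The id is the first whitespace-delimited token of the header; wrapped
    sequence lines are concatenated; a trailing ``*`` stop character is
    stripped.  Internal nonstandard letters (including internal ``*``) are
    kept — peptides containing them are rejected later by the
    unknown-residue policy, with the protein id logged.
    """
    with _fasta.read(str(path)) as reader:
        for description, sequence in reader:
            parts = description.split(None, 1)
            pid = parts[0] if parts else description
            desc = parts[1] if len(parts) > 1 else ""
            seq = sequence.upper().rstrip("*")
            if not seq:
                log.warning("skipping empty-sequence protein %s", pid)
                continue
            yield ProteinRecord(id=pid, description=desc, sequence=seq)
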