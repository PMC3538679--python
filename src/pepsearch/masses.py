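"""Monoisotopic mass model: residues, termini, protons, and modifications.

All mass arithmetic in the package funnels through this module so the
constants live in exactly one place.  Masses are monoisotopic throughout,
matching X!Tandem / K-score practice; the charge carrier is a proton.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

log = logging.getLogger(__name__)

#: Monoisotopic residue masses (Da) for the 20 standard amino acids.
MONOISOTOPIC_RESIDUE_MASS: dict[str, float] = {
    "G": 57.02146372,
    "A": 71.03711379,
    "S": 87.03202841,
    "P": 97.05276385,
    "V": 99.06841391,
    "T": 101.04767847,
    "C": 103.00918448,
    "L": 113.08406398,
    "I": 113.08406398,
    "N": 114.04292744,
    "D": 115.02694302,
    "Q": 128.05857751,
    "K": 128.09496302,
    "E": 129.04259309,
    "M": 131.04048491,
    "H": 137.05891186,
    "F": 147.06841391,
    "R": 156.10111102,
    "Y": 163.06332853,
    "W": 186.07931295,
}

#: Monoisotopic mass of H2O (Da), added once per peptide (the termini).
WATER_MASS = 18.01056468
#: Mass of the charge-carrying proton (Da).
PROTON_MASS = 1.00727646688


class UnknownResidueError(ValueError):
    """Raised when a sequence contains a letter absent from the mass table."""


@dataclass(frozen=True)
class MassTable:
    """Residue masses plus the water/proton constants used everywhere."""

    residue_mass: Mapping[str, float] = field(
        default_factory=lambda: dict(MONOISOTOPIC_RESIDUE_MASS)
    )
    water_mass: float = WATER_MASS
    proton_mass: float = PROTON_MASS

    def __post_init__(self) -> None:
        for aa, m in self.residue_mass.items():
            if not 57.0 <= m <= 190.0:
                raise ValueError(f"residue mass out of range for {aa!r}: {m}")


DEFAULT_MASS_TABLE = MassTable()

ModState = tuple[tuple[int, float], ...]


def peptide_neutral_mass(
    sequence: str,
    mod_state: Iterable[tuple[int, float]] = (),
    table: MassTable = DEFAULT_MASS_TABLE,
) -> float:
    """Neutral monoisotopic mass: sum of residue masses + water + mod deltas.

    Raises :class:`UnknownResidueError` on letters outside the table
    (B, J, O, U, X, Z, ``*`` ...); the caller decides whether that drops
    the peptide or the whole protein.
    """
    if not sequence:
        raise ValueError("empty peptide sequence")
    total = table.water_mass
    rm = table.residue_mass
    for aa in sequence:
        try:
            total += rm[aa]
        except KeyError:
            raise UnknownResidueError(f"unknown residue {aa!r} in {sequence!r}") from None
    for _pos, delta in mod_state:
        total += delta
    return total


def precursor_mz(neutral_mass: float, z: int, table: MassTable = DEFAULT_MASS_TABLE) -> float:
    """m/z of the [M + zH]^z+ ion."""
    if z < 1:
        raise ValueError(f"charge must be >= 1, got {z}")
    if neutral_mass <= 0:
        raise ValueError(f"neutral mass must be positive, got {neutral_mass}")
    return (neutral_mass + z * table.proton_mass) / z


def neutral_mass_from_mz(mz: float, z: int, table: MassTable = DEFAULT_MASS_TABLE) -> float:
    """Inverse of :func:`precursor_mz`."""
    if z < 1:
        raise ValueError(f"charge must be >= 1, got {z}")
    return mz * z - z * table.proton_mass


def mz1_equivalent(mz: float, z: int, table: MassTable = DEFAULT_MASS_TABLE) -> float:
    """Map a precursor of any charge onto the singly-protonated m/z axis.

    The peptide database is binned on this one canonical coordinate so a
    single database serves every charge state.
    """
    return neutral_mass_from_mz(mz, z, table) + table.proton_mass


# ---------------------------------------------------------------------------
# Modifications

N_TERM = "N-term"
C_TERM = "C-term"


@dataclass(frozen=True)
class ModificationSpec:
    """One declared modification: a target residue (or terminus), a signed
    monoisotopic delta, and whether it is fixed or variable.

    Fixed mods apply to every occurrence of the target.  Variable mods
    enumerate presence/absence per site, with at most
    ``max_variable_per_peptide`` applied sites of this spec per peptide.
    """

    target: str
    delta_mass: float
    kind: str = "variable"  # "fixed" | "variable"
    max_variable_per_peptide: int = 3

    def __post_init__(self) -> None:
        if self.kind not in ("fixed", "variable"):
            raise ValueError(f"kind must be 'fixed' or 'variable', got {self.kind!r}")
        if self.target not in (N_TERM, C_TERM) and (
            len(self.target) != 1 or not self.target.isalpha()
        ):
            raise ValueError(f"bad modification target {self.target!r}")
        if self.max_variable_per_peptide < 0:
            raise ValueError("max_variable_per_peptide must be >= 0")

    def sites(self, sequence: str) -> list[int]:
        """1-based positions in ``sequence`` this spec can modify."""
        if self.target == N_TERM:
            return [1]
        if self.target == C_TERM:
            return [len(sequence)]
        return [i + 1 for i, aa in enumerate(sequence) if aa == self.target]


#: Built-in catalog, selectable by name in config files.
MOD_CATALOG: dict[str, ModificationSpec] = {
    "carbamidomethyl-C": ModificationSpec("C", 57.02146, "fixed"),
    "oxidation-M": ModificationSpec("M", 15.99491, "variable", 2),
}


def parse_modification(spec: str) -> ModificationSpec:
    """Parse ``residue:delta:fixed|variable[:max]`` or a catalog name."""
    if spec in MOD_CATALOG:
        return MOD_CATALOG[spec]
    parts = spec.split(":")
    if len(parts) not in (3, 4):
        raise ValueError(
            f"bad modification {spec!r}; expected catalog name or residue:delta:kind[:max]"
        )
    target, delta, kind = parts[0], float(parts[1]), parts[2]
    max_per = int(parts[3]) if len(parts) == 4 else 3
    return ModificationSpec(target, delta, kind, max_per)


def enumerate_mod_states(
    sequence: str, mods: Sequence[ModificationSpec]
) -> list[ModState]:
    """All admissible modification states of ``sequence``.

    Every state carries all fixed-mod sites; variable-mod site subsets are
    enumerated per spec up to its ``max_variable_per_peptide``.  States are
    deduplicated and returned in a deterministic order (sorted by the
    (position, delta) tuples), independent of the order of ``mods``.
    """
    fixed: list[tuple[int, float]] = []
    variable_choices: list[list[ModState]] = []
    for m in sorted(mods, key=lambda m: (m.target, m.delta_mass, m.kind)):
        sites = m.sites(sequence)
        if not sites:
            continue
        if m.kind == "fixed":
            fixed.extend((pos, m.delta_mass) for pos in sites)
        else:
            choices: list[ModState] = []
            for k in range(0, min(m.max_variable_per_peptide, len(sites)) + 1):
                for subset in itertools.combinations(sites, k):
                    choices.append(tuple((pos, m.delta_mass) for pos in subset))
            variable_choices.append(choices)

    states: set[ModState] = set()
    for combo in itertools.product(*variable_choices) if variable_choices else [()]:
        state = list(fixed)
        for part in combo:
            state.extend(part)
        states.add(tuple(sorted(state)))
    return sorted(states)


# ---------------------------------------------------------------------------
# The database record

def mod_state_key(sequence: str, mod_state: Iterable[tuple[int, float]]) -> str:
    """Canonical identity key of a modified peptide.

    Deltas are rounded to 5 decimals so float noise cannot split identical
    states; this key is what "duplicate keys are collapsed automatically"
    means for modified peptides, and it is the deterministic sort order used
    throughout (bin storage, tie-breaking between equal scores).
    """
    mods = ";".join(f"{pos}:{delta:.5f}" for pos, delta in sorted(mod_state))
    return f"{sequence}|{mods}"


def parse_mod_state_key(key: str) -> tuple[str, ModState]:
    sequence, _, mods = key.partition("|")
    if not mods:
        return sequence, ()
    state = []
    for item in mods.split(";"):
        pos, _, delta = item.partition(":")
        state.append((int(pos), float(delta)))
    return sequence, tuple(state)


@dataclass(frozen=True, order=True)
class ModifiedPeptide:
    """A digested sequence with a concrete modification state, its source
    proteins, and its neutral monoisotopic mass — the unit stored in the
    database."""

    sequence: str
    mod_state: ModState = ()
    protein_ids: tuple[str, ...] = ()
    neutral_mass: float = 0.0

    @classmethod
    def create(
        cls,
        sequence: str,
        mod_state: Iterable[tuple[int, float]] = (),
        protein_ids: Iterable[str] = (),
        table: MassTable = DEFAULT_MASS_TABLE,
    ) -> "ModifiedPeptide":
        state = tuple(sorted(mod_state))
        for pos, _ in state:
            if not 1 <= pos <= len(sequence):
                raise ValueError(f"mod position {pos} outside 1..{len(sequence)}")
        return cls(
            sequence=sequence,
            mod_state=state,
            protein_ids=tuple(sorted(set(protein_ids))),
            neutral_mass=peptide_neutral_mass(sequence, state, table),
        )

    @property
    def key(self) -> str:
        return mod_state_key(self.sequence, self.mod_state)

    def mz1(self, table: MassTable = DEFAULT_MASS_TABLE) -> float:
        """Singly-protonated m/z — the database bin coordinate."""
        return self.neutral_mass + table.proton_mass

    def to_json_obj(self) -> dict:
        return {
            "seq": self.sequence,
            "mods": [[pos, delta] for pos, delta in self.mod_state],
            "proteins": list(self.protein_ids),
            "mass": self.neutral_mass,
        }

    @classmethod
    def from_json_obj(cls, obj: dict) -> "ModifiedPeptide":
        return cls(
            sequence=obj["seq"],
            mod_state=tuple((int(p), float(d)) for p, d in obj["mods"]),
            protein_ids=tuple(obj["proteins"]),
            neutral_mass=float(obj["mass"]),
        )
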