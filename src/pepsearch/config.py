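"""Search configuration: enzyme, modifications, tolerances, execution knobs.

A single :class:`SearchConfig` drives both database building and searching.
The subset of fields that determines database content (enzyme, mods, length
filter, bin width, mass constants) is hashed into the database catalog, and
a search refuses to run against a database built under a different hash.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import yaml

from .digestion import EnzymeRule, SEMITRYPTIC, TRYPTIC
from .masses import (
    DEFAULT_MASS_TABLE,
    MassTable,
    ModificationSpec,
    parse_modification,
)
from .scoring import ScoringParams


@dataclass(frozen=True)
class SearchConfig:
    enzyme: EnzymeRule = field(default_factory=EnzymeRule)
    modifications: tuple[ModificationSpec, ...] = ()
    min_peptide_length: int = 6
    max_peptide_length: int = 50
    bin_width: float = 1.0           # Da, on the z=1-equivalent m/z axis
    split_limit: int = 20_000        # peptides per stored bin split
    precursor_tolerance: float = 2.0  # Da on the z=1-equivalent axis
    precursor_tolerance_unit: str = "Da"  # "Da" | "ppm"
    charges: tuple[int, ...] = (2, 3)     # candidate charges for unknown-charge scans
    top_k: int = 10
    min_peaks: int = 5
    scoring: ScoringParams = field(default_factory=ScoringParams)
    backend: str = "serial"
    n_reducers: int = 1
    spill_threshold: int = 200_000
    seed: int = 1
    table: MassTable = field(default_factory=MassTable)

    def db_config_hash(self) -> str:
        """Hash of every field that affects database *content*."""
        payload = {
            "cleave_after": sorted(self.enzyme.cleave_after),
            "block_if_next": sorted(self.enzyme.block_if_next),
            "missed": self.enzyme.max_missed_cleavages,
            "mode": self.enzyme.mode,
            "mods": sorted(
                (m.target, round(m.delta_mass, 5), m.kind, m.max_variable_per_peptide)
                for m in self.modifications
            ),
            "min_len": self.min_peptide_length,
            "max_len": self.max_peptide_length,
            "bin_width": self.bin_width,
            "water": round(self.table.water_mass, 6),
            "proton": round(self.table.proton_mass, 6),
        }
        blob = json.dumps(payload, sort_keys=True, separators=(",", ":"))
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    def with_overrides(self, **kwargs) -> "SearchConfig":
        return replace(self, **kwargs)


def load_config(path: str | Path | None = None, **overrides) -> SearchConfig:
    """Build a SearchConfig from a YAML file plus keyword overrides."""
    data: dict = {}
    if path is not None:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
    data.update(overrides)
    return config_from_dict(data)


def config_from_dict(data: dict) -> SearchConfig:
    kwargs: dict = {}
    enz = data.get("enzyme", {})
    if enz:
        kwargs["enzyme"] = EnzymeRule(
            cleave_after=frozenset(enz.get("cleave_after", "KR")),
            block_if_next=frozenset(enz.get("block_if_next", "P")),
            max_missed_cleavages=int(enz.get("missed_cleavages", 1)),
            mode=enz.get("mode", TRYPTIC),
        )
    if "modifications" in data:
        mods = []
        for item in data["modifications"] or []:
            mods.append(item if isinstance(item, ModificationSpec) else parse_modification(item))
        kwargs["modifications"] = tuple(mods)
    for name in (
        "min_peptide_length",
        "max_peptide_length",
        "bin_width",
        "split_limit",
        "precursor_tolerance",
        "precursor_tolerance_unit",
        "top_k",
        "min_peaks",
        "backend",
        "n_reducers",
        "spill_threshold",
        "seed",
    ):
        if name in data:
            kwargs[name] = data[name]
    if "charges" in data:
        kwargs["charges"] = tuple(int(z) for z in data["charges"])
    if "scoring" in data:
        sc = data["scoring"]
        kwargs["scoring"] = sc if isinstance(sc, ScoringParams) else ScoringParams(**sc)
    return SearchConfig(**kwargs)


__all__ = ["SearchConfig", "load_config", "config_from_dict", "SEMITRYPTIC", "TRYPTIC"]
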