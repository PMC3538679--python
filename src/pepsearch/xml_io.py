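"""Result containers and their XML serializations.

Two dialects live here:

* a compact, versioned ``<scan>`` fragment used to ship partial per-scan
  results between pipeline stages (the intermediate values of the shuffle
  are serialized XML, mirroring the scoring statistics object contract);
* the final X!Tandem/BIOML-style ``<group>/<protein>/<domain>`` document
  the consolidation stage writes.

The ``expect`` attribute is a defined surrogate — the number of candidates
for the scan whose score is >= the match's score (equivalently
candidates_scored x the fraction scoring at least as high).  It is *not*
comparable to X!Tandem e-values.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable

from lxml import etree

from .masses import ModifiedPeptide

PARTIAL_FORMAT_VERSION = 1


@dataclass(frozen=True)
class ScoredMatch:
    """One peptide-spectrum match (PSM)."""

    peptide: ModifiedPeptide
    score: float
    matched_count: int
    total_ions: int
    charge: int          # charge of the spectrum copy that was scored
    measured_mz1: float  # measured z=1-equivalent m/z of that copy
    rank: int = 0
    expect: float | None = None

    def sort_key(self) -> tuple:
        # descending score; ties broken by the canonical modified-sequence key
        return (-self.score, self.peptide.key, self.charge)


@dataclass(frozen=True)
class ScanResult:
    """Per-scan outcome: ranked matches plus scoring statistics."""

    scan_id: str
    matches: tuple[ScoredMatch, ...] = ()
    candidates_scored: int = 0
    scores: tuple[float, ...] = ()  # all candidate scores (for the expect surrogate)


def rank_matches(matches: Iterable[ScoredMatch], top_k: int) -> tuple[ScoredMatch, ...]:
    """Sort descending by score (deterministic tie-break), truncate, re-rank."""
    ordered = sorted(matches, key=ScoredMatch.sort_key)[:top_k]
    return tuple(replace(m, rank=i + 1) for i, m in enumerate(ordered))


def merge_partials(partials: Iterable[ScanResult], top_k: int) -> ScanResult:
    """Combine partial results of one scan (across bins/splits/charge copies).

    Associative and commutative: any grouping or ordering of the partials
    yields the identical ScanResult.
    """
    partials = list(partials)
    if not partials:
        raise ValueError("merge_partials requires at least one partial")
    scan_id = partials[0].scan_id
    all_matches: list[ScoredMatch] = []
    candidates = 0
    scores: list[float] = []
    for p in partials:
        if p.scan_id != scan_id:
            raise ValueError(f"cannot merge partials of {p.scan_id!r} into {scan_id!r}")
        all_matches.extend(p.matches)
        candidates += p.candidates_scored
        scores.extend(p.scores)
    return ScanResult(
        scan_id=scan_id,
        matches=rank_matches(all_matches, top_k),
        candidates_scored=candidates,
        scores=tuple(sorted(scores)),
    )


def with_expect(result: ScanResult) -> ScanResult:
    """Fill each match's expect surrogate from the candidate score list."""
    scores = sorted(result.scores)
    import bisect

    def expect_of(s: float) -> float:
        return float(len(scores) - bisect.bisect_left(scores, s))

    return replace(
        result,
        matches=tuple(replace(m, expect=expect_of(m.score)) for m in result.matches),
    )


# ---------------------------------------------------------------------------
# intermediate <scan> fragments

def _mods_attr(peptide: ModifiedPeptide) -> str:
    return ";".join(f"{pos}:{delta:.5f}" for pos, delta in peptide.mod_state)


def _parse_mods_attr(text: str) -> tuple[tuple[int, float], ...]:
    if not text:
        return ()
    out = []
    for item in text.split(";"):
        pos, _, delta = item.partition(":")
        out.append((int(pos), float(delta)))
    return tuple(out)


def partial_to_xml(result: ScanResult) -> str:
    root = etree.Element(
        "scan",
        id=result.scan_id,
        candidates=str(result.candidates_scored),
        version=str(PARTIAL_FORMAT_VERSION),
    )
    scores_el = etree.SubElement(root, "scores")
    scores_el.text = " ".join(repr(s) for s in result.scores)
    for m in result.matches:
        etree.SubElement(
            root,
            "match",
            seq=m.peptide.sequence,
            mods=_mods_attr(m.peptide),
            proteins=",".join(m.peptide.protein_ids),
            mass=repr(m.peptide.neutral_mass),
            score=repr(m.score),
            matched=str(m.matched_count),
            ions=str(m.total_ions),
            z=str(m.charge),
            mh=repr(m.measured_mz1),
            rank=str(m.rank),
        )
    return etree.tostring(root, encoding="unicode")


def partial_from_xml(text: str) -> ScanResult:
    try:
        root = etree.fromstring(text)
    except etree.XMLSyntaxError as exc:
        raise ValueError(f"cannot deserialize partial result: {exc}") from exc
    if root.tag != "scan" or int(root.get("version", "0")) != PARTIAL_FORMAT_VERSION:
        raise ValueError("unrecognized partial result fragment")
    scores_el = root.find("scores")
    scores = tuple(
        float(tok) for tok in (scores_el.text or "").split()
    ) if scores_el is not None else ()
    matches = []
    for el in root.findall("match"):
        peptide = ModifiedPeptide(
            sequence=el.get("seq"),
            mod_state=_parse_mods_attr(el.get("mods", "")),
            protein_ids=tuple(p for p in el.get("proteins", "").split(",") if p),
            neutral_mass=float(el.get("mass")),
        )
        matches.append(
            ScoredMatch(
                peptide=peptide,
                score=float(el.get("score")),
                matched_count=int(el.get("matched")),
                total_ions=int(el.get("ions")),
                charge=int(el.get("z")),
                measured_mz1=float(el.get("mh")),
                rank=int(el.get("rank", "0")),
            )
        )
    return ScanResult(
        scan_id=root.get("id"),
        matches=tuple(matches),
        candidates_scored=int(root.get("candidates")),
        scores=scores,
    )


# ---------------------------------------------------------------------------
# final BIOML-style output

def scan_group_element(result: ScanResult) -> etree._Element:
    """One ``<group type="model">`` per scan, X!Tandem style."""
    result = with_expect(result)
    top = result.matches[0] if result.matches else None
    group = etree.Element(
        "group",
        id=result.scan_id,
        type="model",
        candidates=str(result.candidates_scored),
    )
    if top is not None:
        group.set("z", str(top.charge))
        group.set("mh", repr(top.measured_mz1))
    for m in result.matches:
        for protein_id in m.peptide.protein_ids:
            protein = etree.SubElement(group, "protein", id=protein_id)
            peptide_el = etree.SubElement(protein, "peptide")
            domain = etree.SubElement(
                peptide_el,
                "domain",
                id=f"{result.scan_id}.{m.rank}",
                seq=m.peptide.sequence,
                mass=repr(m.peptide.neutral_mass),
                mh=repr(m.peptide.mz1()),
                delta=repr(m.measured_mz1 - m.peptide.mz1()),
                z=str(m.charge),
                score=repr(m.score),
                matched=str(m.matched_count),
                ions=str(m.total_ions),
                rank=str(m.rank),
                expect=repr(m.expect),
            )
            for pos, delta in m.peptide.mod_state:
                etree.SubElement(
                    domain,
                    "aa",
                    type=m.peptide.sequence[pos - 1],
                    at=str(pos),
                    modified=f"{delta:.5f}",
                )
    return group


def write_results(
    path: str | Path,
    group_xml_fragments: Iterable[str],
    label: str,
) -> None:
    """Assemble the single consolidated output document.

    ``group_xml_fragments`` must already be in ascending scan order (the
    single-reducer sorted-key guarantee makes that free).
    """
    with open(path, "w") as fh:
        fh.write('<?xml version="1.0" encoding="UTF-8"?>\n')
        fh.write(f'<bioml label="{label}">\n')
        for fragment in group_xml_fragments:
            fh.write(fragment)
            fh.write("\n")
        fh.write("</bioml>\n")


def read_results(path: str | Path) -> list[ScanResult]:
    """Parse a consolidated output file back into ScanResults.

    Candidate score lists are not stored in the final document, so
    ``scores`` comes back empty; every other field round-trips exactly.
    """
    tree = etree.parse(str(path))
    results = []
    for group in tree.getroot().findall("group"):
        by_rank: dict[int, dict] = {}
        for protein in group.findall("protein"):
            domain = protein.find("peptide/domain")
            rank = int(domain.get("rank"))
            entry = by_rank.setdefault(
                rank,
                {
                    "seq": domain.get("seq"),
                    "mods": tuple(
                        (int(aa.get("at")), float(aa.get("modified")))
                        for aa in domain.findall("aa")
                    ),
                    "mass": float(domain.get("mass")),
                    "score": float(domain.get("score")),
                    "matched": int(domain.get("matched")),
                    "ions": int(domain.get("ions")),
                    "z": int(domain.get("z")),
                    "mh": float(domain.get("mh")),
                    "delta": float(domain.get("delta")),
                    "expect": float(domain.get("expect")),
                    "proteins": [],
                },
            )
            entry["proteins"].append(protein.get("id"))
        matches = []
        for rank in sorted(by_rank):
            e = by_rank[rank]
            peptide = ModifiedPeptide(
                sequence=e["seq"],
                mod_state=e["mods"],
                protein_ids=tuple(sorted(e["proteins"])),
                neutral_mass=e["mass"],
            )
            matches.append(
                ScoredMatch(
                    peptide=peptide,
                    score=e["score"],
                    matched_count=e["matched"],
                    total_ions=e["ions"],
                    charge=e["z"],
                    measured_mz1=e["mh"] + e["delta"],
                    rank=rank,
                    expect=e["expect"],
                )
            )
        results.append(
            ScanResult(
                scan_id=group.get("id"),
                matches=tuple(matches),
                candidates_scored=int(group.get("candidates")),
            )
        )
    return results
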