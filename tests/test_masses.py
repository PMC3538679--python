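"""Mass arithmetic and modification-state enumeration."""

from __future__ import annotations

import pytest
from hypothesis import given, settings, strategies as st
from pyteomics import mass as pt_mass

from pepsearch.masses import (
    DEFAULT_MASS_TABLE,
    MONOISOTOPIC_RESIDUE_MASS,
    ModificationSpec,
    ModifiedPeptide,
    UnknownResidueError,
    enumerate_mod_states,
    mod_state_key,
    neutral_mass_from_mz,
    parse_mod_state_key,
    parse_modification,
    peptide_neutral_mass,
    precursor_mz,
)

AA = sorted(MONOISOTOPIC_RESIDUE_MASS)
peptide_strategy = st.text(alphabet=AA, min_size=1, max_size=30)


@pytest.mark.parametrize(
    "sequence",
    ["G", "PEPTIDE", "ACDEFGHIKLMNPQRSTVWY", "KKKKKK"],
)
def test_neutral_mass_matches_elemental_composition_oracle(sequence):
    """Residue-sum masses agree with an independent elemental-composition
    summation (pyteomics) within 1e-4 Da."""
    expected = pt_mass.calculate_mass(sequence=sequence)
    assert peptide_neutral_mass(sequence) == pytest.approx(expected, abs=1e-4)


def test_known_reference_masses():
    assert peptide_neutral_mass("G") == pytest.approx(75.0320, abs=1e-4)
    assert peptide_neutral_mass("PEPTIDE") == pytest.approx(799.3600, abs=1e-4)


@settings(max_examples=200, derandomize=True)
@given(peptide_strategy, peptide_strategy)
def test_concatenation_identity(p1, p2):
    """mass(p1 + p2) = mass(p1) + mass(p2) - water, to 1e-9 Da."""
    lhs = peptide_neutral_mass(p1 + p2)
    rhs = (
        peptide_neutral_mass(p1)
        + peptide_neutral_mass(p2)
        - DEFAULT_MASS_TABLE.water_mass
    )
    assert lhs == pytest.approx(rhs, abs=1e-9)


def test_unknown_residue_rejected():
    with pytest.raises(UnknownResidueError):
        peptide_neutral_mass("PEPTIDEX")
    with pytest.raises(UnknownResidueError):
        peptide_neutral_mass("PEB")


def test_mod_deltas_included():
    base = peptide_neutral_mass("ACK")
    assert peptide_neutral_mass("ACK", [(2, 57.02146)]) == pytest.approx(
        base + 57.02146, abs=1e-9
    )


def test_precursor_mz_formula():
    assert precursor_mz(500.0, 1) == pytest.approx(501.00728, abs=1e-5)
    assert precursor_mz(999.99272, 2) == pytest.approx(501.00364, abs=1e-5)
    with pytest.raises(ValueError):
        precursor_mz(500.0, 0)


@settings(max_examples=100, derandomize=True)
@given(st.floats(min_value=100.0, max_value=5000.0), st.integers(min_value=1, max_value=5))
def test_precursor_mz_round_trip(neutral, z):
    assert neutral_mass_from_mz(precursor_mz(neutral, z), z) == pytest.approx(
        neutral, abs=1e-9
    )


# ---------------------------------------------------------------------------
# modification enumeration

FIXED_C = ModificationSpec("C", 57.02146, "fixed")
VAR_M = ModificationSpec("M", 15.99491, "variable", 2)


def test_enumerate_example_amcm():
    """Fixed C + variable M (max 2) on AMCM: the four M subsets, each
    carrying the fixed C mod — verified against explicit enumeration."""
    states = enumerate_mod_states("AMCM", [FIXED_C, VAR_M])
    expected = {
        ((3, 57.02146),),
        ((2, 15.99491), (3, 57.02146)),
        ((3, 57.02146), (4, 15.99491)),
        ((2, 15.99491), (3, 57.02146), (4, 15.99491)),
    }
    assert set(states) == expected
    assert len(states) == 4
    assert all(any(pos == 3 for pos, _ in s) for s in states)


def test_no_mod_targets_single_empty_state():
    assert enumerate_mod_states("GAVLI", [FIXED_C, VAR_M]) == [()]


@pytest.mark.parametrize("k", [0, 1, 2, 3])
def test_powerset_count_when_max_unlimited(k):
    spec = ModificationSpec("S", 79.96633, "variable", max_variable_per_peptide=10)
    states = enumerate_mod_states("A" + "S" * k, [spec])
    assert len(states) == 2**k


def test_max_variable_cap_respected():
    spec = ModificationSpec("M", 15.99491, "variable", max_variable_per_peptide=1)
    states = enumerate_mod_states("MMM", [spec])
    assert len(states) == 4  # empty + three singletons
    assert all(len(s) <= 1 for s in states)


@settings(max_examples=50, derandomize=True)
@given(st.permutations([FIXED_C, VAR_M, ModificationSpec("K", 8.01420, "variable", 1)]))
def test_enumeration_invariant_to_spec_order(mods):
    reference = enumerate_mod_states("MCKMK", [FIXED_C, VAR_M, ModificationSpec("K", 8.01420, "variable", 1)])
    assert enumerate_mod_states("MCKMK", list(mods)) == reference
    assert len(set(reference)) == len(reference)  # no duplicate states


def test_terminus_mod_sites():
    nterm = ModificationSpec("N-term", 42.01057, "variable", 1)
    states = enumerate_mod_states("PEPK", [nterm])
    assert states == [(), ((1, 42.01057),)]


def test_mod_state_key_round_trip():
    state = ((2, 15.99491), (3, 57.02146))
    key = mod_state_key("AMCK", state)
    assert parse_mod_state_key(key) == ("AMCK", state)
    assert parse_mod_state_key(mod_state_key("AMCK", ())) == ("AMCK", ())


def test_parse_modification_catalog_and_inline():
    carb = parse_modification("carbamidomethyl-C")
    assert (carb.target, carb.kind) == ("C", "fixed")
    inline = parse_modification("S:79.96633:variable:2")
    assert inline == ModificationSpec("S", 79.96633, "variable", 2)
    with pytest.raises(ValueError):
        parse_modification("nonsense")


def test_modified_peptide_identity_and_mass():
    p = ModifiedPeptide.create("AMCK", [(3, 57.02146)], ["P2", "P1", "P1"])
    assert p.protein_ids == ("P1", "P2")
    assert p.neutral_mass == pytest.approx(
        peptide_neutral_mass("AMCK") + 57.02146, abs=1e-6
    )
    assert p.mz1() == pytest.approx(p.neutral_mass + DEFAULT_MASS_TABLE.proton_mass)
    assert ModifiedPeptide.from_json_obj(p.to_json_obj()) == p
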