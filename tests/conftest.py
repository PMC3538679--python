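"""Shared fixtures: the standard synthetic dataset and a built database."""

from __future__ import annotations

import pytest

from pepsearch.config import SearchConfig
from pepsearch.fixtures import generate_fixture
from pepsearch.masses import parse_modification
from pepsearch.peptide_db import build_database


@pytest.fixture(scope="session")
def base_config() -> SearchConfig:
    """Trypsin/1-missed with the conventional fixed+variable modifications."""
    return SearchConfig(
        modifications=(
            parse_modification("carbamidomethyl-C"),
            parse_modification("oxidation-M"),
        )
    )


@pytest.fixture(scope="session")
def clean_fixture(tmp_path_factory, base_config):
    """Noise-free standard fixture: 20 proteins, 50 spectra, seed 1."""
    return generate_fixture(
        tmp_path_factory.mktemp("fixture_clean"), seed=1, config=base_config
    )


@pytest.fixture(scope="session")
def noisy_fixture(tmp_path_factory, base_config):
    """Same conditions with 20% non-colliding noise peaks, seed 1."""
    return generate_fixture(
        tmp_path_factory.mktemp("fixture_noisy"),
        seed=1,
        noise_fraction=0.2,
        config=base_config,
    )


@pytest.fixture(scope="session")
def built_db(tmp_path_factory, base_config, clean_fixture):
    db_dir = tmp_path_factory.mktemp("db")
    return build_database(clean_fixture.fasta_path, base_config, db_dir)
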