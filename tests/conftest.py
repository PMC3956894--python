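"""Shared fixtures: one fully-prepared folding problem reused across tests.

The fixture protein is a 60-residue helix hairpin; the fragment library and
pair potential are built from five other toy structures of different
topologies, lengths and seeds, with target-identity decontamination, so the
target's own torsions never enter the library directly.
"""

import numpy as np
import pytest

from contactfold import (
    EnergyModel,
    ToySpec,
    build_library,
    build_shortlists,
    calibrate_weights,
    make_toy,
    train_pair_potential,
)
from contactfold.synthetic import true_contact_list

TARGET_SPEC = ToySpec("helix_hairpin", 60, 1)
SOURCE_SPECS = [
    ToySpec("helix_hairpin", 50, 7),
    ToySpec("helix_hairpin", 64, 8),
    ToySpec("three_helix_bundle", 75, 7),
    ToySpec("beta_hairpin", 44, 7),
    ToySpec("mixed", 70, 7),
]


@pytest.fixture(scope="session")
def toy60():
    """(native, record, ss_pred) of the 60-residue helix hairpin target."""
    return make_toy(TARGET_SPEC)


@pytest.fixture(scope="session")
def true_contacts(toy60):
    native, _, _ = toy60
    return true_contact_list(native)


@pytest.fixture(scope="session")
def sources():
    return [make_toy(spec)[0] for spec in SOURCE_SPECS]


@pytest.fixture(scope="session")
def library(sources, toy60):
    _, record, _ = toy60
    return build_library(sources, exclude_target=record)


@pytest.fixture(scope="session")
def pair_table(sources):
    return train_pair_potential(sources)


@pytest.fixture(scope="session")
def energy_model(pair_table, toy60, true_contacts):
    _, record, ss_pred = toy60
    em = EnergyModel.from_ss_prediction(pair_table, ss_pred)
    return calibrate_weights(em, record.sequence, true_contacts, seed=3)


@pytest.fixture(scope="session")
def shortlists(library, toy60, energy_model):
    _, record, ss_pred = toy60
    return build_shortlists(library, record, ss_pred, energy_model.pair_table)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
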