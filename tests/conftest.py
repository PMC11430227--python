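"""Shared fixtures.

The expensive artefacts — the ~50k-sample synthetic movement database and
the goal-prediction network trained on it — are built once per session and
shared by every test that needs them.  Seeds are fixed so the whole suite
is reproducible.
"""

from __future__ import annotations

import numpy as np
import pytest

import hybridarm as ha

DB_SEED = 101
TRAIN_SEED = 102


@pytest.fixture(scope="session")
def geometry():
    return ha.default_geometry()


@pytest.fixture(scope="session")
def rom():
    return ha.default_rom()


@pytest.fixture(scope="session")
def database(rom):
    """Full-size synthetic natural-movement database (~500 movements)."""
    return ha.synthetic_database(rom, seed=DB_SEED)


@pytest.fixture(scope="session")
def training_set(database, geometry):
    return ha.build_training_set(database, geometry)


@pytest.fixture(scope="session")
def small_training_set(rom, geometry):
    """A ~6k-sample set for tests of training mechanics (fast)."""
    db = ha.synthetic_database(rom, n_participants=2, movements_per_participant=30, seed=7)
    return ha.build_training_set(db, geometry)


@pytest.fixture(scope="session")
def pc_plus(training_set):
    """PC+ network trained with the standard recipe on the full database."""
    return ha.train(ha.NetworkSpec.for_variant("pc+"), training_set, seed=TRAIN_SEED)


@pytest.fixture(scope="session")
def eval_rom(database, rom):
    """Evaluation range of motion: the user's shoulder range combined with
    the database's distal amplitude quantiles (the rule used when the
    user's own distal joints cannot be measured)."""
    return ha.rom_from_database(database, rom)


@pytest.fixture(scope="session")
def oracle_setup(geometry, rom):
    """Targets with a zero-error lookup predictor, for controller tests."""
    targets, postures = ha.sample_plausible_targets(
        geometry, rom, n=20, seed=33, return_postures=True
    )
    return targets, postures, ha.TablePredictor(targets, postures)
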