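"""Shared fixtures: sequences, canonical builds, and small sampled ensembles."""

import numpy as np
import pytest

from abfret.conformer_model import (
    ToyEnergyParams,
    build_conformer,
    f19p,
    temperature_ladder,
    wild_type,
)

ALPHA = (-63.0, -43.0)
BETA = (-135.0, 135.0)
CANON_HELIX = (-57.0, -47.0)


@pytest.fixture(scope="session")
def wt_seq():
    return wild_type()


@pytest.fixture(scope="session")
def f19p_seq():
    return f19p()


@pytest.fixture(scope="session")
def helix_conformer(wt_seq):
    return build_conformer(wt_seq, [CANON_HELIX] * 19, label="helix")


@pytest.fixture(scope="session")
def extended_conformer(wt_seq):
    return build_conformer(wt_seq, [(-180.0, 180.0)] * 19, label="extended")


@pytest.fixture(scope="session")
def beta_conformer(wt_seq):
    return build_conformer(wt_seq, [BETA] * 19, label="beta")


@pytest.fixture(scope="session")
def default_params():
    return ToyEnergyParams()


@pytest.fixture(scope="session")
def short_ladder():
    return temperature_ladder(220.0, 850.0, 20)


@pytest.fixture()
def rng():
    return np.random.default_rng(20261)
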