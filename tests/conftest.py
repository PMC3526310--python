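"""Shared fixtures: energy model, folding backend, demo trees, RNG helpers."""

from __future__ import annotations

import numpy as np
import pytest

from mirtarget import conservation
from mirtarget.thermo import EnergyModel, NearestNeighborBackend

TWELVE_LEAF_NEWICK = (
    "(((s1:0.1,s2:0.15):0.05,(s3:0.2,s4:0.1):0.1):0.1,"
    "((s5:0.12,s6:0.18):0.07,((s7:0.1,s8:0.1):0.05,"
    "(s9:0.2,(s10:0.1,(s11:0.05,s12:0.08):0.04):0.06):0.05):0.08):0.06);"
)


@pytest.fixture(scope="session")
def energy_model() -> EnergyModel:
    return EnergyModel.default()


@pytest.fixture(scope="session")
def backend(energy_model) -> NearestNeighborBackend:
    return NearestNeighborBackend(energy_model)


@pytest.fixture()
def twelve_leaf_tree():
    return conservation.read_tree(TWELVE_LEAF_NEWICK)


def random_rna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGU"), size=length))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
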