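"""Shared fixtures: hand-built pedigrees and small simulated datasets."""

import numpy as np
import pytest
from hypothesis import settings

from famres.pedigree import Individual, Pedigree

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture
def nuclear_ped() -> Pedigree:
    """Two founders, one son, one daughter."""
    return Pedigree([
        Individual("N", "dad", sex="male"),
        Individual("N", "mom", sex="female"),
        Individual("N", "son", "dad", "mom", "male"),
        Individual("N", "dau", "dad", "mom", "female"),
    ])


@pytest.fixture
def three_gen_ped() -> Pedigree:
    """Three generations with grandparents, avuncular, cousins and half-sibs.

    Founders gf x gm have children a (marries sa), b (marries sb) and u
    (unmarried).  a has children c1, c2; b has child c3; sa also has child
    h1 with an unknown partner (half-sib of c1/c2).
    """
    return Pedigree([
        Individual("T", "gf", sex="male"),
        Individual("T", "gm", sex="female"),
        Individual("T", "a", "gf", "gm", "male"),
        Individual("T", "b", "gf", "gm", "female"),
        Individual("T", "u", "gf", "gm", "male"),
        Individual("T", "sa", sex="female"),
        Individual("T", "sb", sex="male"),
        Individual("T", "c1", "a", "sa", "male"),
        Individual("T", "c2", "a", "sa", "female"),
        Individual("T", "c3", "sb", "b", "male"),
        Individual("T", "h1", None, "sa", "female"),
    ])


@pytest.fixture
def inbred_ped() -> Pedigree:
    """Child of a full-sib mating: F = 0.25, phi(c, c) = 0.625."""
    return Pedigree([
        Individual("I", "f", sex="male"),
        Individual("I", "m", sex="female"),
        Individual("I", "s1", "f", "m", "male"),
        Individual("I", "s2", "f", "m", "female"),
        Individual("I", "c", "s1", "s2", "male"),
    ])


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
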