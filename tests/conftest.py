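import numpy as np
import pandas as pd
import pytest

from tolgen import pedigree as pedmod
from tolgen import simulate as sim


@pytest.fixture(scope="session")
def trio_pedigree():
    return pedmod.make_pedigree([("O", "S", "D"), ("S", None, None), ("D", None, None)])


def random_pedigree(rng, n=60, n_founders=10):
    """Random acyclic pedigree (founders first, arbitrary matings)."""
    trips = []
    for i in range(n):
        if i < n_founders:
            trips.append((f"a{i}", None, None))
        else:
            s = f"a{rng.integers(0, i)}"
            d = f"a{rng.integers(0, i)}"
            if s == d:
                d = None
            trips.append((f"a{i}", s, d))
    return pedmod.make_pedigree(trips)


@pytest.fixture(scope="session")
def tiny_population():
    """360-offspring balanced population used by several model tests."""
    cfg = sim.SimConfig.reduced(n_sires=15, dams_per_sire=4, offspring_per_dam=6)
    ped, tab, truth = sim.simulate_population(cfg, seed=42)
    return ped, tab, truth


@pytest.fixture(scope="session")
def small_population():
    """~1200-offspring population for tolerance-model tests."""
    cfg = sim.SimConfig.reduced(n_sires=25, dams_per_sire=6, offspring_per_dam=8)
    ped, tab, truth = sim.simulate_population(cfg, seed=7)
    return ped, tab, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(20260921)
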