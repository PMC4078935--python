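import numpy as np
import pandas as pd
import pytest

from mulard import pedigree as pg
from mulard import simdata


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240101)


@pytest.fixture(scope="session")
def small_config():
    """A fast, fully featured study configuration for unit tests."""
    return simdata.SimulationConfig(
        n_crossbreds=300,
        n_dams=75,
        n_sires=15,
        common_pedigree_size=120,
        muscovy_pedigree_size=45,
        pedigree_generations=3,
        seed=20240202,
    )


@pytest.fixture(scope="session")
def small_study(small_config):
    return simdata.simulate_study(small_config, spectra=True)


@pytest.fixture(scope="session")
def founder_pedigrees():
    """Unrelated parents: 40 dams and 12 sires, no ancestry."""
    ped_d = pg.from_frame(
        pd.DataFrame({"animal": np.arange(1, 41), "sire": 0, "dam": 0})
    )
    ped_s = pg.from_frame(
        pd.DataFrame({"animal": np.arange(1, 13), "sire": 0, "dam": 0})
    )
    return ped_d, ped_s


def make_crossbred_frame(rng, ped_d, ped_s, n, s2d, s2s, s2e, mean=30.0, n_levels=4):
    """Crossbred records from unrelated parents with known components."""
    nd, ns = len(ped_d), len(ped_s)
    ud = rng.normal(0, np.sqrt(s2d), nd)
    us = rng.normal(0, np.sqrt(s2s), ns)
    dam = rng.integers(nd, size=n)
    sire = rng.integers(ns, size=n)
    lev = rng.integers(n_levels, size=n)
    lev_eff = rng.normal(0, 1.0, n_levels)
    y = mean + lev_eff[lev] + ud[dam] + us[sire] + rng.normal(0, np.sqrt(s2e), n)
    return pd.DataFrame(
        {
            "animal": [f"C{i}" for i in range(n)],
            "dam": ped_d.ids[dam],
            "sire": ped_s.ids[sire],
            "fixed_level": lev + 1,
            "y": y,
        }
    )
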