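import numpy as np
import pytest

from ssgblup import pedigree as pg
from ssgblup import simulate as sim


def random_pedigree(n: int, n_founders: int, seed: int, loops: bool = False) -> pg.Pedigree:
    """Random valid pedigree with arbitrary inbreeding (parents may be
    related; repeated matings allowed)."""
    rng = np.random.default_rng(seed)
    sire, dam = [], []
    for i in range(n):
        if i < n_founders:
            sire.append(-1)
            dam.append(-1)
        else:
            s, d = rng.integers(0, i, 2)
            sire.append(int(s))
            dam.append(int(d))
    return pg.from_arrays(sire, dam)


@pytest.fixture(scope="session")
def trio_ped() -> pg.Pedigree:
    # sire, dam, offspring
    return pg.from_arrays(sire=[-1, -1, 0], dam=[-1, -1, 1])


@pytest.fixture(scope="session")
def small_cfg() -> sim.SimConfig:
    """Scaled-down breeding program used across module tests."""
    return sim.SimConfig(
        n_chromosomes=5,
        n_snps=600,
        n_qtl=200,
        n_founders=150,
        families_per_year=25,
        offspring_per_family=12,
        genotyped_fraction=0.4,
        carcass_fraction=0.5,
        n_year_classes=3,
    )


@pytest.fixture(scope="session")
def small_ds(small_cfg):
    ds, truth, geno_all = sim.simulate_population(small_cfg, seed=20)
    return ds, truth, geno_all
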