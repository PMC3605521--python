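import numpy as np
import pandas as pd
import pytest

from nutribalance import Composition, CompositionTable, default_ionome_sbp

LABELS5 = ("N", "P", "K", "Ca", "Mg")


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def ionome_sbp():
    return default_ionome_sbp()


@pytest.fixture
def np_tissue():
    """The worked 2-part tissue: 2.50% N, 0.15% P."""
    return Composition(np.array([2.50, 0.15]), ("N", "P"), kappa=100.0, unit="%")


@pytest.fixture
def leaf_composition():
    """A 5-nutrient leaf sample in g/kg dry matter."""
    return Composition(np.array([25.0, 1.5, 10.0, 15.0, 2.0]), LABELS5,
                       kappa=1000.0, unit="g/kg")


def random_composition(rng, D=5, labels=None, kappa=100.0):
    vals = rng.lognormal(mean=0.0, sigma=1.0, size=D)
    labels = labels or tuple(f"x{i+1}" for i in range(D))
    return Composition(vals, labels, kappa=kappa)


def random_table(rng, n=20, D=5, labels=None, kappa=100.0, group=None):
    vals = rng.lognormal(mean=0.0, sigma=0.5, size=(n, D))
    labels = labels or [f"x{i+1}" for i in range(D)]
    df = pd.DataFrame(vals, columns=list(labels),
                      index=[f"s{i+1}" for i in range(n)])
    grp = pd.Series(group, index=df.index) if group is not None else None
    return CompositionTable(df, kappa=kappa, group=grp)
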