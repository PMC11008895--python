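import numpy as np
import pandas as pd
import pytest

from ecoeff import synthetic, weights as wmod


@pytest.fixture
def ring4():
    return synthetic.make_lattice_weights(4, "ring")


@pytest.fixture
def ring4_std(ring4):
    return wmod.row_standardize(ring4)


@pytest.fixture
def path4_std():
    w = np.zeros((4, 4))
    for i, j in [(0, 1), (1, 2), (2, 3)]:
        w[i, j] = w[j, i] = 1.0
    return wmod.row_standardize(wmod.SpatialWeights(ids=list("abcd"), w=w))


@pytest.fixture
def small_panel_csv(tmp_path):
    """2 regions x 3 years well-formed long CSV."""
    df = pd.DataFrame({
        "region": ["R1"] * 3 + ["R2"] * 3,
        "year": [2012, 2013, 2014] * 2,
        "capital": [10.0, 11.0, 12.0, 20.0, 21.0, 22.0],
        "labour": [5.0, 5.5, 6.0, 8.0, 8.5, 9.0],
        "energy": [3.0, 3.2, 3.4, 6.0, 6.1, 6.2],
        "gdp": [100.0, 110.0, 121.0, 200.0, 210.0, 220.0],
        "carbon": [7.0, 7.1, 7.2, 12.0, 12.5, 13.0],
    })
    path = tmp_path / "panel.csv"
    df.to_csv(path, index=False)
    return path
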