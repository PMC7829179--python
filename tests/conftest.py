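import numpy as np
import pandas as pd
import pytest

from morphospace import FERN_SCHEMA, TraitTable


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_traits(rows: dict[str, tuple]) -> TraitTable:
    """Build a trait table from {species: (rhizome, dissection, texture, length, hydathodes)}."""
    df = pd.DataFrame.from_dict(
        rows, orient="index",
        columns=["rhizome_type", "laminar_dissection", "laminar_texture",
                 "laminar_length", "hydathodes"],
    )
    df.index.name = "species_id"
    return TraitTable(df, FERN_SCHEMA)


@pytest.fixture
def two_species():
    # hand-computable Gower pair: d = (0 + 1 + 1 + 1 + 1)/5 = 0.8
    return make_traits({"A": (1, 0, 1, 10.0, 0), "B": (1, 2, 3, 30.0, 1)})


@pytest.fixture
def unit_square():
    return np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 1.0], [0.0, 1.0]])


@pytest.fixture
def unit_cube():
    g = np.array([0.0, 1.0])
    return np.array([[x, y, z] for x in g for y in g for z in g])
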