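import warnings

import numpy as np
import pandas as pd
import pytest

from fdprice import SimConfig, generate_counts, generate_traits
from fdprice.traits import BODY_MASS_COL, DIET_COLS, STRATA_COLS

warnings.filterwarnings(
    "ignore",
    message="negative eigenvalues carry",
    category=UserWarning,
)


@pytest.fixture
def small_config():
    return SimConfig(n_sites=12, n_years=3, n_species=15, seed=42)


@pytest.fixture
def small_data(small_config):
    traits = generate_traits(small_config)
    counts = generate_counts(small_config)
    return traits, counts


def make_traits(diet, strata, mass, species=None):
    """Assemble a valid trait table from per-species percentage dicts."""
    n = len(mass)
    species = species or [f"s{i}" for i in range(n)]
    df = pd.DataFrame(0.0, index=pd.Index(species, name="species"),
                      columns=DIET_COLS + STRATA_COLS + [BODY_MASS_COL])
    for i, d in enumerate(diet):
        for k, v in d.items():
            df.iloc[i, df.columns.get_loc(k)] = v
    for i, s in enumerate(strata):
        for k, v in s.items():
            df.iloc[i, df.columns.get_loc(k)] = v
    df[BODY_MASS_COL] = mass
    return df


@pytest.fixture
def five_site_fixture():
    """5 sites x 6 species counts plus 2-D coordinates, hand-buildable."""
    rng = np.random.default_rng(7)
    counts = pd.DataFrame(
        rng.integers(0, 5, size=(5, 6)),
        index=[f"site{i}" for i in range(5)],
        columns=[f"sp{j}" for j in range(6)],
    )
    counts.iloc[3] = 0  # one empty site
    counts.iloc[4, :] = 0
    counts.iloc[4, 2] = 3  # one single-species site
    coords = pd.DataFrame(
        rng.normal(size=(6, 2)), index=counts.columns, columns=["axis1", "axis2"]
    )
    return counts, coords
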