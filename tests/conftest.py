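import numpy as np
import pandas as pd
import pytest

from regalforage import SeasonConfig, VisitationDataset, simulate_season


def make_dataset(rows):
    """Build a dataset from (year, day, sex, species[, count]) tuples."""
    frame = pd.DataFrame(
        [r if len(r) == 5 else (*r, 1) for r in rows],
        columns=["year", "ordinal_day", "sex", "plant_species", "count"],
    )
    return VisitationDataset.from_frame(frame)


@pytest.fixture(scope="session")
def default_season():
    """One seeded realization of the default 21-year study conditions."""
    return simulate_season(SeasonConfig(), seed=42)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
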