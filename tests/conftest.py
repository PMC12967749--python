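import numpy as np
import pandas as pd
import pytest

from colimstat import Thresholds, design_for_year
from colimstat.tables import biomass_from_frame


@pytest.fixture(scope="session")
def design2022():
    return design_for_year(2022)


@pytest.fixture(scope="session")
def design2021():
    return design_for_year(2021)


@pytest.fixture(scope="session")
def thresholds():
    return Thresholds()


def make_biomass_frame(means, stream_id="S1", response_var="chl_a", replicates=5, sd=0.0, seed=0):
    """Frame with `replicates` cups per treatment around the given means."""
    rng = np.random.default_rng(seed)
    rows = []
    for label, mu in means.items():
        for rep in range(1, replicates + 1):
            val = mu if sd == 0 else max(0.0, mu + rng.normal(0, sd))
            rows.append((stream_id, response_var, label, rep, val))
    return pd.DataFrame(rows, columns=["stream_id", "response_var", "treatment", "replicate", "biomass"])


@pytest.fixture
def flat_means_2022(design2022):
    """Complete 2022 design at a constant mean of 2.0."""
    return {t.label: 2.0 for t in design2022.treatments}


@pytest.fixture
def flat_table_2022(design2022, flat_means_2022):
    return biomass_from_frame(make_biomass_frame(flat_means_2022), design2022)
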