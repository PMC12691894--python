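import numpy as np
import pandas as pd
import pytest

import healthfin as hf


@pytest.fixture(scope="session")
def ref_coords() -> pd.DataFrame:
    """Packaged 3-D MDS coordinates of the 38 OECD health systems."""
    return hf.load_reference_coordinates()


@pytest.fixture(scope="session")
def ref_V(ref_coords) -> pd.DataFrame:
    return ref_coords[["V1", "V2", "V3"]]


@pytest.fixture(scope="session")
def default_truth() -> hf.SimulationTruth:
    return hf.truth_defaults()


@pytest.fixture(scope="session")
def default_panel(default_truth) -> pd.DataFrame:
    """One default synthetic panel (38 countries × 22 years × 12 indicators)."""
    return hf.simulate_panel(default_truth, n_years=22, seed=7)


@pytest.fixture(scope="session")
def zero_noise_panel(default_truth) -> pd.DataFrame:
    return hf.simulate_panel(default_truth.zero_noise(), n_years=22, seed=1)


def wide_panel_frame(n_countries=2, n_years=2, rng=None) -> pd.DataFrame:
    """A small wide-format panel with plausible values for every indicator."""
    rng = rng or np.random.default_rng(0)
    rows = []
    for i in range(n_countries):
        for y in range(2000, 2000 + n_years):
            rows.append({
                "country": f"c{i}",
                "year": y,
                "oop_pc": 500 + 10 * rng.random(),
                "oop_gdp": 1.5,
                "vol_pc": 100.0,
                "vol_gdp": 0.5,
                "comp_pc": 2000.0,
                "comp_gdp": 6.0,
                "hale_total": 43.0,
                "hale_male": 42.0,
                "hale_female": 44.0,
                "im_total": 4.0,
                "im_male": 4.3,
                "im_female": 3.7,
            })
    return pd.DataFrame(rows)
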