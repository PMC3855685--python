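import numpy as np
import pandas as pd
import pytest

from canopyocc.synthetic import CanopySpec, SimConfig, Stratum, simulate_detection_data


@pytest.fixture
def two_strata_spec():
    """Shrub + canopy strata over a strong ground return."""
    return CanopySpec(
        strata=(Stratum(3.0, 1.0, 0.2), Stratum(25.0, 3.0, 0.5)),
        ground_energy_fraction=0.3,
    )


@pytest.fixture
def noise_free_cfg():
    return SimConfig(seed=1)


@pytest.fixture
def separable_spec():
    """Three strata each dominated by a distinct height band, with a ground
    return stronger than the shrub layer (so ground identification is
    unambiguous)."""
    return CanopySpec(
        strata=(
            Stratum(2.5, 0.4, 0.15),
            Stratum(6.5, 0.8, 0.30),
            Stratum(20.0, 2.0, 0.25),
        ),
        ground_energy_fraction=0.30,
    )


@pytest.fixture
def small_detection_data():
    """n=40 sites, 2 visits, one informative site covariate."""
    rng = np.random.default_rng(42)
    covs = pd.DataFrame({"x": rng.normal(size=40)})
    data, truth = simulate_detection_data(
        covs, np.array([0.2, 1.0]), np.array([0.8, 0.0, -0.3, 0.0]), 2, seed=7
    )
    return data, truth
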