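import numpy as np
import pandas as pd
import pytest

from littoralhdm import (
    CoastlineDataset,
    HabitatSpec,
    SyntheticCoastConfig,
    generate_coast,
    generate_environment,
    generate_habitat,
)


@pytest.fixture(scope="session")
def small_env():
    """A 1,200-point synthetic environment (predictors only)."""
    return generate_environment(SyntheticCoastConfig(n=1200, seed=11))


@pytest.fixture(scope="session")
def widespread_dataset(small_env):
    """Environment plus one widespread ~30 % habitat layer."""
    spec = HabitatSpec("wide", "widespread", 0.30,
                       {"sst_avg": -1.0, "wh_avg": 2.0}, 0.0)
    return generate_habitat(small_env, spec, seed=5)


@pytest.fixture(scope="session")
def six_habitat_dataset():
    """A 2,000-point coast with the six default habitat layers."""
    from littoralhdm import default_habitat_specs
    return generate_coast(
        SyntheticCoastConfig(n=2000, seed=21, habitat_specs=default_habitat_specs())
    )


def make_tiny_dataset(n=8, habitat=None):
    """Hand-built minimal dataset on a vertical line."""
    df = pd.DataFrame({
        "x": np.zeros(n),
        "y": -10.0 * np.arange(n),
        "sst_avg": np.linspace(16.8, 18.7, n),
        "wh_avg": np.linspace(0.1, 0.5, n),
        "wh_min": np.linspace(0.01, 0.05, n),
        "slope_class": ([1, 2, 3, 4, 5] * n)[:n],
        "geology": (["plutonic", "sedimentary"] * n)[:n],
        "substrate": (["natural", "natural", "artificial"] * n)[:n],
    })
    codes = ()
    if habitat is not None:
        df["Hab"] = habitat
        codes = ("Hab",)
    return CoastlineDataset(df, codes)
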