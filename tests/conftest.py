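import numpy as np
import pandas as pd
import pytest

from ursatroph.diet import default_categories
from ursatroph.inference import MCMCConfig


@pytest.fixture(scope="session")
def categories():
    return default_categories()


@pytest.fixture(scope="session")
def fast_mcmc():
    return MCMCConfig.reduced(seed=42, chains=2, iterations=1500, burn_in=400)


@pytest.fixture
def toy_refs():
    """Small but well-formed reference tables for paleo sub-models."""
    from ursatroph.isotopes import ReferenceTables

    rng = np.random.default_rng(5)
    elev = pd.DataFrame({
        "d15N": rng.normal(4.0, 1.0, 30) - 0.001 * np.linspace(0, 3000, 30),
        "elevation": np.linspace(0, 3000, 30),
        "material": np.tile(["vegetation", "sheep_wool", "cattle_hair"], 10),
    })
    return ReferenceTables(
        tooth_bone=rng.normal(0.8, 0.4, 20),
        elevation=elev,
        tdf=rng.normal(3.3, 0.9, 10),
        marine=pd.DataFrame({"d13C": [-13.0, -12.0, -14.0],
                             "d15N": [15.0, 16.0, 14.0]}),
    )
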