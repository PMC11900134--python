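"""Shared fixtures: small planted-signal datasets, generated at test time."""

from __future__ import annotations

import numpy as np
import pytest

from gpcrscreen.featurize import FingerprintSpec, featurize_set
from gpcrscreen.synthetic import PlantedSAR, generate_library


@pytest.fixture(scope="session")
def spec512() -> FingerprintSpec:
    return FingerprintSpec(radius=2, n_bits=512)


@pytest.fixture(scope="session")
def sar_small() -> PlantedSAR:
    return PlantedSAR(receptor_id="CCR6", pharmacophore_smiles="NC(=O)c1ccco1",
                      baseline=5.0, effect_size=3.0, noise_sd=0.1,
                      n_actives=60, n_inactives=60, seed=3)


@pytest.fixture(scope="session")
def sar_library(sar_small):
    """60 carriers + 60 non-carriers with a planted furanamide signal."""
    return generate_library(sar_small)


@pytest.fixture(scope="session")
def sar_features(sar_library, spec512):
    compounds, activities = sar_library
    X = featurize_set(compounds, spec512)
    y = np.array([a.pchembl for a in activities])
    return X, y


@pytest.fixture(scope="session")
def fitted_regressor(sar_features):
    from gpcrscreen.models import PChEMBLRegressor

    X, y = sar_features
    return PChEMBLRegressor(n_estimators=(50, 500), n_trials=3,
                            random_state=1).fit(X, y)
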