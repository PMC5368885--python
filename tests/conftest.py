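import numpy as np
import pytest

from leafphys import reference
from leafphys.model_core import BiochemParams, KineticConstants
from leafphys.conductance import StomatalParams
from leafphys.synthetic_data import (
    FLUOR_WELL_WATERED,
    NoiseModel,
    TreatmentSpec,
)


@pytest.fixture(scope="session")
def kinetics() -> KineticConstants:
    return KineticConstants()


@pytest.fixture(scope="session")
def n85_biochem() -> BiochemParams:
    """Well-watered high-nitrogen reference parameter set."""
    return reference.reference_biochem("well-watered", "N85")


@pytest.fixture(scope="session")
def n85_stomatal() -> StomatalParams:
    return reference.reference_stomatal("well-watered", "N85")


@pytest.fixture(scope="session")
def n85_spec(n85_biochem, n85_stomatal) -> TreatmentSpec:
    return TreatmentSpec(
        water="well-watered", nitrogen="N85",
        na=reference.reference_na("well-watered", "N85"),
        biochem=n85_biochem, stomatal=n85_stomatal,
        fluorescence=FLUOR_WELL_WATERED, n_replicates=6)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20170328)


@pytest.fixture(scope="session")
def zero_noise() -> NoiseModel:
    return NoiseModel.zero()


def draw_leaf_params(rng: np.random.Generator):
    """One random physiologically valid parameter/environment draw."""
    from leafphys.model_core import Environment

    biochem = BiochemParams(
        vcmax25=rng.uniform(40, 150),
        jmax25=rng.uniform(80, 200),
        kappa2ll=rng.uniform(0.15, 0.35),
        rd25=rng.uniform(0.2, 1.5),
        gm25=rng.uniform(0.05, 0.4),
    )
    a1 = rng.uniform(0.3, 0.8)
    b1 = rng.uniform(0.0, 0.3)
    stomatal = StomatalParams(g0=rng.uniform(0.005, 0.05), a1=a1, b1=b1)
    while True:
        vpd = rng.uniform(0.5, 2.5)
        if 0.05 < a1 - b1 * vpd < 0.95:
            break
    env = Environment(iinc=rng.uniform(0, 1500), ca=rng.uniform(200, 1000),
                      t=rng.uniform(15, 30), vpd=vpd)
    return env, biochem, stomatal
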