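import numpy as np
import pytest

from imprintqg import ImprintingLocus, PopulationState

#: Printed 4-decimal values of the two worked inactivation scenarios
#: (column group -> row -> value); None marks cells merged in the layout.
TABLE6_EXPECTED = {
    "paternal_inactivation": {
        "A1_2b": {
            "additive_variance_female": 0.4278,
            "additive_variance_male": 0.0028,
            "dominance_variance": 0.1808,
            "sigma_AD_female": -0.1966,
            "sigma_AD_male": 0.0159,
            "cov_offspring_parent_female": 0.1156,
            "cov_offspring_parent_male": 0.0094,
            "cov_halfsib_female": 0.1070,
            "cov_halfsib_male": 0.0007,
            "cov_fullsib": 0.1077,
        },
        "A2a_3b": {
            "additive_variance_female": 0.2153,
            "additive_variance_male": None,
            "dominance_variance": 0.0002,
            "sigma_AD_female": 0.0,
            "sigma_AD_male": None,
            "cov_offspring_parent_female": 0.1077,
            "cov_offspring_parent_male": None,
            "cov_halfsib_female": 0.0538,
            "cov_halfsib_male": None,
            "cov_fullsib": 0.1077,
        },
        "A3a": {
            "additive_variance_female": 0.1250,
            "additive_variance_male": None,
            "dominance_variance": 0.0905,
            "sigma_AD_female": 0.0,
            "sigma_AD_male": None,
            "cov_offspring_parent_female": 0.0625,
            "cov_offspring_parent_male": None,
            "cov_halfsib_female": 0.0313,
            "cov_halfsib_male": None,
            "cov_fullsib": 0.0851,
        },
    },
    "maternal_inactivation": {
        "A1_2b": {
            "additive_variance_female": 0.0020,
            "additive_variance_male": 0.3534,
            "dominance_variance": 0.1520,
            "sigma_AD_female": 0.0122,
            "sigma_AD_male": -0.1635,
            "cov_offspring_parent_female": 0.0071,
            "cov_offspring_parent_male": 0.0949,
            "cov_halfsib_female": 0.0005,
            "cov_halfsib_male": 0.0883,
            "cov_fullsib": 0.0890,
        },
        "A2a_3b": {
            "additive_variance_female": 0.1777,
            "additive_variance_male": None,
            "dominance_variance": 0.0008,
            "sigma_AD_female": 0.0,
            "sigma_AD_male": None,
            "cov_offspring_parent_female": 0.0888,
            "cov_offspring_parent_male": None,
            "cov_halfsib_female": 0.0444,
            "cov_halfsib_male": None,
            "cov_fullsib": 0.0890,
        },
        "A3a": {
            "additive_variance_female": 0.1020,
            "additive_variance_male": None,
            "dominance_variance": 0.0764,
            "sigma_AD_female": 0.0,
            "sigma_AD_male": None,
            "cov_offspring_parent_female": 0.0510,
            "cov_offspring_parent_male": None,
            "cov_halfsib_female": 0.0255,
            "cov_halfsib_male": None,
            "cov_fullsib": 0.0701,
        },
    },
}


@pytest.fixture
def paternal_scenario():
    """Near-complete paternal inactivation worked example."""
    return ImprintingLocus(a=0.5, k1=0.9, k2=-0.8), PopulationState(p1=0.5)


@pytest.fixture
def maternal_scenario():
    """Near-complete maternal inactivation worked example."""
    return ImprintingLocus(a=0.5, k1=-0.7, k2=0.95), PopulationState(p1=1.0 / 3.0)


def random_model(rng: np.random.Generator, f: bool = False):
    """A random admissible (locus, population) pair for property checks."""
    locus = ImprintingLocus(
        a=rng.uniform(-1.5, 1.5),
        k1=rng.uniform(-1.0, 1.0),
        k2=rng.uniform(-1.0, 1.0),
    )
    pop = PopulationState(
        p1=rng.uniform(0.02, 0.98), f=rng.uniform(0.0, 1.0) if f else 0.0
    )
    return locus, pop
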