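import numpy as np
import pytest

from hordeomics import GeneratorParams, default_design
from hordeomics.pipeline import synthetic_inputs


#: Table of trait summaries as printed for the wild-type and mutant lines
#: (mean, sd, n per genotype; g/100 g dry weight). Used as pipeline input.
TABLE1 = {
    "fatty_acid": {
        "WT": (3.15, 0.07), "B": (3.12, 0.04), "C": (5.76, 0.38), "D": (2.76, 0.07),
        "BC": (5.28, 0.04), "CD": (5.74, 0.53), "BD": (3.47, 0.23),
    },
    "tag": {
        "WT": (1.39, 0.20), "B": (1.47, 0.27), "C": (3.22, 0.32), "D": (1.26, 0.18),
        "BC": (2.92, 0.35), "CD": (3.16, 0.15), "BD": (1.57, 0.12),
    },
    "starch": {
        "WT": (51.65, 0.96), "B": (45.02, 2.20), "C": (38.82, 0.83), "D": (49.16, 2.84),
        "BC": (38.42, 2.60), "CD": (35.64, 0.90), "BD": (42.95, 0.90),
    },
    "beta_glucan": {
        "WT": (3.29, 0.04), "B": (2.54, 0.05), "C": (1.20, 0.04), "D": (3.36, 0.07),
        "BC": (1.40, 0.10), "CD": (1.24, 0.11), "BD": (2.09, 0.07),
    },
}
TABLE1_N = 3


@pytest.fixture(scope="session")
def default_params():
    return GeneratorParams(seed=11)


@pytest.fixture(scope="session")
def study(default_params):
    """A complete synthetic study shared across tests (read-only)."""
    return synthetic_inputs(default_params)


@pytest.fixture(scope="session")
def design():
    return default_design()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
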