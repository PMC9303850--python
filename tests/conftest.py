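import numpy as np
import pytest

from collectivegame import ErrorModel, GameParams, SimulationSpec
from collectivegame.io import investment_summary
from collectivegame.synthetic_data import design_three_strain, simulate_assay


@pytest.fixture
def params():
    """Canonical benefit/cost parameters (b=12, c=1, theta=11/24)."""
    return GameParams(b=12.0, c=1.0)


@pytest.fixture
def params_D(params):
    return GameParams(b=params.b, c=params.c, D=0.15)


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


@pytest.fixture(scope="session")
def noiseless_three_strain_data():
    """Per-composition mean table from a noise-free three-strain assay
    generated at b=12, c=1, e=0.2, t=0.5."""
    spec = SimulationSpec(
        params=GameParams(12.0, 1.0), error=ErrorModel(0.2, 0.5),
        noise_cv=0.0, clonal_strain_cv=0.0, replicates_per_composition=1,
        seed=7,
    )
    records = simulate_assay(design_three_strain(["s1", "s2", "s3"]), spec)
    return investment_summary(records)
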