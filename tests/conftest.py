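import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from metasym import (
    DemographyParams,
    MigrationParams,
    ModelParams,
    SymbiontParams,
    build_migration_matrix,
)


@pytest.fixture
def default_params() -> ModelParams:
    return ModelParams()


@pytest.fixture
def coinfection_params() -> SymbiontParams:
    """Generating values of the four-population coinfection experiment."""
    return SymbiontParams(beta_A=0.5, beta_B=0.35, q=0.7, psi=1.2)


@pytest.fixture
def three_patch_params() -> ModelParams:
    distances = np.array([[0.0, 1.0, 2.0], [1.0, 0.0, 3.0], [2.0, 3.0, 0.0]])
    rho = build_migration_matrix(distances, kernel_scale=1.0)
    return ModelParams(
        symbiont=SymbiontParams(beta_A=0.4, beta_B=0.3, q=0.8, psi=1.1),
        demography=DemographyParams(nu_b=0.05, nu_d=0.05, phi=0.6, c_A=0.3, c_B=0.2),
        migration=MigrationParams(m=0.1, rho=rho, J=3),
    )
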