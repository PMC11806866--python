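import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from plscortex import ExpressionMatrix, make_cohort, make_expression

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def planted_dataset():
    """Small planted-signal dataset shared across tests.

    Expression (50 regions x 500 genes, 50 planted on factor 1), a cohort
    whose genetic group carries a factor-1 atrophy pattern, and the truth.
    """
    expr, truth = make_expression(
        n_regions=50, n_genes=500, n_latent=3, noise_sd=0.5, n_planted=50, seed=7
    )
    atrophy = truth.spatial_factors["factor_1"]
    cohort = make_cohort(
        n_controls=60, n_sporadic=30, n_genetic=30,
        atrophy_map=atrophy, effect=1.5, seed=11,
    )
    return ExpressionMatrix(values=expr), truth, cohort


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture()
def toy_expression():
    """Tiny fully deterministic expression matrix for I/O round trips."""
    rng = np.random.default_rng(42)
    regions = [f"LH_region_{i + 1:03d}" for i in range(6)]
    genes = [f"GENE{i + 1:03d}" for i in range(10)]
    df = pd.DataFrame(rng.normal(size=(6, 10)), index=regions, columns=genes)
    df.index.name = "region"
    return ExpressionMatrix(values=df)
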