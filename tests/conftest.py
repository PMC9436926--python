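"""Shared fixtures: scaled-down synthetic datasets generated at test time."""

import numpy as np
import pandas as pd
import pytest

from bftx.simulate import (CohortConfig, ExpressionConfig, SurfaceConfig,
                           generate_dataset)

SMALL_SURFACE = dict(n_vertices_per_hemi=400, n_subcortical_per_structure=50)
SMALL_EXPRESSION = dict(n_genes=500, cortical_samples_per_donor=40)


def small_configs(**cohort_overrides):
    return dict(
        cohort_cfg=CohortConfig(**cohort_overrides),
        surface_cfg=SurfaceConfig(**SMALL_SURFACE),
        expr_cfg=ExpressionConfig(**SMALL_EXPRESSION),
    )


@pytest.fixture(scope="session")
def small_dataset():
    """One deterministic scaled-down dataset shared across tests."""
    return generate_dataset(seed=11, **small_configs())


@pytest.fixture(scope="session")
def cohort():
    """Default-size cohort (subjects, roi, truth)."""
    from bftx.simulate import generate_cohort
    return generate_cohort(seed=5)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
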