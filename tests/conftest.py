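import numpy as np
import pytest

from sbmorph import BrainMask, CohortConfig, flatten_volumes, generate_cohort

SMALL_GRID = (12, 14, 12)


@pytest.fixture(scope="session")
def clean_cohort():
    """Noise-free planted cohort: 120 subjects, 4 sources, strong effect."""
    cfg = CohortConfig(
        n_subjects=120, n_sources=4, noise_sd=0.0, loading_shift=2.0,
        ab_positive_fraction=0.5, seed=11,
    )
    volumes, table, truth = generate_cohort(cfg)
    return cfg, volumes, table, truth


@pytest.fixture(scope="session")
def clean_matrix(clean_cohort):
    cfg, volumes, table, truth = clean_cohort
    mask = BrainMask.full(cfg.grid_shape)
    return flatten_volumes(volumes, mask)


@pytest.fixture(scope="session")
def tiny_cohort():
    """Small fast cohort for classification plumbing tests."""
    cfg = CohortConfig(
        n_subjects=60, n_sources=3, noise_sd=0.0, loading_shift=2.5,
        ab_positive_fraction=0.5, grid_shape=SMALL_GRID, source_extent=2.0, seed=5,
    )
    volumes, table, truth = generate_cohort(cfg)
    matrix = flatten_volumes(volumes, BrainMask.full(cfg.grid_shape))
    return cfg, matrix, table, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
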