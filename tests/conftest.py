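import dataclasses

import numpy as np
import pytest

from petref import (
    build_toy_atlas,
    default_ageing_model,
    matrix_from_region_means,
    preset,
    sample_cohort,
    simulate_region_means,
)


@pytest.fixture(scope="session")
def toy_atlas():
    """Small 12-region atlas with renamed cerebellum/vermis/pons regions."""
    return build_toy_atlas((24, 24, 24), (2.0, 2.0, 2.0), n_regions=12, seed=7)


@pytest.fixture(scope="session")
def tiny_atlas():
    return build_toy_atlas((16, 16, 16), (4.0, 4.0, 4.0), n_regions=10, seed=0)


@pytest.fixture
def small_cohort_config():
    """Digital-style preset scaled down for per-test speed."""
    return preset("digital", n_subjects=12, n_women=6, seed=3)


@pytest.fixture
def noise_free_config(small_cohort_config):
    return dataclasses.replace(
        small_cohort_config, noise_sd=0.0, global_factor_sd=0.0, smoothing_fwhm_mm=0.0
    )


def make_uptake_matrix(atlas, config, model_seed=0, flat_regions=("Pons",)):
    """Simulated uptake matrix straight from regional means (no rendering)."""
    model = default_ageing_model(
        atlas.region_names, seed=model_seed, flat_regions=flat_regions,
        reference_age=config.age_mean,
    )
    cohort = sample_cohort(config)
    means = np.vstack([
        simulate_region_means(meta, model, config) for meta in cohort
    ])
    return matrix_from_region_means(cohort, means, atlas.region_names)
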