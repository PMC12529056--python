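"""Shared fixtures: small kernels, landscapes and generated histories.

Expensive artifacts (kernel discretizations, survey histories, assembled
model data) are session-scoped; everything is generated programmatically
with fixed seeds.
"""

import numpy as np
import pytest

import mpbspread as mp


@pytest.fixture(scope="session")
def kernel_default_small():
    """Field-default kernel discretized on a 30-pixel support (test-sized)."""
    return mp.discretize_kernel(subpixel_n=5, support_radius=30)


@pytest.fixture(scope="session")
def kernel_wide():
    """Smooth, wide kernel (rho ~ pixel scale) for discretization-machinery tests."""
    return mp.discretize_kernel(mp.KernelParams(nu=3.0, rho=1.2), subpixel_n=5,
                                support_radius=15)


@pytest.fixture(scope="session")
def landscape48():
    return mp.generate_landscape(48, 48, seed=5)


@pytest.fixture(scope="session")
def kernel48():
    return mp.discretize_kernel(subpixel_n=5, support_radius=48)


@pytest.fixture(scope="session")
def true_params_species():
    return mp.default_true_params("species")


@pytest.fixture(scope="session")
def history48(landscape48, kernel48, true_params_species):
    return mp.generate_survey_history(
        landscape48, true_params_species, n_years=8, seed=11, kernel=kernel48
    )


@pytest.fixture(scope="session")
def grids48(landscape48, history48):
    rasters, _ = mp.rasterize_surveys(history48.points, landscape48)
    return mp.derive_infestation_vars(
        rasters["sanitized"], rasters["red_top"], shape=landscape48.shape
    )


@pytest.fixture(scope="session")
def mask48(landscape48):
    return mp.build_analysis_mask(landscape48)


@pytest.fixture(scope="session")
def model_data48(landscape48, grids48, kernel48, mask48):
    return mp.assemble_model_data(landscape48, grids48, kernel48, mask48)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
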