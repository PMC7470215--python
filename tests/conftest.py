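import numpy as np
import pytest

from carsdelin import phantom, preprocess
from carsdelin.core import TissueClass, WavenumberAxis


@pytest.fixture(scope="session")
def axis():
    return WavenumberAxis(np.arange(2700.0, 3201.0, 25.0))


@pytest.fixture(scope="session")
def small_config():
    """Small but fully-featured phantom: 2x2 grid of 64-px frames."""
    return phantom.PhantomConfig(
        frame_size=64,
        mosaic_grid=(2, 2),
        wavenumbers=tuple(np.arange(2700.0, 3201.0, 25.0)),
        region_smooth_sigma=8.0,
        seed=1,
    )


@pytest.fixture(scope="session")
def small_phantom(small_config):
    return phantom.generate_phantom(small_config)


@pytest.fixture(scope="session")
def small_table(small_phantom):
    stack, labels, calibration = small_phantom
    return preprocess.preprocess_stack(stack, labels, calibration, sample_id="s0")


@pytest.fixture(scope="session")
def clean_config(small_config):
    """Identity instrument: no noise, flat shading, zero offset, unit powers."""
    return phantom.scaled_config(
        small_config,
        noise_sigma=0.0,
        power_fluctuation=0.0,
        adc_offset=0.0,
        shading_coefficients={(0, 0): 1.0},
    )


@pytest.fixture(scope="session")
def clean_phantom(clean_config):
    return phantom.generate_phantom(clean_config)


@pytest.fixture(scope="session")
def uniform_fat_config(small_config):
    """Single-class phantom: spatially homogeneous expected content."""
    return phantom.scaled_config(
        small_config,
        classes=(TissueClass.FAT,),
        noise_sigma=0.0,
        power_fluctuation=0.0,
        adc_offset=0.0,
        seed=3,
    )


@pytest.fixture(scope="session")
def cohort_table():
    """Six preprocessed phantom samples (distinct seeds) in one table."""
    from carsdelin.cli import RunConfig, build_cohort

    return build_cohort(RunConfig(n_samples=6, frame_size=64, cv_splits=3, seed=0))
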