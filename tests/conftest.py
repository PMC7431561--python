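import numpy as np
import pytest

from ihcmark.simulate import (CohortSimConfig, ImageSimConfig,
                              OmicsSimConfig, generate_cohort,
                              generate_ihc_image, generate_omics_dataset)


@pytest.fixture(scope="session")
def omics_default():
    """Small four-genotype dataset with 5 planted targets (seed 7)."""
    return generate_omics_dataset(OmicsSimConfig(), seed=7)


@pytest.fixture(scope="session")
def image_default():
    """Default synthetic section: 40 nuclei, 30% DAB-positive (seed 3)."""
    return generate_ihc_image(ImageSimConfig(), seed=3)


@pytest.fixture(scope="session")
def cohort_default():
    """Default 75-patient prognostic cohort (seed 1)."""
    return generate_cohort(CohortSimConfig(), seed=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
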