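import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")

from marrowquant import (CohortSpec, Lesion, Organ, PhantomSpec,
                         generate_cohort, generate_phantom_study)


@pytest.fixture(scope="session")
def single_lesion_spec() -> PhantomSpec:
    """Noise-free phantom: one 10-mm lesion at ADC 1.0e-3 plus an organ blob."""
    return PhantomSpec(
        lesions=(Lesion((32.0, 32.0, 32.0), 10.0, target_adc=1.0e-3),),
        organs=(Organ((32.0, 56.0, 32.0), 5.0),),
        noise_sd=0.0,
        seed=7,
    )


@pytest.fixture(scope="session")
def single_lesion_study(single_lesion_spec):
    return generate_phantom_study(single_lesion_spec)


@pytest.fixture(scope="session")
def default_cohort():
    """16 adequate / 22 poor patients with the published group parameters."""
    return generate_cohort(CohortSpec(seed=11))
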