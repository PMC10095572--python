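import dataclasses

import numpy as np
import pytest

from alphaerd.cohort import CohortSpec, generate_profiles, synth_recording


@pytest.fixture(scope="session")
def tiny_spec() -> CohortSpec:
    """Three subjects, 60 s per condition: fast but long enough for 15 epochs."""
    return CohortSpec(
        n_per_genotype_group=(2, 1),
        duration_per_condition=60.0,
        artifact_epoch_rate=0.1,
        seed=101,
    )


@pytest.fixture(scope="session")
def tiny_recording(tiny_spec):
    """One 16-channel rest recording of the tiny cohort."""
    profile = generate_profiles(tiny_spec)[0]
    return synth_recording(profile, "rest", tiny_spec)


@pytest.fixture(scope="session")
def clean_spec() -> CohortSpec:
    """One subject, artifact-free and jitter-free: analytic oracles are exact."""
    return CohortSpec(
        n_per_genotype_group=(1, 0),
        artifact_epoch_rate=0.0,
        amp_jitter_sigma=0.0,
        attenuation_jitter_sd=0.0,
        duration_per_condition=600.0,
        seed=7,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)


def replace_spec(spec, **kw):
    return dataclasses.replace(spec, **kw)
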