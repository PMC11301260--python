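import dataclasses

import pytest

from glygln.assay import generate_plate, normalize_plate
from glygln.calibrate import reference_parameters
from glygln.model import RateConstants
from glygln.simulate import run_assay_conditions


def make_constants(**overrides) -> RateConstants:
    """A rate-constant set with every constant zero except the overrides
    (kr_3 included), for isolating single reactions in closed-form tests."""
    zeros = dict.fromkeys(
        ("kf_Glc", "kf_Gln", "kf_1", "kf_2", "kf_3", "kf_4", "kf_5", "kf_6",
         "kf_7", "kr_1", "kr_2", "kr_3", "kr_4"),
        0.0,
    )
    zeros.update(overrides)
    return RateConstants(**zeros)


@pytest.fixture(scope="session")
def ref_k() -> RateConstants:
    return reference_parameters()


@pytest.fixture(scope="session")
def ref_trajectories(ref_k):
    """The four standard assay conditions simulated once at default tolerance."""
    return run_assay_conditions(ref_k)


@pytest.fixture(scope="session")
def clean_plate(ref_k):
    """Noise-free plate (drift retained) from the reference constants."""
    return generate_plate(ref_k, noise_cv=0.0, seed=0)


@pytest.fixture(scope="session")
def clean_plate_normalized(clean_plate):
    return normalize_plate(clean_plate)


@pytest.fixture(scope="session")
def noisy_plate_normalized(ref_k):
    """3 % multiplicative noise, normalized; the standard recovery input."""
    return normalize_plate(generate_plate(ref_k, noise_cv=0.03, seed=7))
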