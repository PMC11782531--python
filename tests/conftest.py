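"""Shared simulated-detector fixtures.

Session-scoped so the expensive stacks (the 30+30 gain-reference protocol
at 256 x 256) are simulated once and reused across test modules.
"""

import numpy as np
import pytest

from ccdnoise.calibration import (
    build_gain_reference,
    estimate_kref_autocov,
)
from ccdnoise.simulate import BeamModel, DetectorModel, simulate_dark, simulate_frame

T_REF = 0.84
TARGET_COUNTS = 7050.0


@pytest.fixture(scope="session")
def det256():
    """Reference detector, 256x256, beta*g = 1.55, sigma_read = 4, sigma_row = 0.6."""
    return DetectorModel.reference((256, 256), seed=1)


@pytest.fixture(scope="session")
def det128():
    return DetectorModel.reference((128, 128), seed=7)


@pytest.fixture(scope="session")
def flat_beam_256(det256):
    return BeamModel.flat(TARGET_COUNTS / det256.g / T_REF)


@pytest.fixture(scope="session")
def refstack256(det256, flat_beam_256):
    """The 30+30 flat/dark acquisition protocol of a gain reference."""
    sigs = [simulate_frame(det256, flat_beam_256, T_REF, (1, 10, i)) for i in range(30)]
    darks = [simulate_dark(det256, T_REF, (1, 20, i)) for i in range(30)]
    return sigs, darks


@pytest.fixture(scope="session")
def gain_ref_256(refstack256):
    sigs, darks = refstack256
    ref = build_gain_reference(sigs, darks, clean_cosmics=False)
    k, rho = estimate_kref_autocov(sigs, darks, ref.sigma_ref, clean_cosmics=False)
    ref.k_ref, ref.noise_rho = k, rho
    return ref


@pytest.fixture(scope="session")
def refstack128(det128):
    beam = BeamModel.flat(TARGET_COUNTS / det128.g / T_REF)
    sigs = [simulate_frame(det128, beam, T_REF, (201, 10, i)) for i in range(20)]
    darks = [simulate_dark(det128, T_REF, (201, 20, i)) for i in range(20)]
    return sigs, darks


@pytest.fixture(scope="session")
def gain_ref_128(refstack128):
    sigs, darks = refstack128
    ref = build_gain_reference(sigs, darks, clean_cosmics=False)
    k, rho = estimate_kref_autocov(sigs, darks, ref.sigma_ref, clean_cosmics=False)
    ref.k_ref, ref.noise_rho = k, rho
    return ref


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
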