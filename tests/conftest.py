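"""Shared fixtures: materials and cached uniform-sensor spectra."""

import numpy as np
import pytest

from roughspr import (
    MaterialSet,
    HarmonicBasis,
    uniform_stack,
    angular_sweep,
)
from roughspr.spectral_metrics import SpectrumPair, compute_performance


@pytest.fixture(scope="session")
def materials():
    return MaterialSet()


@pytest.fixture(scope="session")
def uniform_pair(materials):
    """Water/BSA spectrum pair of the ideal smooth 50-nm gold sensor.

    Uniform stacks have no order coupling, so the single-harmonic basis is
    exact; the 0.01 degree grid keeps refined dip positions converged.
    """
    basis = HarmonicBasis(1)
    ref = angular_sweep(
        uniform_stack(materials, 50.0, 0.0), basis, 633.0, angle_step=0.01
    )
    bound = angular_sweep(
        uniform_stack(materials, 50.0, 5.0), basis, 633.0, angle_step=0.01
    )
    return SpectrumPair(ref, bound, 5.0, 0.02, materials)


@pytest.fixture(scope="session")
def uniform_report(uniform_pair):
    return compute_performance(uniform_pair)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
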