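from __future__ import annotations

import sys
from pathlib import Path

import numpy as np
import pytest
from hypothesis import settings

sys.path.insert(0, str(Path(__file__).parent))  # expose tests/_oracles.py

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")

from exmorph import AxonMask, PhantomSpec, ProbabilityVolume, generate_axon_phantom


@pytest.fixture
def unit_spacing():
    return (1.0, 1.0, 1.0)


@pytest.fixture
def anisotropic_spacing():
    return (0.522, 0.33, 0.33)


@pytest.fixture(scope="session")
def small_phantom():
    """A modest tubular phantom reused by several tests (session-cached)."""
    spec = PhantomSpec(seed=7, n_axons=8, radius=3.0)
    return spec, *generate_axon_phantom(spec)


def make_volume(data, spacing=(1.0, 1.0, 1.0), name="test"):
    return ProbabilityVolume(np.asarray(data, dtype=float), spacing, name=name)


def make_mask(data, spacing=(1.0, 1.0, 1.0), **kw):
    return AxonMask(np.asarray(data, dtype=bool), spacing, **kw)
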