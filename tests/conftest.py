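"""Shared fixtures: a default phantom, montage, and sphere lead field.

Everything is generated programmatically; session scope keeps the expensive
objects (lead fields, kernels) shared across test modules.
"""

from __future__ import annotations

import numpy as np
import pytest

from presaccade.forward import build_source_space, leadfield_sphere
from presaccade.montage import make_montage
from presaccade.phantom import make_phantom_head

SHELLS = (92.0, 86.0, 80.0, 78.0)
SIGMAS = (0.33, 0.0042, 1.79, 0.33)  # scalp, skull, CSF, brain


@pytest.fixture(scope="session")
def phantom():
    tissue, atlas = make_phantom_head()
    return tissue, atlas


@pytest.fixture(scope="session")
def montage():
    return make_montage()


@pytest.fixture(scope="session")
def source_space_coarse(phantom):
    tissue, _ = phantom
    return build_source_space(tissue, 8.0, include_eyes=False)


@pytest.fixture(scope="session")
def leadfield_coarse(montage, source_space_coarse):
    return leadfield_sphere(montage, source_space_coarse, SHELLS, SIGMAS)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20130702)
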