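"""Shared fixtures: small phantoms and study runs, generated at test time."""

from __future__ import annotations

import numpy as np
import pytest

from lungfx.study import StudyConfig, run_synthetic_study
from lungfx.synthetic import PhantomSpec, make_lung_phantom


@pytest.fixture(scope="session")
def small_phantom():
    """A 48^3 thorax phantom (4 mm voxels, full 192 mm physical extent)."""
    return make_lung_phantom(PhantomSpec(shape=(48, 48, 48), seed=7))


@pytest.fixture(scope="session")
def study_phantom():
    """The 64^3 phantom used by end-to-end study tests (3 mm voxels)."""
    return make_lung_phantom(PhantomSpec(shape=(64, 64, 64), seed=1))


@pytest.fixture(scope="session")
def study_result():
    """One full synthetic cohort at the default study conditions (5 subjects,
    96^3 grid at 2 mm), shared across the end-to-end tests."""
    return run_synthetic_study(StudyConfig(seed=1))


@pytest.fixture()
def rng():
    return np.random.default_rng(20230609)
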