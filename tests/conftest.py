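"""Shared fixtures: small seeded cohorts and noise-free subjects."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from nirsdoc import preprocess, synthetic_data

settings.register_profile("repeatable", derandomize=True, deadline=None)
settings.load_profile("repeatable")
from nirsdoc.synthetic_data import CohortSpec


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def tiny_cohort():
    """Five-subject cohort with default noise (session-cached for speed)."""
    spec = CohortSpec(n_per_group={"HC": 2, "MCS": 1, "VS": 2}, seed=11)
    return synthetic_data.generate_cohort(spec)


@pytest.fixture(scope="session")
def noise_free_subject():
    """One healthy-control subject with every noise term silenced."""
    spec = CohortSpec(n_per_group={"HC": 1, "MCS": 0, "VS": 0}, seed=5)
    spec.noise = spec.noise.silent()
    spec.paradigm.run_order = "fixed"
    cohort = synthetic_data.generate_cohort(spec)
    return cohort.subjects[0]


@pytest.fixture
def default_config():
    return preprocess.PreprocessConfig()
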