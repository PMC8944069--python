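"""Shared fixtures.

Expensive objects (the reference dataset and the scaled-down study
ensemble) are session-scoped: the reference solve takes ~10 s and the
4-chain DRAM ensemble several minutes, so each is computed once and shared
by every test that needs it.
"""

import numpy as np
import pytest

import myosampler as ms
from myosampler.config import RunConfig
from myosampler.pipeline import run_study

REFERENCE_SEED = 0
STUDY_SEED = 1


@pytest.fixture(scope="session")
def reference():
    """The default synthetic elbow reference dataset (seed 0)."""
    return ms.make_reference_dataset(seed=REFERENCE_SEED)


@pytest.fixture(scope="session")
def elbow_spec():
    return ms.default_elbow_spec()


@pytest.fixture(scope="session")
def posterior(reference, elbow_spec):
    return ms.ElbowPosterior(reference, elbow_spec)


@pytest.fixture(scope="session")
def study():
    """The scaled-down study: 4 DRAM chains on the elbow posterior.

    Shared by the acceptance tests (tracking fidelity, force structure,
    correlation structure, equilibration).
    """
    cfg = RunConfig.default(seed=STUDY_SEED)
    return run_study(cfg)
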