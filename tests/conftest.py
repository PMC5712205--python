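"""Shared fixtures: small synthetic arms and population fits reused across
test modules (session-scoped because the mixed-effects fit is the expensive
step)."""

import numpy as np
import pytest

from tgikit.population_fit import fit_population
from tgikit.synthetic_cohort import docetaxel_like, generate_cohort


@pytest.fixture(scope="session")
def small_arm():
    """Docetaxel-like arm, n=120, fixed seed: (assessments, survival, truth)."""
    return generate_cohort(docetaxel_like(n_patients=120), seed=5)


@pytest.fixture(scope="session")
def small_forward_fit(small_arm):
    assessments, _, _ = small_arm
    return fit_population(assessments, alignment="forward")


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
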