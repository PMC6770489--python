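"""Shared fixtures: the packaged parameter set, one full-size baseline run
(reused by every test that inspects national results), and a synthetic
survey fixture sized for the scenario pathway."""

from __future__ import annotations

import numpy as np
import pytest

from ironburden import burden, load_parameters, synthetic_data

#: Seed for the shared full-size run; individual tests needing their own
#: randomness derive generators locally.
BASELINE_SEED = 1


@pytest.fixture(scope="session")
def params():
    return load_parameters()


@pytest.fixture(scope="session")
def baseline(params):
    """Full-size national pipeline run: 1000 uncertainty x 10,000 variability."""
    return burden.run_baseline(params, n_unc=1000, n_var=10_000, seed=BASELINE_SEED)


@pytest.fixture(scope="session")
def fixture_bundle():
    """(records, parameter_set) synthetic survey bundle, 2000 people/stratum."""
    return synthetic_data.end_to_end_fixture(seed=0, n_per_stratum=2000)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
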