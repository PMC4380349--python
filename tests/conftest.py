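import warnings

import numpy as np
import pytest

from tanfv import fit_tan, replica_counts_cohort


@pytest.fixture(scope="session")
def replica():
    """The deterministic 299-row count-matched cohort."""
    return replica_counts_cohort()


@pytest.fixture(scope="session")
def replica_model(replica):
    """Maximum-likelihood TAN fit of the replica cohort."""
    with warnings.catch_warnings():
        # sparse states (e.g. 6 smallest-size tumors) leave some parent
        # contexts unobserved at alpha=0; the uniform fill is expected
        warnings.simplefilter("ignore", UserWarning)
        return fit_tan(replica, alpha=0.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
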