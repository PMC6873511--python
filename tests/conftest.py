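import pytest
from hypothesis import settings

import varreclass as v

settings.register_profile("deterministic", derandomize=True, max_examples=50)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def reference_results() -> v.ReclassificationResults:
    """Full pipeline run on the deterministic reference dataset.

    Session-scoped: building the ~576k-record fixture and fitting takes a
    few seconds and several test modules read from the same result.
    """
    records = v.make_reference_fixture()
    return v.ReclassificationModel(records).fit()


@pytest.fixture(scope="session")
def reference_matrix(reference_results) -> v.TransitionMatrix:
    return reference_results.matrix
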