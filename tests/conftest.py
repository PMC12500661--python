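import pytest

from brmcda import nsclc_case_study, score_alternatives


@pytest.fixture(scope="session")
def case():
    """Packaged NSCLC combination-therapy reference model."""
    return nsclc_case_study()


@pytest.fixture(scope="session")
def computed_matrix(case):
    """Preference matrix computed from the reference pooled estimates."""
    return score_alternatives(case.pooled, case.tree)
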