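import pytest

from pedprs import make_preset, synthetic_lms_reference


@pytest.fixture(scope="session")
def lms_ref():
    return synthetic_lms_reference()


@pytest.fixture(scope="session")
def paper_cohort():
    """1046 subjects, 55 clean SNPs, planted effects +0.10 / -0.11."""
    return make_preset("paper_cohort", seed=11)


@pytest.fixture(scope="session")
def qc_stress():
    """85 candidate SNPs engineered to exercise every QC verdict."""
    return make_preset("qc_stress", seed=11)
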