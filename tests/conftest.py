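import pytest

from splicestrat import simulate, splicing
from splicestrat.io import Patient


@pytest.fixture(scope="session")
def default_cohort():
    """Default-configuration synthetic cohort at seed 1, shared read-only."""
    return simulate.simulate_cohort(seed=1)


@pytest.fixture(scope="session")
def default_psi_matrix(default_cohort):
    return splicing.build_psi_matrix(default_cohort.psi, default_cohort.annotation)


@pytest.fixture(scope="session")
def default_labels(default_cohort, default_psi_matrix):
    css = splicing.compute_css(default_psi_matrix)
    return splicing.classify_patients(css["css"], default_cohort.metadata)


@pytest.fixture
def tiny_metadata():
    return [
        Patient("N1", "neuro-normal", "none", False, "F"),
        Patient("N2", "neuro-normal", "none", False, "M"),
        Patient("S1", "ALS", "SOD1", False, "F"),
        Patient("P1", "ALS", "none", False, "M"),
        Patient("P2", "ALS-FTD", "none", True, "F"),
        Patient("P3", "FTD-MND", "none", True, "M"),
        Patient("C1", "ALS", "C9", False, "F"),
    ]
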