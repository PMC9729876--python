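import numpy as np
import pytest

from mirdsd import BiomarkerPanel, CohortSpec, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """50-gene, 30v20 cohort with four planted markers (up: 0,1; down: 2,3)."""
    spec = CohortSpec(
        n_genes=50,
        n_case=30,
        n_control=20,
        planted_markers=((0, "up", 2.0), (1, "up", 1.5), (2, "down", 2.0), (3, "down", 1.5)),
        baseline_mu=4.0,
        sigma=0.5,
        seed=7,
    )
    return generate_cohort(spec)


@pytest.fixture
def four_input_panel():
    return BiomarkerPanel(
        positive=(("T1", 2.0), ("T2", 1.5)),
        negative=(("H1", -2.0), ("H2", -1.5)),
    )


@pytest.fixture
def sample_fpkm():
    return {"T1": 10.0, "T2": 8.0, "H1": 6.0, "H2": 4.0}
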