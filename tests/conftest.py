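import numpy as np
import pytest

from plasmalfq import simulate as sim


@pytest.fixture(scope="session")
def small_design():
    """A reduced cohort (fast) keeping the default temporal design."""
    return sim.CohortDesign(n_proteins=60, seed=20)


@pytest.fixture(scope="session")
def small_cohort(small_design):
    proteins = [f"P{i:03d}" for i in range(small_design.n_proteins)]
    tensor, truth = sim.simulate_abundance(small_design, proteins)
    return tensor, truth


@pytest.fixture(scope="session")
def default_cohort():
    """A full-size cohort at the default design (278 proteins, 6 fish, 10 days)."""
    design = sim.CohortDesign(seed=101)
    proteins = [f"P{i:03d}" for i in range(design.n_proteins)]
    tensor, truth = sim.simulate_abundance(design, proteins)
    return design, tensor, truth
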