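import numpy as np
import pytest

from crossepi.simulate import (CrossDesign, DefectModel, PenetranceSpec,
                               simulate_cohort, uniform_map)


@pytest.fixture(scope="session")
def sparse_map():
    """Sparse genome-wide panel, one marker every 21 Mb (1 cM = 2 Mb)."""
    return uniform_map(21.0, 0.5)


@pytest.fixture(scope="session")
def baseline_penetrance():
    """Single defect, no modifier loci: pure binomial risk for mutants."""
    return PenetranceSpec({"ASD": DefectModel(baseline=0.137)})


@pytest.fixture(scope="session")
def f2_cohort(sparse_map, baseline_penetrance):
    design = CrossDesign(strains=("B", "A"), generations=(("F2", 3000),))
    return simulate_cohort(design, sparse_map, baseline_penetrance, seed=101)


@pytest.fixture(scope="session")
def combined_cohort(baseline_penetrance):
    """F2 + F10 + F14 combined cohort on a dense panel."""
    design = CrossDesign(strains=("B", "F"),
                         generations=(("F2", 400), ("F10", 300), ("F14", 300)))
    return simulate_cohort(design, uniform_map(3.0, 0.5), baseline_penetrance,
                           seed=202)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
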