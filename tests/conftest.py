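import numpy as np
import pytest
from hypothesis import settings as _hypothesis_settings

_hypothesis_settings.register_profile("deterministic", derandomize=True, deadline=None)
_hypothesis_settings.load_profile("deterministic")

from kdpselect.kdp_model import ExperimentDesign
from kdpselect.objective import CaseStudyProblem
from kdpselect.synthetic_data import (
    GenerationProtocol,
    generate,
    nominal_parameters,
)


@pytest.fixture(scope="session")
def nominal():
    return nominal_parameters()


@pytest.fixture(scope="session")
def tiny_dataset():
    """One wild-strain experiment, five time points, 5% noise."""
    return generate(GenerationProtocol(
        seed=42, strains=("wild",), K_levels=(1.0,),
        t_grid=tuple(np.linspace(0.0, 1.0, 5)),
    ))


@pytest.fixture(scope="session")
def full_dataset():
    """The complete 2-strain × 5-K⁺-level protocol."""
    return generate(GenerationProtocol(seed=42))


@pytest.fixture(scope="session")
def noisefree_dataset():
    return generate(GenerationProtocol(seed=42, noise_level=0.0))


@pytest.fixture(scope="session")
def ident_dataset():
    """Both strains at two K⁺ levels — rich enough for a full-rank FIM."""
    return generate(GenerationProtocol(
        seed=13, strains=("wild", "mutant"), K_levels=(1.0, 50.0),
    ))


@pytest.fixture(scope="session")
def mutant_dataset():
    return generate(GenerationProtocol(seed=7, strains=("mutant",), K_levels=(10.0, 100.0)))


@pytest.fixture(scope="session")
def case_problem(full_dataset, nominal):
    return CaseStudyProblem(full_dataset, nominal[1])


@pytest.fixture
def wild_design():
    return ExperimentDesign("wild", 10.0, tuple(np.linspace(0.0, 1.0, 8)))


@pytest.fixture
def mutant_design():
    return ExperimentDesign("mutant", 10.0, tuple(np.linspace(0.0, 1.0, 8)))
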