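import numpy as np
import pytest

import sfcoupling as sf
from sfcoupling.datatypes import AnalysisConfig
from sfcoupling.simulate import SimulationParams, generate_cohort


@pytest.fixture(scope="session")
def small_params() -> SimulationParams:
    """A small but non-trivial study design used across tests."""
    return SimulationParams(
        n_nodes=30, n_hc=6, n_vci=7, n_timepoints=100, backbone_k=6, seed=1234
    )


@pytest.fixture(scope="session")
def small_cohort(small_params):
    cohort, truth = generate_cohort(small_params)
    return cohort, truth


@pytest.fixture(scope="session")
def small_config() -> AnalysisConfig:
    return AnalysisConfig(
        null_count=10, permutations=200, min_coupling_pairs=3,
        sparsity_grid=(0.05, 0.40, 0.05), seed=99,
    )


@pytest.fixture(scope="session")
def fitted_small_study(small_cohort, small_config):
    cohort, truth = small_cohort
    study = sf.CouplingStudy(cohort, small_config, ground_truth=truth)
    return study.fit()
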