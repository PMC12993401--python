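import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # makes oracles importable

from tremornet.cohort import CohortDesign, simulate_cohort
from tremornet.connectivity import SparsityGrid, binarize_stack, fc_matrix


@pytest.fixture(scope="session")
def tiny_design() -> CohortDesign:
    """Small planted-effect cohort used across tests (6 subjects, 48 ROIs)."""
    return CohortDesign(
        n_subjects=6,
        n_timepoints=80,
        n_rois=48,
        planted_partition=tuple(i // 8 for i in range(48)),
        hub_rois=(8, 9),
        seed=11,
    )


@pytest.fixture(scope="session")
def tiny_cohort(tiny_design):
    return simulate_cohort(tiny_design)


@pytest.fixture(scope="session")
def coarse_grid() -> SparsityGrid:
    return SparsityGrid(0.10, 0.40, 0.05)


@pytest.fixture(scope="session")
def example_stack(tiny_cohort, coarse_grid):
    return binarize_stack(fc_matrix(tiny_cohort[0]), coarse_grid)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
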