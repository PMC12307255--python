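import math

import numpy as np
import pytest

from pahscape.grids import ConcentrationGrid
from pahscape.model import GaussianFit
from pahscape.pipeline import cluster_cohort, process_cohort
from pahscape.plates import ActivityLandscape
from pahscape.simulate import simulate_cohort, truth_surface

COHORT_SEED = 1


@pytest.fixture(scope="session")
def grid():
    return ConcentrationGrid()


@pytest.fixture(scope="session")
def canonical_truth():
    """A mid-activity surface peaking at the wild-type position."""
    return GaussianFit(50.0, math.log(330.0), math.log(101.0), 0.85, 0.9, True, 0.0)


@pytest.fixture(scope="session")
def noiseless_landscape(canonical_truth, grid):
    z = truth_surface(canonical_truth, grid, raw_units=False)
    return ActivityLandscape("G000", z, "percent_wt", grid)


@pytest.fixture(scope="session")
def cohort():
    """Default synthetic study cohort (99 genotypes, default noise)."""
    return simulate_cohort(seed=COHORT_SEED)


@pytest.fixture(scope="session")
def cohort_results(cohort):
    return process_cohort(cohort)


@pytest.fixture(scope="session")
def clustered(cohort_results):
    return cluster_cohort(cohort_results, seed=COHORT_SEED)


@pytest.fixture(scope="session")
def planted_labels(cohort):
    return dict(zip(cohort.truth.genotype_id, cohort.truth.label.astype(int)))
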