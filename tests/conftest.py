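import numpy as np
import pytest

from prevproj import demography, synthetic_data
from prevproj.demography import N_AGES, PopulationPyramid, SurvivalSchedule


@pytest.fixture(scope="session")
def fixture_bundle():
    """Base-year pyramid, survival slice and all ten rate schedules."""
    return synthetic_data.build_fixture_bundle()


@pytest.fixture(scope="session")
def le_increasing_world(fixture_bundle):
    """Projected pyramid + survival trajectory under the rising-LE variant."""
    pyramid0, survival0, rates = fixture_bundle
    assumptions = demography.ProjectionAssumptions(variant="le_increasing")
    schedule = demography.build_survival_trajectory(survival0.sr[:, :, 0], assumptions)
    pyramid = demography.project_population(pyramid0.K[:, :, 0], schedule, assumptions)
    return pyramid, schedule, rates, assumptions


@pytest.fixture
def flat_survival():
    """sr = 0.98 everywhere; a featureless but valid schedule."""
    return SurvivalSchedule.constant(np.full((N_AGES, 2), 0.98), 2018, 2060)


@pytest.fixture
def uniform_pyramid():
    """1000 persons in every age/gender cell, base year only."""
    return PopulationPyramid(np.full((N_AGES, 2), 1000.0), 2018)
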