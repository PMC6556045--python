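import numpy as np
import pytest

from roamcount import (
    RouteType,
    ScenarioConfig,
    SightingRecord,
    StudyDataset,
    ZoneSurvey,
    run_scenario,
)


def make_zone_survey(
    zone_id="Z01",
    survey_day=1,
    route_type=RouteType.ALL_ROADS,
    n_marked_initial=55,
    road_length_m=3881.0,
    buffer_area_m2=776_200.0,
    marked_flags=(),
    distances=None,
):
    """Build a ZoneSurvey with the given mark flags (and optional distances)."""
    if distances is None:
        distances = [5.0 * i for i in range(len(marked_flags))]
    sightings = [
        SightingRecord(
            zone_id=zone_id,
            survey_day=survey_day,
            route_type=route_type,
            marked=bool(mk),
            perp_distance_m=float(d),
        )
        for mk, d in zip(marked_flags, distances)
    ]
    return ZoneSurvey(
        zone_id=zone_id,
        survey_day=survey_day,
        route_type=route_type,
        n_marked_initial=n_marked_initial,
        road_length_m=road_length_m,
        buffer_area_m2=buffer_area_m2,
        sightings=sightings,
    )


@pytest.fixture
def small_zone():
    """Zone survey yielding the mark-resight counts (55, 23, 10)."""
    flags = [True] * 10 + [False] * 13
    return make_zone_survey(marked_flags=flags, distances=np.linspace(0, 30, 23))


@pytest.fixture(scope="session")
def simulated_study():
    """One full 26-zone simulated study with its truth table."""
    dataset, truth = run_scenario(ScenarioConfig(seed=20_240_101))
    return dataset, truth


@pytest.fixture
def tiny_dataset():
    zone = make_zone_survey(marked_flags=[True, False, True])
    return StudyDataset([zone])
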