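from datetime import date
from types import SimpleNamespace

import pytest
from hypothesis import HealthCheck, settings

from querytrends import (
    DiseaseQuery,
    EpidemicEvent,
    GrowthSpec,
    ReferenceQuery,
    Scenario,
    WeekId,
    aggregate,
    default_scenario,
    fit_trend,
    generate_logs,
    parse_pattern,
)

settings.register_profile(
    "suite", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def default_world():
    """The stock five-year scenario, generated once per session."""
    scenario = default_scenario()
    entries, truth = generate_logs(scenario)
    return SimpleNamespace(scenario=scenario, entries=entries, truth=truth)


@pytest.fixture(scope="session")
def default_pipeline(default_world):
    """Reference aggregation and fitted trend on the stock scenario."""
    scenario = default_world.scenario
    reference = aggregate(default_world.entries,
                          parse_pattern(scenario.reference.label),
                          gaps=scenario.gaps)
    model = fit_trend(reference)
    return SimpleNamespace(scenario=scenario, entries=default_world.entries,
                           truth=default_world.truth, reference=reference,
                           model=model)


@pytest.fixture()
def small_scenario():
    """A fast ~60-week world with one epidemic and a 5-week gap."""
    return Scenario(
        start_week=WeekId(2007, 1),
        n_weeks=60,
        growth=GrowthSpec("linear", 200.0, 400.0),
        volume_seasonality=0.2,
        reference=ReferenceQuery("herpes", 0.05),
        diseases=(
            DiseaseQuery(
                label="kräk", base_share=0.03, token_form="kräkningar",
                compound_forms=("kräksjuka", "projektilkräkningar"),
                phrase_forms=("kräkningar barn",),
                epidemics=(EpidemicEvent(WeekId(2008, 2), width=2.0, height=6.0),),
            ),
        ),
        gaps=((date(2007, 6, 4), date(2007, 7, 8)),),
        seed=77,
    )
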