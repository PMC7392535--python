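from datetime import date

import pytest
from hypothesis import HealthCheck, settings

from griefwatch import default_config, simulate_stream
from griefwatch.synthetic import (
    EventSeed,
    NoiseConfig,
    StreamConfig,
    TerritoryConfig,
)

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=60,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def small_stream_config(seed: int = 3) -> StreamConfig:
    """Three territories over eight months, two injected deaths, light noise.

    Small enough for fast unit tests, rich enough to exercise bursts,
    retweets, duplicates and every irrelevant-noise class.
    """
    territories = (
        TerritoryConfig("alpha", 0.5, ("alpha", "alphagang", "alp")),
        TerritoryConfig("bravo", 1.0, ("bravo", "bravoblock", "brv")),
        TerritoryConfig("cedar", 0.3, ("cedar", "cedargang", "cdr")),
    )
    events = (
        EventSeed(
            person_id="marco",
            aliases=("marco", "lil marco"),
            death_date=date(2012, 3, 10),
            territory_id="alpha",
            burst_magnitude=15.0,
        ),
        EventSeed(
            person_id="dre",
            aliases=("dre",),
            death_date=date(2012, 5, 20),
            territory_id="bravo",
            burst_magnitude=25.0,  # >= 20x the 1.0/day baseline
        ),
    )
    return StreamConfig(
        start=date(2012, 1, 1),
        end=date(2012, 8, 31),
        territories=territories,
        events=events,
        noise=NoiseConfig(),
        seed=seed,
    )


@pytest.fixture(scope="session")
def small_bundle():
    return simulate_stream(small_stream_config(seed=3))


@pytest.fixture(scope="session")
def default_bundle():
    """The full study-conditions stream, shared across tests (seed 7)."""
    return simulate_stream(default_config(seed=7))
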