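from datetime import datetime, timedelta

import pytest

from dyadrank.interaction_io import (
    AnimalId,
    InteractionRecord,
    PenRoster,
    preset_schedule,
)


@pytest.fixture(scope="session")
def piglet_schedule():
    """28 observed hours: 12:00-18:00 on day 1, then two 07:00-18:00 days."""
    return preset_schedule("weaned_piglet")


@pytest.fixture(scope="session")
def short_schedule():
    """17 observed hours: 12:00-18:00 on day 1 plus one 07:00-18:00 day."""
    return preset_schedule("gilt")


@pytest.fixture
def trio_roster():
    pen = "penA"
    animals = frozenset(AnimalId(pen, t) for t in ("a", "b", "c"))
    return PenRoster(pen, "weaned_piglet", animals)


def make_record(schedule, pen, winner_tag, loser_tag, hour=0.5, duration=10.0,
                initiator_is_winner=True):
    """Build a valid record at the given observed hour."""
    ts = schedule.timestamp_at(hour)
    winner = AnimalId(pen, winner_tag)
    loser = AnimalId(pen, loser_tag)
    initiator, receiver = (winner, loser) if initiator_is_winner else (loser, winner)
    return InteractionRecord(
        pen=pen,
        timestamp=ts,
        observed_hour=schedule.observed_hour_of(ts),
        initiator=initiator,
        receiver=receiver,
        winner=winner,
        loser=loser,
        duration_s=duration,
    )


@pytest.fixture
def record_factory(piglet_schedule):
    def factory(pen, winner, loser, hour=0.5, **kw):
        return make_record(piglet_schedule, pen, winner, loser, hour, **kw)

    return factory
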