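"""Data model, tabular I/O and observation-time handling for agonistic-interaction logs.

An *agonistic interaction* is a fight or displacement between exactly two
identified animals in one pen, with a clear initiator, receiver, winner and
loser.  Logs are kept as flat tables (CSV, one row per fight) next to a pen
roster table mapping each pen to its animals and age group.

Because pens are observed on a daytime schedule with an overnight gap
(recording pauses 18:00–07:00), wall-clock timestamps are not a useful time
axis for within-group dynamics.  Every record therefore carries an
``observed_hour``: the cumulative hours of *observation* elapsed since mixing,
with unobserved gaps excised.  The observed hour is always derived from the
timestamp and the :class:`ObservationSchedule`; a value present in an input
file is never trusted.

Input rows that violate the record invariants are not silently dropped: they
are routed to a reject report with machine-readable reason codes so the
record filter is auditable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, datetime, timedelta
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "AGE_GROUPS",
    "AnimalId",
    "PenRoster",
    "ObservationSchedule",
    "InteractionRecord",
    "ReadResult",
    "FilterResult",
    "FormatError",
    "ValidationError",
    "ScheduleError",
    "daily_schedule",
    "preset_schedule",
    "read_roster",
    "write_roster",
    "read_interactions",
    "write_interactions",
    "filter_clear_outcomes",
    "records_frame",
]

AGE_GROUPS = ("weaned_piglet", "fattening_pig", "gilt")

#: Hours of analysed observation per age group (mixing at 12:00, overnight gap
#: 18:00-07:00; piglets are followed for two and a half days, older groups for
#: one and a half).
OBSERVATION_HOURS = {"weaned_piglet": 28.0, "fattening_pig": 17.0, "gilt": 17.0}

INTERACTION_COLUMNS = (
    "pen",
    "timestamp",
    "initiator",
    "receiver",
    "winner",
    "loser",
    "duration_s",
)
ROSTER_COLUMNS = ("pen", "age_group", "tag")

#: Default mixing day used when a schedule is built without an explicit date.
DEFAULT_MIXING_DAY = date(2019, 3, 4)

#: Values in a participant field that mark an unidentified animal.
_AMBIGUOUS = {"", "?", "unknown", "unclear", "na", "nan", "none"}
#: Separators that mark several animals crammed into one participant field
#: (a melee involving more than two animals).
_MULTI_SEPARATORS = ("+", ";", "|")


class FormatError(ValueError):
    """The input table is structurally unusable (e.g. a required column is missing)."""


class ValidationError(ValueError):
    """A row violates a record invariant and strict reading was requested."""


class ScheduleError(ValueError):
    """A timestamp or observed hour falls outside the observation schedule."""


@dataclass(frozen=True, order=True)
class AnimalId:
    """Identity of one animal: the pen label plus the tag painted on its back.

    Pen labels are expected to be globally unique across batches (a batch
    prefix folded into the label), so ``(pen, tag)`` identifies an animal
    study-wide while ``tag`` alone identifies it within its pen.
    """

    pen: str
    tag: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.pen}/{self.tag}"


@dataclass(frozen=True)
class PenRoster:
    """All animals housed together in one pen after a mixing event."""

    pen: str
    age_group: str
    animals: frozenset[AnimalId]

    def __post_init__(self) -> None:
        if self.age_group not in AGE_GROUPS:
            raise ValueError(f"unknown age group {self.age_group!r}")
        if len(self.animals) < 2:
            raise ValueError(f"pen {self.pen!r} needs at least 2 animals")
        for a in self.animals:
            if a.pen != self.pen:
                raise ValueError(f"animal {a} does not belong to pen {self.pen!r}")

    @property
    def group_size_n(self) -> int:
        """Group size *n*, the normaliser of the dominance index."""
        return len(self.animals)

    def tags(self) -> list[str]:
        return sorted(a.tag for a in self.animals)

    def __contains__(self, animal: AnimalId) -> bool:
        return animal in self.animals


@dataclass(frozen=True)
class ObservationSchedule:
    """Ordered, non-overlapping wall-clock windows during which pens are observed.

    Windows are half-open ``[start, end)`` for record membership, so a fight
    logged exactly at a window's end does not belong to it.  The cumulative
    observed-hour map is continuous: evaluating it exactly at a window end
    gives the same value as at the next window's start.
    """

    windows: tuple[tuple[datetime, datetime], ...]

    def __post_init__(self) -> None:
        if not self.windows:
            raise ValueError("schedule needs at least one window")
        prev_end = None
        for start, end in self.windows:
            if end <= start:
                raise ValueError(f"empty or reversed window {start}..{end}")
            if prev_end is not None and start < prev_end:
                raise ValueError("windows overlap or are unordered")
            prev_end = end

    @property
    def start(self) -> datetime:
        return self.windows[0][0]

    @property
    def total_hours(self) -> float:
        """Total scheduled observation time, in hours."""
        return sum((e - s).total_seconds() for s, e in self.windows) / 3600.0

    def contains(self, ts: datetime) -> bool:
        """True iff ``ts`` lies inside an observation window (half-open)."""
        return any(s <= ts < e for s, e in self.windows)

    def observed_hour_of(self, ts: datetime) -> float:
        """Cumulative observed hours elapsed at wall-clock time ``ts``.

        Piecewise linear in ``ts``: 0 at the start of the first window,
        increasing at unit rate inside windows and flat across gaps.  Window
        boundaries are valid evaluation points; timestamps strictly inside a
        gap or outside the schedule raise :class:`ScheduleError`.
        """
        cum = 0.0
        for s, e in self.windows:
            if ts < s:
                break
            if ts <= e:
                return cum + (ts - s).total_seconds() / 3600.0
            cum += (e - s).total_seconds() / 3600.0
        raise ScheduleError(f"{ts.isoformat()} is outside every observation window")

    def timestamp_at(self, hours: float) -> datetime:
        """Inverse of :meth:`observed_hour_of` (gaps mapped to window starts)."""
        if hours < 0:
            raise ScheduleError(f"negative observed hour {hours}")
        cum = 0.0
        for i, (s, e) in enumerate(self.windows):
            w = (e - s).total_seconds() / 3600.0
            last = i == len(self.windows) - 1
            if hours < cum + w or (last and hours <= cum + w):
                return s + timedelta(hours=hours - cum)
            cum += w
        raise ScheduleError(f"observed hour {hours} exceeds schedule ({cum} h)")


def daily_schedule(
    windows_by_day: Sequence[tuple[int, float, float]],
    mixing_day: date = DEFAULT_MIXING_DAY,
) -> ObservationSchedule:
    """Build a schedule from ``(day_offset, start_hour, end_hour)`` triples.

    ``day_offset`` 0 is the mixing day; hours are wall-clock hours of that day.
    """
    windows = []
    for day, start_h, end_h in windows_by_day:
        base = datetime.combine(mixing_day + timedelta(days=day), datetime.min.time())
        windows.append((base + timedelta(hours=start_h), base + timedelta(hours=end_h)))
    return ObservationSchedule(tuple(windows))


def preset_schedule(
    age_group: str, mixing_day: date = DEFAULT_MIXING_DAY
) -> ObservationSchedule:
    """Observation schedule of one mixing event for the given age group.

    Mixing happens at 12:00 on day 1; recording pauses overnight from 18:00 to
    07:00.  Weaned piglets are followed for 28 observed hours
    (12:00-18:00, then two full 07:00-18:00 days); fattening pigs and gilts
    for 17 observed hours (12:00-18:00 plus one 07:00-18:00 day).
    """
    if age_group not in AGE_GROUPS:
        raise ValueError(f"unknown age group {age_group!r}")
    days = [(0, 12.0, 18.0), (1, 7.0, 18.0)]
    if age_group == "weaned_piglet":
        days.append((2, 7.0, 18.0))
    return daily_schedule(days, mixing_day)


@dataclass(frozen=True)
class InteractionRecord:
    """One clear-outcome fight between two identified pen mates.

    ``observed_hour`` is the cumulative observed time at which the fight was
    logged, derived from ``timestamp`` under the run's schedule.  The four
    role fields must name exactly two distinct animals of the record's pen:
    ``{winner, loser} == {initiator, receiver}``.
    """

    pen: str
    timestamp: datetime
    observed_hour: float
    initiator: AnimalId
    receiver: AnimalId
    winner: AnimalId
    loser: AnimalId
    duration_s: float

    def __post_init__(self) -> None:
        if self.initiator == self.receiver:
            raise ValueError("initiator and receiver must differ")
        if {self.winner, self.loser} != {self.initiator, self.receiver}:
            raise ValueError("winner/loser must be the initiator and receiver")
        for a in (self.initiator, self.receiver):
            if a.pen != self.pen:
                raise ValueError(f"animal {a} not from pen {self.pen!r}")
        if not self.duration_s > 1.0:
            raise ValueError("a fight lasts more than 1 s")
        if self.observed_hour < 0:
            raise ValueError("observed_hour must be >= 0")

    @property
    def pair(self) -> frozenset[AnimalId]:
        return frozenset((self.initiator, self.receiver))


@dataclass
class FilterResult:
    """Outcome of the clear-outcome filter on raw rows."""

    rows: pd.DataFrame
    n_removed: int
    removed: pd.DataFrame


@dataclass
class ReadResult:
    """Validated records plus the sidecar reject report."""

    records: list[InteractionRecord]
    rejects: pd.DataFrame  # columns: row, reason, detail


def _is_ambiguous(value: object) -> bool:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return True
    text = str(value).strip()
    if text.lower() in _AMBIGUOUS:
        return True
    return any(sep in text for sep in _MULTI_SEPARATORS)


def filter_clear_outcomes(rows: pd.DataFrame) -> FilterResult:
    """Keep only fights between two animals with all four roles resolved.

    A row survives iff initiator, receiver, winner and loser each name a
    single identified animal, the initiator differs from the receiver, and
    (when an ``n_animals`` column is present) exactly two animals were
    involved.  Rows removed here are fights the observers could not resolve —
    removal is reported, not an error.  The filter is idempotent.
    """
    roles = ["initiator", "receiver", "winner", "loser"]
    missing = [c for c in roles if c not in rows.columns]
    if missing:
        raise FormatError(f"missing required column(s): {', '.join(missing)}")
    keep = pd.Series(True, index=rows.index)
    for c in roles:
        keep &= ~rows[c].map(_is_ambiguous)
    keep &= rows["initiator"].astype(str) != rows["receiver"].astype(str)
    if "n_animals" in rows.columns:
        keep &= pd.to_numeric(rows["n_animals"], errors="coerce") == 2
    kept = rows.loc[keep].copy()
    removed = rows.loc[~keep].copy()
    return FilterResult(rows=kept, n_removed=len(removed), removed=removed)


def read_roster(path) -> dict[str, PenRoster]:
    """Read a roster CSV (``pen,age_group,tag``) into per-pen rosters."""
    df = pd.read_csv(path, dtype=str, sep=None, engine="python")
    missing = [c for c in ROSTER_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"roster: missing required column(s): {', '.join(missing)}")
    rosters: dict[str, PenRoster] = {}
    for pen, grp in df.groupby("pen", sort=True):
        ages = set(grp["age_group"])
        if len(ages) != 1:
            raise FormatError(f"pen {pen!r} has conflicting age groups {sorted(ages)}")
        animals = frozenset(AnimalId(str(pen), str(t)) for t in grp["tag"])
        if len(animals) != len(grp):
            raise FormatError(f"pen {pen!r} has duplicate tags")
        rosters[str(pen)] = PenRoster(str(pen), ages.pop(), animals)
    return rosters


def write_roster(rosters: Mapping[str, PenRoster], path) -> None:
    rows = [
        {"pen": r.pen, "age_group": r.age_group, "tag": tag}
        for r in rosters.values()
        for tag in r.tags()
    ]
    pd.DataFrame(rows, columns=list(ROSTER_COLUMNS)).to_csv(path, index=False)


def read_interactions(
    path,
    rosters: Mapping[str, PenRoster],
    schedule: ObservationSchedule,
    strict: bool = False,
) -> ReadResult:
    """Read, filter and validate an interaction log.

    The raw table is first passed through :func:`filter_clear_outcomes`
    (removed rows appear in the reject report with reason
    ``unclear_outcome``), then each surviving row is checked against the
    record invariants.  Violations are rejected with a reason code; with
    ``strict=True`` the first invariant violation raises instead.

    Raises
    ------
    FormatError
        If a required column is missing.
    ValidationError
        In strict mode, on the first rejected row.
    """
    df = pd.read_csv(path, dtype=str, sep=None, engine="python")
    missing = [c for c in INTERACTION_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"missing required column(s): {', '.join(missing)}")

    rejects: list[dict] = []

    def reject(idx, reason, detail):
        if strict:
            raise ValidationError(f"row {idx}: {reason}: {detail}")
        rejects.append({"row": idx, "reason": reason, "detail": detail})

    filt = filter_clear_outcomes(df)
    for idx in filt.removed.index:
        reject(int(idx), "unclear_outcome", "ambiguous participant or not a 2-animal fight")

    records: list[InteractionRecord] = []
    for idx, row in filt.rows.iterrows():
        pen = str(row["pen"])
        roster = rosters.get(pen)
        if roster is None:
            reject(int(idx), "unknown_pen", pen)
            continue
        try:
            ts = datetime.fromisoformat(str(row["timestamp"]))
        except ValueError:
            reject(int(idx), "bad_timestamp", str(row["timestamp"]))
            continue
        animals = {}
        bad = False
        for role in ("initiator", "receiver", "winner", "loser"):
            a = AnimalId(pen, str(row[role]).strip())
            if a not in roster:
                reject(int(idx), "unknown_animal", f"({a.pen}, {a.tag})")
                bad = True
                break
            animals[role] = a
        if bad:
            continue
        if {animals["winner"], animals["loser"]} != {animals["initiator"], animals["receiver"]}:
            reject(int(idx), "outcome_mismatch", "winner/loser not the two participants")
            continue
        try:
            duration = float(row["duration_s"])
        except (TypeError, ValueError):
            reject(int(idx), "bad_duration", str(row["duration_s"]))
            continue
        if not duration > 1.0:
            reject(int(idx), "duration_not_gt_1s", f"{duration}")
            continue
        if not schedule.contains(ts):
            reject(int(idx), "outside_observation_window", ts.isoformat())
            continue
        records.append(
            InteractionRecord(
                pen=pen,
                timestamp=ts,
                observed_hour=schedule.observed_hour_of(ts),
                initiator=animals["initiator"],
                receiver=animals["receiver"],
                winner=animals["winner"],
                loser=animals["loser"],
                duration_s=duration,
            )
        )
    reject_frame = pd.DataFrame(rejects, columns=["row", "reason", "detail"])
    return ReadResult(records=records, rejects=reject_frame)


def records_frame(records: Iterable[InteractionRecord]) -> pd.DataFrame:
    """Flatten records to the canonical interaction table (tags only)."""
    rows = [
        {
            "pen": r.pen,
            "timestamp": r.timestamp.isoformat(),
            "initiator": r.initiator.tag,
            "receiver": r.receiver.tag,
            "winner": r.winner.tag,
            "loser": r.loser.tag,
            "duration_s": r.duration_s,
        }
        for r in records
    ]
    return pd.DataFrame(rows, columns=list(INTERACTION_COLUMNS))


def write_interactions(records: Iterable[InteractionRecord], path) -> None:
    records_frame(records).to_csv(path, index=False)
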