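"""Dominance index per animal, on full logs and on expanding time windows.

The dominance index of a focal animal combines how much it fights, how often
it wins, and against how many *distinct* pen mates it wins or loses::

    DI = (wins * P_won - defeats * P_lost) / ((wins + defeats) * (n - 1))

where ``wins``/``defeats`` count fights, ``P_won`` is the number of distinct
pen mates the focal animal beat at least once, ``P_lost`` the number of
distinct pen mates that beat it at least once, and ``n`` is the group size.
DI ranges from -1 (absolute submissive: lost to every pen mate, never won)
to +1 (absolute dominant: beat every pen mate, never lost).  An animal with
no fights at all has no DI — the index is undefined, never zero-filled,
and undefined animals are reported separately.

Temporal stability is assessed on *expanding windows*: DI is recomputed on
the records of the first 1, 2, ... T cumulative observed hours after mixing,
so each window nests the previous one.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .interaction_io import AnimalId, InteractionRecord, PenRoster
from .significance import Dataset

__all__ = [
    "DominanceScore",
    "dominance_index",
    "score_dataset",
    "score_series",
    "expanding_windows",
    "di_histogram",
    "scores_frame",
]


@dataclass(frozen=True)
class DominanceScore:
    """DI of one animal in one data set over one time window.

    ``di`` is ``None`` when the animal had no retained fight in the window.
    """

    animal: AnimalId
    dataset: str
    window_hours: float
    wins: int
    defeats: int
    p_won: int
    p_lost: int
    group_size_n: int
    di: float | None


def dominance_index(
    wins: int, defeats: int, p_won: int, p_lost: int, group_size_n: int
) -> float | None:
    """Evaluate the dominance index; ``None`` when the animal never fought.

    Raises on internally inconsistent counts (an animal cannot have beaten a
    distinct opponent without a win, nor more distinct opponents than fights
    or pen mates).
    """
    if group_size_n < 2:
        raise ValueError("group size must be >= 2")
    for name, v in (("wins", wins), ("defeats", defeats), ("p_won", p_won), ("p_lost", p_lost)):
        if v < 0:
            raise ValueError(f"{name} must be >= 0")
    if (p_won > 0 and wins == 0) or (p_lost > 0 and defeats == 0):
        raise ValueError("distinct-opponent counts without matching fights")
    if (p_won == 0 and wins > 0) or (p_lost == 0 and defeats > 0):
        raise ValueError("fights without matching distinct-opponent counts")
    if p_won > min(wins, group_size_n - 1) or p_lost > min(defeats, group_size_n - 1):
        raise ValueError("distinct opponents exceed fights or pen mates")
    total = wins + defeats
    if total == 0:
        return None
    return (wins * p_won - defeats * p_lost) / (total * (group_size_n - 1))


def _tally(
    records: Iterable[InteractionRecord], max_hour: float | None
) -> dict[AnimalId, dict[str, object]]:
    """Per-animal win/defeat counts and distinct opponents, window-restricted."""
    acc: dict[AnimalId, dict[str, object]] = {}

    def slot(a: AnimalId) -> dict[str, object]:
        return acc.setdefault(a, {"wins": 0, "defeats": 0, "beat": set(), "lost_to": set()})

    for r in records:
        if max_hour is not None and not r.observed_hour < max_hour:
            continue
        w, l = slot(r.winner), slot(r.loser)
        w["wins"] += 1  # type: ignore[operator]
        w["beat"].add(r.loser)  # type: ignore[union-attr]
        l["defeats"] += 1  # type: ignore[operator]
        l["lost_to"].add(r.winner)  # type: ignore[union-attr]
    return acc


def score_dataset(
    dataset: Dataset,
    rosters: Mapping[str, PenRoster],
    window_hours: float | None = None,
) -> list[DominanceScore]:
    """DI for every animal in every pen the data set retains.

    Counts come exclusively from the data set's own records (for PEN/DYAD:
    fights of significant dyads only) with ``observed_hour < window_hours``.
    The group size in the denominator is the original pen size, regardless of
    how many animals keep fights in the subset.  Animals with no retained
    fight get an undefined DI.
    """
    acc = _tally(dataset.records, window_hours)
    label_hours = window_hours if window_hours is not None else math.inf
    scores: list[DominanceScore] = []
    for pen in dataset.pens:
        roster = rosters[pen]
        for animal in sorted(roster.animals):
            t = acc.get(animal)
            if t is None:
                scores.append(
                    DominanceScore(animal, dataset.label, label_hours, 0, 0, 0, 0,
                                   roster.group_size_n, None)
                )
                continue
            wins, defeats = int(t["wins"]), int(t["defeats"])
            p_won, p_lost = len(t["beat"]), len(t["lost_to"])
            di = dominance_index(wins, defeats, p_won, p_lost, roster.group_size_n)
            scores.append(
                DominanceScore(animal, dataset.label, label_hours, wins, defeats,
                               p_won, p_lost, roster.group_size_n, di)
            )
    return scores


def expanding_windows(total_hours: float, step: float = 1.0) -> list[float]:
    """Window end points ``step, 2*step, ...`` up to and including the full period."""
    if step <= 0:
        raise ValueError("step must be > 0")
    ends = [round(k * step, 9) for k in range(1, int(math.floor(total_hours / step)) + 1)]
    if not ends or ends[-1] < total_hours:
        ends.append(float(total_hours))
    return ends


def score_series(
    dataset: Dataset,
    rosters: Mapping[str, PenRoster],
    windows: Sequence[float],
) -> list[DominanceScore]:
    """Scores for every expanding window, concatenated."""
    out: list[DominanceScore] = []
    for end in windows:
        out.extend(score_dataset(dataset, rosters, window_hours=end))
    return out


def di_histogram(
    scores: Sequence[DominanceScore], bin_width: float = 0.1
) -> tuple[pd.DataFrame, int]:
    """Frequency table of defined DIs over [-1, 1], plus the undefined count.

    Bins are left-closed with the last bin closed on both sides; when
    ``bin_width`` does not divide the range evenly the final bin is narrower.
    Undefined scores are never binned.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    values = np.array([s.di for s in scores if s.di is not None], dtype=float)
    n_undefined = sum(1 for s in scores if s.di is None)
    edges = np.arange(-1.0, 1.0, bin_width)
    edges = np.append(edges, 1.0)
    counts, _ = np.histogram(values, bins=edges)
    table = pd.DataFrame(
        {"bin_left": edges[:-1], "bin_right": edges[1:], "count": counts}
    )
    return table, n_undefined


def scores_frame(scores: Iterable[DominanceScore]) -> pd.DataFrame:
    rows = [
        {
            "pen": s.animal.pen,
            "animal": s.animal.tag,
            "dataset": s.dataset,
            "window_hours": s.window_hours,
            "wins": s.wins,
            "defeats": s.defeats,
            "p_won": s.p_won,
            "p_lost": s.p_lost,
            "di": s.di if s.di is not None else np.nan,
        }
        for s in scores
    ]
    return pd.DataFrame(
        rows,
        columns=["pen", "animal", "dataset", "window_hours",
                 "wins", "defeats", "p_won", "p_lost", "di"],
    )
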