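"""Directional win counts per dyad and the four-way dyad classification.

A dyad is an unordered pair of pen mates. Over an observation period each
dyad is either *unknown* (never interacted), *one-way* (one animal won every
fight), *two-way* (wins in both directions, one animal ahead) or *tied*
(wins in both directions, equal). The four categories partition all
n(n-1)/2 possible dyads of a pen, so their percentages sum to 100.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .interaction_io import AnimalId, InteractionRecord, PenRoster

__all__ = [
    "CATEGORIES",
    "DyadKey",
    "DyadSummary",
    "CategoryStats",
    "classify",
    "build_dyads",
    "category_stats",
    "category_summary",
    "dyads_frame",
]

CATEGORIES = ("unknown", "one_way", "two_way", "tied")


@dataclass(frozen=True, order=True)
class DyadKey:
    """Canonical identity of an unordered pair within one pen (a.tag < b.tag)."""

    pen: str
    a: AnimalId
    b: AnimalId

    @classmethod
    def of(cls, x: AnimalId, y: AnimalId) -> "DyadKey":
        if x.pen != y.pen:
            raise ValueError(f"cross-pen dyad {x} / {y}")
        if x.tag == y.tag:
            raise ValueError(f"dyad of {x} with itself")
        a, b = sorted((x, y), key=lambda t: t.tag)
        return cls(x.pen, a, b)


@dataclass(frozen=True)
class DyadSummary:
    """Directional win counts of one dyad.

    ``wins_a``/``wins_b`` follow the canonical animal order of the key;
    ``wins_hi``/``wins_lo`` are the order statistics the significance tests
    use: the lower count is the sign-test statistic x, the difference
    ``wins_hi - wins_lo`` feeds the pen-level limit.
    """

    key: DyadKey
    wins_a: int
    wins_b: int

    def __post_init__(self) -> None:
        if self.wins_a < 0 or self.wins_b < 0:
            raise ValueError("win counts must be non-negative")

    @property
    def n_fights(self) -> int:
        return self.wins_a + self.wins_b

    @property
    def wins_hi(self) -> int:
        return max(self.wins_a, self.wins_b)

    @property
    def wins_lo(self) -> int:
        return min(self.wins_a, self.wins_b)

    @property
    def diff(self) -> int:
        return self.wins_hi - self.wins_lo

    @property
    def category(self) -> str:
        return classify(self.wins_hi, self.wins_lo)


def classify(wins_hi: int, wins_lo: int) -> str:
    """Four-way dyad category from the ordered win counts.

    unknown: no fights; one_way: the same animal won everything;
    tied: equal nonzero counts; two_way: wins in both directions with one
    animal ahead. two_way and tied are disjoint, so the categories partition.
    """
    if wins_lo > wins_hi or wins_lo < 0:
        raise ValueError("need wins_hi >= wins_lo >= 0")
    if wins_hi == 0:
        return "unknown"
    if wins_lo == 0:
        return "one_way"
    if wins_lo == wins_hi:
        return "tied"
    return "two_way"


def build_dyads(
    records: Iterable[InteractionRecord], roster: PenRoster
) -> list[DyadSummary]:
    """Tally directional wins for every possible dyad of one pen.

    Returns exactly n(n-1)/2 summaries (never-interacting pairs included with
    zero counts), sorted by key. Total fights over dyads equals the record
    count.
    """
    counts: dict[DyadKey, dict[AnimalId, int]] = {
        DyadKey.of(x, y): {} for x, y in combinations(sorted(roster.animals), 2)
    }
    for r in records:
        if r.pen != roster.pen:
            raise ValueError(f"record from pen {r.pen!r} given roster {roster.pen!r}")
        for a in (r.winner, r.loser):
            if a not in roster:
                raise ValueError(f"animal {a} absent from roster of pen {roster.pen!r}")
        key = DyadKey.of(r.winner, r.loser)
        counts[key][r.winner] = counts[key].get(r.winner, 0) + 1
    return [
        DyadSummary(key, wins.get(key.a, 0), wins.get(key.b, 0))
        for key, wins in sorted(counts.items())
    ]


@dataclass(frozen=True)
class CategoryStats:
    """Per-pen category percentages over all possible dyads (sum to 100)."""

    pen: str
    n_possible: int
    pct_unknown: float
    pct_one_way: float
    pct_two_way: float
    pct_tied: float

    def as_dict(self) -> dict[str, float]:
        return {
            "unknown": self.pct_unknown,
            "one_way": self.pct_one_way,
            "two_way": self.pct_two_way,
            "tied": self.pct_tied,
        }


def category_stats(dyads: Sequence[DyadSummary]) -> CategoryStats:
    """Category percentages for the complete dyad set of one pen."""
    if not dyads:
        raise ValueError("empty dyad list")
    pens = {d.key.pen for d in dyads}
    if len(pens) != 1:
        raise ValueError(f"dyads from several pens: {sorted(pens)}")
    n = len(dyads)
    counts = {c: 0 for c in CATEGORIES}
    for d in dyads:
        counts[d.category] += 1
    pct = {c: 100.0 * counts[c] / n for c in CATEGORIES}
    return CategoryStats(pens.pop(), n, pct["unknown"], pct["one_way"], pct["two_way"], pct["tied"])


def category_summary(stats: Sequence[CategoryStats]) -> pd.DataFrame:
    """Across-pen mean and SD of the category percentages (pens are the units)."""
    if not stats:
        raise ValueError("no pens")
    data = {c: np.array([s.as_dict()[c] for s in stats]) for c in CATEGORIES}
    return pd.DataFrame(
        {
            "category": CATEGORIES,
            "mean_pct": [data[c].mean() for c in CATEGORIES],
            "sd_pct": [data[c].std(ddof=1) if len(stats) > 1 else 0.0 for c in CATEGORIES],
            "n_pens": len(stats),
        }
    )


def dyads_frame(dyads: Iterable[DyadSummary]) -> pd.DataFrame:
    rows = [
        {
            "pen": d.key.pen,
            "animal_a": d.key.a.tag,
            "animal_b": d.key.b.tag,
            "wins_a": d.wins_a,
            "wins_b": d.wins_b,
            "n_fights": d.n_fights,
            "diff": d.diff,
            "category": d.category,
        }
        for d in dyads
    ]
    return pd.DataFrame(
        rows,
        columns=["pen", "animal_a", "animal_b", "wins_a", "wins_b", "n_fights", "diff", "category"],
    )
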