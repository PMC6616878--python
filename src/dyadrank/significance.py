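"""Significant-dyad determination and assembly of the ALL/PEN/DYAD data sets.

Whether one animal *dominates* another cannot be read off a raw win-loss
difference: a 1-0 dyad says almost nothing.  Two rules decide when a dyad's
win-loss asymmetry is statistically significant, both built on the exact
one-sided sign test (binomial with success probability 1/2, no normal
approximation):

**Dyad-individual limits.**  Each dyad is tested on its own.  With
``n_fights`` interactions, the statistic x is the win count of the member
with *fewer* wins; the dyad is significant iff ``x < x_max(n_fights)`` where
``x_max(n)`` is the smallest x with ``P(X <= x) >= alpha`` under
Binomial(n, 1/2).  At alpha = 0.05 the smallest significant configuration is
5 wins vs 0 defeats.

**Pen-individual limits.**  All interacting dyads of a pen contribute their
win-count differences ``wins_hi - wins_lo``; an order-statistic confidence
interval for the median difference yields a pen-specific limit, and a dyad is
significant iff its difference strictly exceeds that limit.  Because the
limit adapts to the pen's fighting frequency, significant dyads can be found
even in pens with few fights, where the rigid dyad-level rule cannot fire.

From the full clear-outcome log (data set ALL), the records of dyads passing
the pen rule form data set PEN, those passing the dyad rule form DYAD.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .dyads import DyadKey, DyadSummary, build_dyads
from .interaction_io import AnimalId, InteractionRecord, PenRoster

__all__ = [
    "DATASET_LABELS",
    "CriticalValueTable",
    "PenLimit",
    "SignificanceResult",
    "Dataset",
    "SignificanceAnalysis",
    "sign_test_p",
    "critical_value",
    "critical_value_table",
    "dyad_limit_test",
    "median_ci",
    "pen_limit",
    "pen_limit_test",
    "build_datasets",
    "dataset_summary",
    "significance_frame",
]

DATASET_LABELS = ("ALL", "PEN", "DYAD")

PenLimitMode = Literal["two_sided_upper", "one_sided_lower"]


# ---------------------------------------------------------------------------
# Exact one-sided sign test and critical values (dyad-individual limits)
# ---------------------------------------------------------------------------

def sign_test_p(x_lo: int, n_fights: int) -> float:
    """Exact lower-tail p-value of the one-sided sign test.

    ``P(X <= x_lo)`` for X ~ Binomial(n_fights, 1/2), computed with exact
    integer arithmetic (the cumulative binomial sum over 2**n), then rounded
    to float.  No normal approximation is ever used: the dyad sample sizes of
    interest are tiny (a handful of fights).

    Parameters
    ----------
    x_lo : int
        Win count of the dyad member with fewer wins, ``0 <= x_lo <= n_fights``.
    n_fights : int
        Total interactions of the dyad, ``>= 1``.
    """
    if n_fights < 1:
        raise ValueError(f"n_fights must be >= 1, got {n_fights}")
    if not 0 <= x_lo <= n_fights:
        raise ValueError(f"need 0 <= x_lo <= n_fights, got x_lo={x_lo}, n={n_fights}")
    total = sum(math.comb(n_fights, k) for k in range(x_lo + 1))
    return float(Fraction(total, 2**n_fights))


def critical_value(n_fights: int, alpha: float = 0.05) -> int:
    """Critical value x_max of the one-sided sign test.

    The smallest x with ``P(X <= x) >= alpha`` under Binomial(n_fights, 1/2),
    so that a dyad is significant iff its observed ``wins_lo`` is strictly
    below x_max (equivalently: the exact p-value of ``wins_lo`` is < alpha).
    ``x_max = 0`` means no outcome of that dyad size can be significant; at
    alpha = 0.05 this holds for every ``n_fights < 5``.
    """
    if n_fights < 1:
        raise ValueError(f"n_fights must be >= 1, got {n_fights}")
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    denom = 2**n_fights
    total = 0
    for x in range(n_fights + 1):
        total += math.comb(n_fights, x)
        if Fraction(total, denom) >= Fraction(alpha).limit_denominator(10**9):
            return x
    return n_fights  # unreachable: cdf reaches 1


@dataclass(frozen=True)
class CriticalValueTable:
    """Tabulated x_max per number of fights at one significance level."""

    alpha: float
    entries: Mapping[int, int]

    @classmethod
    def compute(cls, alpha: float = 0.05, n_max: int = 25) -> "CriticalValueTable":
        return cls(alpha, {n: critical_value(n, alpha) for n in range(1, n_max + 1)})

    def __getitem__(self, n_fights: int) -> int:
        if n_fights in self.entries:
            return self.entries[n_fights]
        return critical_value(n_fights, self.alpha)


def critical_value_table(alpha: float = 0.05, n_max: int = 25) -> CriticalValueTable:
    return CriticalValueTable.compute(alpha, n_max)


@dataclass(frozen=True)
class SignificanceResult:
    """Verdict on one dyad under one of the two rules.

    Under ``dyad_limit`` the threshold is x_max and the dyad is significant
    iff ``wins_lo < threshold``; under ``pen_limit`` the threshold is the
    pen's limit and the dyad is significant iff ``diff > threshold``.
    """

    key: DyadKey
    method: Literal["pen_limit", "dyad_limit"]
    n_fights: int
    wins_lo: int
    diff: int
    threshold: float
    significant: bool


def dyad_limit_test(dyad: DyadSummary, alpha: float = 0.05) -> SignificanceResult:
    """Test one dyad against its own exact sign-test critical value.

    Never-interacting dyads are never significant (there is nothing to test).
    """
    if dyad.n_fights == 0:
        return SignificanceResult(dyad.key, "dyad_limit", 0, 0, 0, 0.0, False)
    x_max = critical_value(dyad.n_fights, alpha)
    return SignificanceResult(
        dyad.key,
        "dyad_limit",
        dyad.n_fights,
        dyad.wins_lo,
        dyad.diff,
        float(x_max),
        dyad.wins_lo < x_max,
    )


# ---------------------------------------------------------------------------
# Order-statistic confidence interval for the median (pen-individual limits)
# ---------------------------------------------------------------------------

def _binom_cdf(x: int, n: int) -> float:
    if x < 0:
        return 0.0
    return float(Fraction(sum(math.comb(n, k) for k in range(x + 1)), 2**n))


def median_ci(
    diffs: Sequence[float],
    conf: float = 0.95,
    mode: PenLimitMode = "two_sided_upper",
) -> tuple[float, float]:
    """Distribution-free confidence interval for the median of ``diffs``.

    Sign-test (order-statistic) interval.  Because the achievable coverage of
    ``(X_(d), X_(n-d+1))`` is the discrete set ``1 - 2 P(X <= d-1)`` under
    Binomial(n, 1/2), the requested level is met by linear interpolation
    between the innermost interval covering at least ``conf`` and the next
    interval inside it (the interpolated interval of Hettmansperger and
    Sheather, as implemented in the sign-test routines of the R ecosystem).
    When even the full sample range cannot cover ``conf`` (small n), the
    endpoints are clamped to the sample minimum and maximum.

    ``mode='two_sided_upper'`` returns the two-sided interval;
    ``mode='one_sided_lower'`` returns ``(L, +inf)`` where L is the
    interpolated lower confidence bound of a one-sided interval at ``conf``.
    """
    x = np.sort(np.asarray(list(diffs), dtype=float))
    n = len(x)
    if n == 0:
        raise ValueError("median_ci needs at least one value")
    if not 0.0 < conf < 1.0:
        raise ValueError(f"conf must be in (0, 1), got {conf}")
    if n == 1:
        return (x[0], x[0]) if mode == "two_sided_upper" else (x[0], math.inf)

    if mode == "two_sided_upper":
        alpha = 1.0 - conf
        # largest d whose interval (X_(d), X_(n-d+1)) still covers >= conf
        loc = 1
        while _binom_cdf(loc, n) < alpha / 2.0:
            loc += 1
        # loc is now qbinom(alpha/2); the outer interval uses d = max(loc, 1)
        d = max(loc, 1)
        cov_outer = 1.0 - 2.0 * _binom_cdf(d - 1, n)
        if cov_outer < conf:
            return (x[0], x[-1])  # requested coverage unattainable: clamp
        cov_inner = 1.0 - 2.0 * _binom_cdf(d, n)
        if d + 1 > n - d:  # inner interval degenerate; keep the outer one
            return (x[d - 1], x[n - d])
        w = (conf - cov_inner) / (cov_outer - cov_inner)
        lower = (1.0 - w) * x[d] + w * x[d - 1]
        upper = (1.0 - w) * x[n - d - 1] + w * x[n - d]
        return (float(lower), float(upper))

    if mode == "one_sided_lower":
        # coverage of [X_(d), inf) is 1 - P(X <= d-1); interpolate on d
        if 1.0 - _binom_cdf(0, n) < conf:
            return (float(x[0]), math.inf)  # unattainable: clamp to minimum
        d = 1
        while d + 1 <= n and 1.0 - _binom_cdf(d, n) >= conf:
            d += 1
        cov_outer = 1.0 - _binom_cdf(d - 1, n)  # >= conf
        if d + 1 > n:
            return (float(x[d - 1]), math.inf)
        cov_inner = 1.0 - _binom_cdf(d, n)  # < conf
        w = (conf - cov_inner) / (cov_outer - cov_inner)
        lower = (1.0 - w) * x[d] + w * x[d - 1]
        return (float(lower), math.inf)

    raise ValueError(f"unknown mode {mode!r}")


@dataclass(frozen=True)
class PenLimit:
    """Pen-adaptive significance limit derived from the median-difference CI."""

    pen: str
    limit: float
    n_dyads_used: int
    ci: tuple[float, float]
    conf: float
    mode: PenLimitMode


def pen_limit(
    dyads: Sequence[DyadSummary],
    conf: float = 0.95,
    mode: PenLimitMode = "two_sided_upper",
    include_zero_diff_dyads: bool = False,
) -> PenLimit | None:
    """Compute one pen's significance limit from its dyad win differences.

    The sample entering the median CI holds the ``diff`` of every interacting
    dyad (``n_fights >= 1``); never-interacting dyads carry no fight
    information and are excluded unless ``include_zero_diff_dyads`` asks for
    their structural zeros.  The limit is the upper endpoint of the two-sided
    CI (default) or the lower endpoint of the one-sided interval.  Returns
    ``None`` when the pen has no usable dyads — such a pen has no limit and
    none of its dyads can be significant under this method.
    """
    if include_zero_diff_dyads:
        sample = [d.diff for d in dyads]
    else:
        sample = [d.diff for d in dyads if d.n_fights >= 1]
    if not sample:
        return None
    pens = {d.key.pen for d in dyads}
    if len(pens) != 1:
        raise ValueError(f"dyads from several pens: {sorted(pens)}")
    ci = median_ci(sample, conf=conf, mode=mode)
    limit = ci[1] if mode == "two_sided_upper" else ci[0]
    return PenLimit(pens.pop(), float(limit), len(sample), ci, conf, mode)


def pen_limit_test(dyad: DyadSummary, limit: PenLimit | None) -> SignificanceResult:
    """Significance of one dyad under its pen's limit: ``diff > limit``, strictly."""
    if limit is None:
        return SignificanceResult(
            dyad.key, "pen_limit", dyad.n_fights, dyad.wins_lo, dyad.diff, math.inf, False
        )
    return SignificanceResult(
        dyad.key,
        "pen_limit",
        dyad.n_fights,
        dyad.wins_lo,
        dyad.diff,
        limit.limit,
        dyad.n_fights >= 1 and dyad.diff > limit.limit,
    )


# ---------------------------------------------------------------------------
# Data sets ALL / PEN / DYAD
# ---------------------------------------------------------------------------

@dataclass
class Dataset:
    """Records retained by one rule, with its pen/animal bookkeeping.

    ``pens`` lists only pens with at least one retained interaction;
    ``animals`` is the full roster of those pens (an animal counts as "in"
    the data set when its pen is, even if none of its own fights survive).
    """

    label: str
    records: list[InteractionRecord]
    pens: list[str]
    animals: set[AnimalId]
    significant_keys: set[DyadKey] = field(default_factory=set)

    @property
    def n_interactions(self) -> int:
        return len(self.records)

    def per_pen_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {p: 0 for p in self.pens}
        for r in self.records:
            counts[r.pen] += 1
        return counts


@dataclass
class SignificanceAnalysis:
    """Full output of the dyad-significance stage for one mixing event."""

    datasets: dict[str, Dataset]
    dyads_by_pen: dict[str, list[DyadSummary]]
    pen_limits: dict[str, PenLimit | None]
    results: list[SignificanceResult]


def _make_dataset(
    label: str,
    records: Sequence[InteractionRecord],
    keys: set[DyadKey] | None,
    rosters: Mapping[str, PenRoster],
) -> Dataset:
    if keys is None:
        kept = list(records)
    else:
        kept = [r for r in records if DyadKey.of(r.winner, r.loser) in keys]
    pens = sorted({r.pen for r in kept})
    animals: set[AnimalId] = set()
    for p in pens:
        animals |= rosters[p].animals
    return Dataset(label, kept, pens, animals, keys or set())


def build_datasets(
    records: Sequence[InteractionRecord],
    rosters: Mapping[str, PenRoster],
    alpha: float = 0.05,
    conf: float = 0.95,
    pen_limit_mode: PenLimitMode = "two_sided_upper",
    include_zero_diff_dyads: bool = False,
) -> SignificanceAnalysis:
    """Run both significance rules and assemble the three data sets.

    ALL holds every clear-outcome record; PEN (DYAD) holds the records of
    dyads significant under the pen-individual (dyad-individual) rule.  Both
    subsets are subsets of ALL by construction.  A pen belongs to a data set
    only when at least one of its interactions is retained.
    """
    by_pen: dict[str, list[InteractionRecord]] = {}
    for r in records:
        by_pen.setdefault(r.pen, []).append(r)
    for pen in by_pen:
        if pen not in rosters:
            raise ValueError(f"records for pen {pen!r} but no roster")

    dyads_by_pen: dict[str, list[DyadSummary]] = {}
    pen_limits: dict[str, PenLimit | None] = {}
    results: list[SignificanceResult] = []
    sig_pen: set[DyadKey] = set()
    sig_dyad: set[DyadKey] = set()

    for pen in sorted(by_pen):
        dyads = build_dyads(by_pen[pen], rosters[pen])
        dyads_by_pen[pen] = dyads
        limit = pen_limit(
            dyads,
            conf=conf,
            mode=pen_limit_mode,
            include_zero_diff_dyads=include_zero_diff_dyads,
        )
        pen_limits[pen] = limit
        for d in dyads:
            rp = pen_limit_test(d, limit)
            rd = dyad_limit_test(d, alpha)
            results.extend((rp, rd))
            if rp.significant:
                sig_pen.add(d.key)
            if rd.significant:
                sig_dyad.add(d.key)

    datasets = {
        "ALL": _make_dataset("ALL", records, None, rosters),
        "PEN": _make_dataset("PEN", records, sig_pen, rosters),
        "DYAD": _make_dataset("DYAD", records, sig_dyad, rosters),
    }
    return SignificanceAnalysis(datasets, dyads_by_pen, pen_limits, results)


def dataset_summary(analysis: SignificanceAnalysis) -> pd.DataFrame:
    """Bookkeeping table per data set: pens, animals, interaction counts.

    One row per data set with the number of retained pens, the animals housed
    in them (mean and SD of animals per pen), and the interaction counts
    (total plus mean and SD per retained pen).
    """
    rows = []
    for label in DATASET_LABELS:
        ds = analysis.datasets[label]
        per_pen = list(ds.per_pen_counts().values())
        sizes = [len({a for a in ds.animals if a.pen == p}) for p in ds.pens]
        rows.append(
            {
                "dataset": label,
                "n_pens": len(ds.pens),
                "n_animals": len(ds.animals),
                "animals_per_pen_mean": float(np.mean(sizes)) if sizes else 0.0,
                "animals_per_pen_sd": float(np.std(sizes, ddof=1)) if len(sizes) > 1 else 0.0,
                "n_interactions": ds.n_interactions,
                "interactions_per_pen_mean": float(np.mean(per_pen)) if per_pen else 0.0,
                "interactions_per_pen_sd": float(np.std(per_pen, ddof=1)) if len(per_pen) > 1 else 0.0,
            }
        )
    return pd.DataFrame(rows)


def significance_frame(results: Iterable[SignificanceResult]) -> pd.DataFrame:
    rows = [
        {
            "pen": r.key.pen,
            "animal_a": r.key.a.tag,
            "animal_b": r.key.b.tag,
            "method": r.method,
            "n_fights": r.n_fights,
            "wins_lo": r.wins_lo,
            "diff": r.diff,
            "threshold": r.threshold,
            "significant": r.significant,
        }
        for r in results
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "pen", "animal_a", "animal_b", "method",
            "n_fights", "wins_lo", "diff", "threshold", "significant",
        ],
    )
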