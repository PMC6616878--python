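"""Cross-data-set and cross-group statistics.

Rank-order agreement between the ALL/PEN/DYAD dominance indices is tracked
with Spearman rank correlations on each expanding window (animals with an
undefined DI in either data set are excluded pairwise — an undefined index
is missing, not zero).  Group contrasts (age groups, data sets) use the
tie-corrected Kruskal-Wallis test with Dunn's post-hoc pairwise z tests on
mean ranks, multiplicity-adjusted.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .dominance import DominanceScore

__all__ = [
    "PairwiseResult",
    "GroupTestResult",
    "spearman_series",
    "kruskal_wallis",
    "dunn_posthoc",
]

MIN_COMMON_ANIMALS = 3


@dataclass(frozen=True)
class PairwiseResult:
    """One Dunn pairwise comparison on mean ranks."""

    group_a: str
    group_b: str
    z: float
    p: float
    adjusted_p: float


@dataclass(frozen=True)
class GroupTestResult:
    """Kruskal-Wallis omnibus result, optionally with Dunn pairwise follow-up."""

    statistic: float
    df: int
    p_value: float
    pairwise: tuple[PairwiseResult, ...] = ()


def spearman_series(
    scores_by_dataset: Mapping[str, Sequence[DominanceScore]],
    pairs: Sequence[tuple[str, str]] | None = None,
    min_n: int = MIN_COMMON_ANIMALS,
) -> pd.DataFrame:
    """Spearman r_s between data-set DIs, per expanding window and pair.

    Animals are pooled across pens; for each window only animals with a
    defined DI in *both* data sets of a pair enter, and windows with fewer
    than ``min_n`` such animals are omitted from the series.  Ties are
    handled with average ranks (the rank-then-Pearson convention).

    Returns a table with columns ``pair, window_hours, n_animals, r_s``.
    """
    labels = list(scores_by_dataset)
    if pairs is None:
        pairs = list(itertools.combinations(labels, 2))
    frames = {
        lab: {(s.animal, s.window_hours): s.di for s in scores}
        for lab, scores in scores_by_dataset.items()
    }
    windows = sorted({s.window_hours for ss in scores_by_dataset.values() for s in ss})
    rows = []
    for a, b in pairs:
        for w in windows:
            common = [
                (frames[a][k], frames[b][k])
                for k in frames[a]
                if k[1] == w and k in frames[b]
                and frames[a][k] is not None and frames[b][k] is not None
            ]
            if len(common) < min_n:
                continue
            xs, ys = zip(*common)
            if len(set(xs)) == 1 or len(set(ys)) == 1:
                continue  # constant vector: correlation undefined
            r = stats.spearmanr(xs, ys).statistic
            rows.append({"pair": f"{a}-{b}", "window_hours": w,
                         "n_animals": len(common), "r_s": float(r)})
    return pd.DataFrame(rows, columns=["pair", "window_hours", "n_animals", "r_s"])


def kruskal_wallis(samples: Sequence[Sequence[float]]) -> GroupTestResult:
    """Tie-corrected Kruskal-Wallis H with its chi-square p-value.

    The degenerate case of all observations identical across groups (which
    the rank test cannot distinguish) returns H = 0, p = 1.
    """
    if len(samples) < 2:
        raise ValueError("need at least 2 groups")
    if any(len(s) == 0 for s in samples):
        raise ValueError("every group must be non-empty")
    flat = np.concatenate([np.asarray(s, dtype=float) for s in samples])
    df = len(samples) - 1
    if np.all(flat == flat[0]):
        return GroupTestResult(0.0, df, 1.0)
    h, p = stats.kruskal(*samples)
    return GroupTestResult(float(h), df, float(p))


def dunn_posthoc(
    samples: Sequence[Sequence[float]],
    groups: Sequence[str] | None = None,
    adjustment: str = "bonferroni",
) -> tuple[PairwiseResult, ...]:
    """Dunn's pairwise z tests on mean ranks, with tie correction.

    For groups i, j with mean ranks R_i, R_j over the pooled sample of size N,

        z = (R_i - R_j) / sqrt((N(N+1)/12 - T) (1/n_i + 1/n_j)),
        T = sum(t^3 - t) / (12 (N - 1))  over tie groups of size t.

    Two-sided normal p-values are adjusted for the number of comparisons
    (``bonferroni``, ``holm`` or ``none``).
    """
    k = len(samples)
    if k < 2:
        raise ValueError("need at least 2 groups")
    if groups is None:
        groups = [f"group{i + 1}" for i in range(k)]
    if len(groups) != k:
        raise ValueError("one name per group required")
    sizes = np.array([len(s) for s in samples])
    if np.any(sizes == 0):
        raise ValueError("every group must be non-empty")
    pooled = np.concatenate([np.asarray(s, dtype=float) for s in samples])
    n_total = len(pooled)
    ranks = stats.rankdata(pooled)
    mean_ranks = []
    pos = 0
    for n in sizes:
        mean_ranks.append(ranks[pos:pos + n].mean())
        pos += n
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (12.0 * (n_total - 1))
    var_base = n_total * (n_total + 1) / 12.0 - tie_term

    raw: list[tuple[str, str, float, float]] = []
    for i, j in itertools.combinations(range(k), 2):
        se = math.sqrt(var_base * (1.0 / sizes[i] + 1.0 / sizes[j]))
        if se == 0.0:
            z = 0.0
        else:
            z = (mean_ranks[i] - mean_ranks[j]) / se
        p = 2.0 * stats.norm.sf(abs(z))
        raw.append((groups[i], groups[j], z, min(p, 1.0)))

    m = len(raw)
    if adjustment == "bonferroni":
        adj = [min(1.0, p * m) for *_, p in raw]
    elif adjustment == "holm":
        order = np.argsort([p for *_, p in raw])
        adj_arr = np.empty(m)
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, (m - rank) * raw[idx][3])
            adj_arr[idx] = min(1.0, running)
        adj = adj_arr.tolist()
    elif adjustment == "none":
        adj = [p for *_, p in raw]
    else:
        raise ValueError(f"unknown adjustment {adjustment!r}")

    return tuple(
        PairwiseResult(a, b, float(z), float(p), float(q))
        for (a, b, z, p), q in zip(raw, adj)
    )
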