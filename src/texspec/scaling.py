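"""Rank-data analysis: pairwise win matrices and Thurstone Case V scaling.

Observers rank the synthesis methods for each texture; each (observer,
item) ranking is unfolded into pairwise comparisons, giving a matrix of
win proportions. A method's quality score is the sum of the log-transformed
win proportions against the other methods (a Thurstone Case V variant),
additively normalized so the minimum score is 0; the classical probit
transform is available as an option. A Welch t statistic on per-observer
score vectors completes the pipeline.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import stats

__all__ = [
    "RankTable",
    "WinMatrix",
    "win_matrix",
    "thurstone_scale",
    "per_observer_scores",
    "welch_t",
]


@dataclass(frozen=True)
class RankTable:
    """Strict rankings: ``ranks[observer, item, method]`` in 1..n_methods.

    Every (observer, item) slice must be a permutation of 1..n_methods;
    rank 1 is the best. Ties are rejected.
    """

    ranks: np.ndarray
    methods: tuple[str, ...]

    def __post_init__(self) -> None:
        r = np.asarray(self.ranks)
        if r.ndim != 3:
            raise ValueError("ranks must be a 3D (observer, item, method) array")
        m = r.shape[2]
        if m < 2 or len(self.methods) != m:
            raise ValueError("need >= 2 methods and matching labels")
        expected = np.arange(1, m + 1)
        if not np.all(np.sort(r, axis=2) == expected):
            raise ValueError(
                "every (observer, item) slice must be a permutation of "
                f"1..{m} (tied or missing ranks are not allowed)"
            )

    @property
    def n_observers(self) -> int:
        return self.ranks.shape[0]

    @property
    def n_items(self) -> int:
        return self.ranks.shape[1]

    @classmethod
    def from_csv(cls, path: str | Path) -> "RankTable":
        """Read long-format CSV with columns observer, item, method, rank."""
        rows = []
        with open(path, newline="") as fh:
            for row in csv.DictReader(fh):
                rows.append(
                    (row["observer"], row["item"], row["method"], int(row["rank"]))
                )
        if not rows:
            raise ValueError(f"no rank rows in {path}")
        observers = sorted({r[0] for r in rows})
        items = sorted({r[1] for r in rows})
        methods = sorted({r[2] for r in rows})
        idx_o = {v: i for i, v in enumerate(observers)}
        idx_i = {v: i for i, v in enumerate(items)}
        idx_m = {v: i for i, v in enumerate(methods)}
        ranks = np.zeros((len(observers), len(items), len(methods)), dtype=int)
        for o, it, m, k in rows:
            ranks[idx_o[o], idx_i[it], idx_m[m]] = k
        return cls(ranks=ranks, methods=tuple(methods))

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["observer", "item", "method", "rank"])
            for o in range(self.n_observers):
                for i in range(self.n_items):
                    for m, name in enumerate(self.methods):
                        writer.writerow([o, i, name, int(self.ranks[o, i, m])])


@dataclass(frozen=True)
class WinMatrix:
    """Pairwise win proportions; ``p[i, j]`` is how often method i
    out-ranked method j over all (observer, item) cells. ``p[i, j] +
    p[j, i] == 1`` off the diagonal; the diagonal is 0.5 by convention."""

    p: np.ndarray
    n_comparisons: int
    methods: tuple[str, ...]


def win_matrix(ranks: RankTable) -> WinMatrix:
    """Unfold rankings into pairwise win proportions (lower rank wins)."""
    r = ranks.ranks
    m = r.shape[2]
    wins = (r[..., :, None] < r[..., None, :]).mean(axis=(0, 1))
    np.fill_diagonal(wins, 0.5)
    return WinMatrix(
        p=wins,
        n_comparisons=ranks.n_observers * ranks.n_items,
        methods=ranks.methods,
    )


def thurstone_scale(
    win: WinMatrix,
    clip: float | None = None,
    transform: str = "log",
) -> np.ndarray:
    """Quality scores from a win matrix, min-normalized to 0.

    ``transform='log'`` (default) sums the natural log of the win
    proportions against every other method; ``transform='probit'`` is the
    classical Case V solution, averaging the standard-normal quantiles of
    the win proportions. Proportions are floored at ``clip`` (default
    ``1/(2 * n_comparisons)``) so empty cells stay finite; scores are
    monotone in every win proportion.
    """
    p = np.asarray(win.p, dtype=float)
    m = p.shape[0]
    if clip is None:
        clip = 1.0 / (2.0 * max(win.n_comparisons, 1))
    off = ~np.eye(m, dtype=bool)
    if transform == "log":
        vals = np.log(np.maximum(p, clip))
    elif transform == "probit":
        vals = stats.norm.ppf(np.clip(p, clip, 1.0 - clip))
    else:
        raise ValueError(f"transform must be 'log' or 'probit', got {transform!r}")
    scores = np.where(off, vals, 0.0).sum(axis=1)
    if transform == "probit":
        scores = scores / (m - 1)
    return scores - scores.min()


def per_observer_scores(
    ranks: RankTable, clip: float | None = None, transform: str = "log"
) -> np.ndarray:
    """Thurstone scores computed separately for each observer.

    Returns an (n_observers, n_methods) array; the rows are the inputs to
    across-observer statistics such as :func:`welch_t`.
    """
    out = np.empty((ranks.n_observers, len(ranks.methods)))
    for o in range(ranks.n_observers):
        sub = RankTable(ranks=ranks.ranks[o : o + 1], methods=ranks.methods)
        out[o] = thurstone_scale(win_matrix(sub), clip=clip, transform=transform)
    return out


def welch_t(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Welch's unequal-variance t statistic and one-sided p (a > b)."""
    res = stats.ttest_ind(a, b, equal_var=False, alternative="greater")
    return float(res.statistic), float(res.pvalue)
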