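"""Probabilistic priority ranking of determinants from posterior ATE draws.

Each posterior draw induces a complete ranking of the contrasts by absolute
effect size (rank 1 = largest |ATE|; absolute values acknowledge that effect
direction is a coding choice).  Aggregating over draws gives rank
probabilities, cumulative rank curves (rankograms), and the SUCRA summary

    SUCRA_i = sum_{r=1}^{n-1} P_{i,r} / (n - 1),
    E[rank_i] = n - (n - 1) * SUCRA_i,

where ``P_{i,r}`` is the probability that item ``i`` ranks ``r`` or better.
SUCRA is 1 for an item certain to rank first and 0 for one certain to rank
last.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError

__all__ = [
    "RankProfile",
    "rank_draws",
    "cumulative_rank_probs",
    "sucra",
    "rankogram_table",
]


@dataclass(frozen=True)
class RankProfile:
    """Rank and cumulative-rank probabilities for a set of ranked items."""

    items: tuple[tuple[str, str], ...]          # (variable, level) pairs
    rank_probs: np.ndarray = field(repr=False)  # (n_items, n_ranks)
    cumulative_probs: np.ndarray = field(repr=False)

    @property
    def n(self) -> int:
        return len(self.items)


def rank_draws(ate_matrix: np.ndarray) -> np.ndarray:
    """Rank items within each draw by absolute ATE (1 = largest magnitude).

    Ties break by item declaration order (first item wins); each row of the
    result is a permutation of 1..n.
    """
    a = np.asarray(ate_matrix, dtype=float)
    if a.ndim != 2 or a.shape[0] < 1 or a.shape[1] < 2:
        raise DataError("ate matrix must be draws x items with >=1 draw, >=2 items")
    if np.isnan(a).any():
        raise DataError("ate draws contain NaN")
    order = np.argsort(-np.abs(a), axis=1, kind="stable")
    ranks = np.empty_like(order)
    n = a.shape[1]
    rows = np.arange(a.shape[0])[:, None]
    ranks[rows, order] = np.arange(1, n + 1)[None, :]
    return ranks


def cumulative_rank_probs(
    ranks: np.ndarray, items: Sequence[tuple[str, str]]
) -> RankProfile:
    """Empirical rank probabilities and their cumulative sums over draws."""
    ranks = np.asarray(ranks)
    n = ranks.shape[1]
    if len(items) != n:
        raise DataError("item list length does not match rank matrix width")
    expected = np.arange(1, n + 1)
    if not np.array_equal(np.sort(ranks, axis=1), np.tile(expected, (ranks.shape[0], 1))):
        raise DataError("each draw's ranks must be a permutation of 1..n")
    probs = np.stack(
        [np.bincount(ranks[:, i] - 1, minlength=n) / ranks.shape[0] for i in range(n)]
    )
    return RankProfile(
        items=tuple(items),
        rank_probs=probs,
        cumulative_probs=np.cumsum(probs, axis=1),
    )


def sucra(profile: RankProfile) -> pd.DataFrame:
    """SUCRA and expected rank per item (unrounded).

    Satisfies the exact linear identity ``expected_rank = n - (n-1) * sucra``.
    """
    n = profile.n
    if n < 2:
        raise DataError("SUCRA needs at least two ranked items")
    partial = profile.cumulative_probs[:, : n - 1].sum(axis=1)
    s = partial / (n - 1)
    return pd.DataFrame(
        {
            "variable": [v for v, _ in profile.items],
            "level": [l for _, l in profile.items],
            "sucra": s,
            "expected_rank": n - partial,
        }
    )


def rankogram_table(
    profile: RankProfile, top_ranks: int = 4, min_prob: float = 0.25
) -> pd.DataFrame:
    """Long-format cumulative rank curve restricted to the leading ranks.

    Keeps only items whose cumulative probability at ``top_ranks`` reaches
    ``min_prob`` (``min_prob=0`` retains everything, giving the unfiltered
    rankogram).
    """
    if not (0.0 <= min_prob <= 1.0):
        raise ConfigError("min_prob must lie in [0, 1]")
    if top_ranks < 1 or top_ranks > profile.n:
        raise ConfigError("top_ranks must lie in 1..n")
    rows = []
    for i, (v, l) in enumerate(profile.items):
        if profile.cumulative_probs[i, top_ranks - 1] < min_prob:
            continue
        for r in range(1, top_ranks + 1):
            rows.append(
                {
                    "variable": v,
                    "level": l,
                    "rank": r,
                    "cumulative_prob": profile.cumulative_probs[i, r - 1],
                }
            )
    return pd.DataFrame(rows, columns=["variable", "level", "rank", "cumulative_prob"])
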