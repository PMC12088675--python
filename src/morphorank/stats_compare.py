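"""Ranking-comparison and distribution statistics.

Spearman correlation between two orderings of the same cells,
Freedman-Diaconis bin counts for Andrews-score histograms, and the
histogram overlapping coefficient used to compare two groups' score
distributions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "RankingComparison",
    "spearman",
    "rank_vector",
    "fd_bin_count",
    "score_overlap",
    "compare_rankings",
]


@dataclass(frozen=True)
class RankingComparison:
    """Spearman rho, per-cell rank differences and their FD histogram."""

    spearman_rho: float
    cell_ids: tuple[str, ...]
    rank_differences: np.ndarray
    bin_edges: np.ndarray
    histogram: np.ndarray


def rank_vector(order: Sequence[str]) -> dict[str, int]:
    """Map each id in an ordered sequence to its 1-based rank."""
    return {cid: i + 1 for i, cid in enumerate(order)}


def _ranks_from(arg: Sequence[str] | Mapping[str, float]) -> dict[str, float]:
    if isinstance(arg, Mapping):
        return {str(k): float(v) for k, v in arg.items()}
    return {str(k): float(v) for k, v in rank_vector(arg).items()}


def spearman(
    rank_a: Sequence[str] | Mapping[str, float],
    rank_b: Sequence[str] | Mapping[str, float],
) -> float:
    """Spearman rank correlation between two orderings of the same ids.

    Each argument is either an ordered id sequence (rank = position) or a
    mapping id -> rank/score; ties are handled by scipy's average ranks.
    """
    a = _ranks_from(rank_a)
    b = _ranks_from(rank_b)
    if set(a) != set(b):
        only_a = sorted(set(a) - set(b))[:5]
        only_b = sorted(set(b) - set(a))[:5]
        raise ValueError(
            f"rankings cover different ids (e.g. only in a: {only_a}, "
            f"only in b: {only_b})"
        )
    ids = sorted(a)
    rho = stats.spearmanr([a[i] for i in ids], [b[i] for i in ids]).statistic
    return float(rho)


def fd_bin_count(values: Sequence[float]) -> int:
    """Freedman-Diaconis histogram bin count.

    k = ceil((max - min) / (2 * IQR * N^(-1/3))); when the IQR is zero the
    square-root rule ceil(sqrt(N)) is used instead, with a warning.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 4:
        raise ValueError(f"need >= 4 values for FD binning, got {x.size}")
    iqr = float(np.subtract(*np.percentile(x, [75, 25])))
    if iqr <= 0:
        warnings.warn(
            "zero interquartile range; falling back to the square-root rule",
            stacklevel=2,
        )
        return int(np.ceil(np.sqrt(x.size)))
    k = (x.max() - x.min()) / (2.0 * iqr * x.size ** (-1.0 / 3.0))
    return max(1, int(np.ceil(k)))


def score_overlap(
    scores_a: Sequence[float], scores_b: Sequence[float]
) -> tuple[float, np.ndarray, np.ndarray, np.ndarray]:
    """Histogram overlapping coefficient of two score samples.

    Both samples are binned on shared Freedman-Diaconis bins spanning the
    pooled range; the coefficient is sum_i min(p_i, q_i) over the bins'
    proportions, 1 for identical binned distributions and 0 for disjoint
    supports.  Returns (coefficient, bin_edges, proportions_a,
    proportions_b).
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both score samples must be non-empty")
    pooled = np.concatenate([a, b])
    lo, hi = float(pooled.min()), float(pooled.max())
    if lo == hi:
        edges = np.array([lo - 0.5, hi + 0.5])
    else:
        k = fd_bin_count(pooled) if pooled.size >= 4 else int(np.ceil(np.sqrt(pooled.size)))
        edges = np.linspace(lo, hi, k + 1)
    pa = np.histogram(a, bins=edges)[0] / a.size
    pb = np.histogram(b, bins=edges)[0] / b.size
    return float(np.minimum(pa, pb).sum()), edges, pa, pb


def compare_rankings(
    order_a: Sequence[str], order_b: Sequence[str]
) -> RankingComparison:
    """Full comparison of two orderings: rho plus rank-difference histogram."""
    rho = spearman(order_a, order_b)
    ra = rank_vector(order_a)
    rb = rank_vector(order_b)
    ids = tuple(order_a)
    diffs = np.array([ra[i] - rb[i] for i in ids], dtype=int)
    if diffs.size >= 4 and np.subtract(*np.percentile(diffs, [75, 25])) != 0:
        k = fd_bin_count(diffs)
    else:
        k = max(1, int(np.ceil(np.sqrt(diffs.size))))
    hist, edges = np.histogram(diffs, bins=k)
    return RankingComparison(
        spearman_rho=rho,
        cell_ids=ids,
        rank_differences=diffs,
        bin_edges=edges,
        histogram=hist,
    )
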