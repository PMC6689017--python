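"""Rank-rank hypergeometric overlap (RRHO) between two ranked gene lists.

Both lists cover the same gene universe and are ranked by -log10(p), most
significant first. For every pair of rank thresholds (i*step, j*step) the
overlap k between the two top lists is scored with the upper-tail
hypergeometric probability; the map holds -log10 of those probabilities,
with the origin at the most-significant corner. Only over-enrichment is
scored (every comparison here is of overlap strength), and no
multiple-testing correction is applied across the map — it is a display
statistic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import hypergeom

from .datatypes import ValidationError


@dataclass
class RRHOMap:
    matrix: np.ndarray  # -log10 enrichment p per rank-threshold pair
    step: int
    n_universe: int
    orientation: str = "origin=most-significant"


def rank_genes(pvals: dict[str, float]) -> list[str]:
    """Gene IDs ranked by descending -log10(p); ties by lexicographic ID."""
    return sorted(pvals, key=lambda g: (pvals[g], g))


def hypergeom_tail(k: int, n1: int, n2: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, n1, n2) (exact upper tail)."""
    if not (0 <= k <= min(n1, n2) <= N) or max(n1, n2) > N:
        raise ValidationError(f"infeasible hypergeometric arguments k={k}, "
                              f"n1={n1}, n2={n2}, N={N}")
    if k == 0:
        return 1.0
    return float(hypergeom.sf(k - 1, N, n1, n2))


def rrho_map(ranking1: list[str], ranking2: list[str],
             step: int | None = None) -> RRHOMap:
    """Threshold-free overlap map of two rankings of the same universe.

    Overlap counts for all threshold pairs are accumulated incrementally
    (2-D cumulative count of joint rank positions), so the cost is
    O(N^2/step^2 + N) rather than repeated set intersections.
    """
    if set(ranking1) != set(ranking2) or len(ranking1) != len(set(ranking1)):
        raise ValidationError("rankings must be permutations of one universe")
    N = len(ranking1)
    if step is None:
        step = max(1, N // 100)
    n_thresh = int(np.ceil(N / step))
    pos2 = {g: i for i, g in enumerate(ranking2)}
    # joint histogram of (rank1 bin, rank2 bin), then 2-D cumulative sum
    hist = np.zeros((n_thresh, n_thresh), dtype=int)
    for i1, g in enumerate(ranking1):
        hist[i1 // step, pos2[g] // step] += 1
    cum = hist.cumsum(axis=0).cumsum(axis=1)
    thresholds = np.minimum((np.arange(1, n_thresh + 1)) * step, N)
    mat = np.empty((n_thresh, n_thresh))
    sf = hypergeom.sf
    for i in range(n_thresh):
        n1 = int(thresholds[i])
        k = cum[i]  # overlap counts for every column threshold
        p = sf(k - 1, N, n1, thresholds)
        p = np.where(k == 0, 1.0, p)
        mat[i] = -np.log10(np.maximum(p, np.finfo(float).tiny))
    return RRHOMap(matrix=mat, step=step, n_universe=N)
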