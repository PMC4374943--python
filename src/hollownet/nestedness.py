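"""NODF and WNODF nestedness estimators.

Nestedness is the pattern in which specialists interact with proper subsets
of the partners of generalists.  NODF (nestedness based on overlap and
decreasing fill) scores every pair of rows and every pair of columns: a
pair contributes only when the "heavier" member has strictly larger fill
(marginal total for the weighted variant), in which case the contribution
is the percentage of the lighter member's presences that overlap (NODF) or
are strictly smaller than the heavier member's counts (WNODF).  The total
is the mean over all C(S_rows,2) + C(S_cols,2) pairs, on a 0-100 scale.

Ties never count: pairs with equal fill (NODF) or equal marginal totals
(WNODF) contribute zero, per the published estimator definitions.  Both
statistics are therefore invariant under row/column permutation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .matrix import AbundanceMatrix, DegenerateNetworkError


@dataclass(frozen=True)
class NestednessValue:
    """Nestedness score with its row/column decomposition.

    ``total`` is the mean pairwise contribution over all row pairs and
    column pairs (0-100).  ``row_component``/``col_component`` are the means
    restricted to row pairs and column pairs (``nan`` when an axis has a
    single node).
    """

    total: float
    row_component: float
    col_component: float
    pair_count: int

    def __float__(self) -> float:
        return self.total


def _pair_contributions_binary(b: np.ndarray) -> tuple[float, int]:
    """Sum of NODF contributions over ordered pairs of rows of ``b``.

    For rows (u, v) with fill(u) > fill(v) > 0 the contribution is
    100 * |ones of v also in u| / fill(v); all other pairs contribute 0.
    Returns (contribution sum, number of unordered pairs).
    """
    n = b.shape[0]
    if n < 2:
        return 0.0, 0
    fills = b.sum(axis=1)
    overlap = b @ b.T
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(fills[None, :] > 0, overlap / fills[None, :], 0.0)
    decreasing = fills[:, None] > fills[None, :]
    return float(100.0 * frac[decreasing].sum()), n * (n - 1) // 2


def _pair_contributions_weighted(w: np.ndarray) -> tuple[float, int]:
    """Sum of WNODF contributions over ordered pairs of rows of ``w``.

    For rows (u, v) with total(u) > total(v): contribution is
    100 * |cells of v that are > 0 and strictly < the matching cell of u|
    / (positive cells of v).
    """
    n = w.shape[0]
    if n < 2:
        return 0.0, 0
    totals = w.sum(axis=1)
    pos = np.count_nonzero(w, axis=1)
    lighter_pos = w[None, :, :] > 0
    strictly_less = w[None, :, :] < w[:, None, :]
    counts = (lighter_pos & strictly_less).sum(axis=2)
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(pos[None, :] > 0, counts / pos[None, :], 0.0)
    decreasing = totals[:, None] > totals[None, :]
    return float(100.0 * frac[decreasing].sum()), n * (n - 1) // 2


def _assemble(row_sum: float, row_pairs: int, col_sum: float, col_pairs: int) -> NestednessValue:
    pair_count = row_pairs + col_pairs
    if pair_count == 0:
        raise DegenerateNetworkError(
            "nestedness is undefined for a single-row AND single-column matrix"
        )
    return NestednessValue(
        total=(row_sum + col_sum) / pair_count,
        row_component=row_sum / row_pairs if row_pairs else float("nan"),
        col_component=col_sum / col_pairs if col_pairs else float("nan"),
        pair_count=pair_count,
    )


def nodf(b: AbundanceMatrix) -> NestednessValue:
    """Qualitative nestedness (NODF) of an incidence matrix.

    Abundance input is binarized first; the statistic only depends on which
    cells are positive.
    """
    mat = (np.asarray(b.values) > 0).astype(np.float64)
    row_sum, row_pairs = _pair_contributions_binary(mat)
    col_sum, col_pairs = _pair_contributions_binary(mat.T)
    return _assemble(row_sum, row_pairs, col_sum, col_pairs)


def wnodf(a: AbundanceMatrix) -> NestednessValue:
    """Quantitative nestedness (WNODF) of an abundance matrix.

    Counts strictly-smaller positive cells under strictly decreasing
    marginal totals; on a 0/1 matrix overlapping cells are always equal, so
    they never count.
    """
    mat = np.asarray(a.values, dtype=np.float64)
    row_sum, row_pairs = _pair_contributions_weighted(mat)
    col_sum, col_pairs = _pair_contributions_weighted(mat.T)
    return _assemble(row_sum, row_pairs, col_sum, col_pairs)
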