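"""CE and RC null-matrix generators and the Monte-Carlo significance wrapper.

CE is the qualitative null: each cell of a replicate is an independent
Bernoulli draw whose probability is the average of the row's and the
column's occupancy proportion, so the chance of an interaction scales with
the generalization level of both the insect species and the tree hollow.
The ensemble conserves the expected fill exactly: sum_ij p_ij = L.

RC is the quantitative null: the m observed individuals are placed one at a
time into cells, drawing the row with probability proportional to the
observed row totals and the column proportionally to the observed column
totals, rejecting any draw whose row or column has already reached its
observed marginal total.  Every replicate therefore reproduces all row and
column totals (and the grand total) exactly.

Significance of any scalar matrix statistic is summarised by a
:class:`NullEnsemble` with the one-tailed add-one p-value
p = (#{null >= observed} + 1) / (n_rep + 1) and the z-score
(observed - mean(null)) / sd(null).  With 1000 replicates the smallest
attainable p is 1/1001, printed as 0.001.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Callable, Iterator

import numpy as np

from .matrix import AbundanceMatrix, IncidenceMatrix

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class NullEnsemble:
    """Observed statistic plus its Monte-Carlo null distribution."""

    statistic: str
    observed: float
    null_values: np.ndarray
    n_rep: int
    seed: int | None
    n_dropped: int = 0

    @property
    def p_value(self) -> float:
        """One-tailed (observed greater) add-one p-value."""
        n = len(self.null_values)
        return (int(np.sum(self.null_values >= self.observed)) + 1) / (n + 1)

    @property
    def z_score(self) -> float:
        mean = float(np.mean(self.null_values))
        sd = float(np.std(self.null_values, ddof=1)) if len(self.null_values) > 1 else 0.0
        if sd == 0.0:
            return float("nan")
        return (self.observed - mean) / sd

    def summary(self) -> dict:
        return {
            "statistic": self.statistic,
            "observed": self.observed,
            "p": self.p_value,
            "z": self.z_score,
            "null_mean": float(np.mean(self.null_values)),
            "null_sd": float(np.std(self.null_values, ddof=1)) if len(self.null_values) > 1 else 0.0,
            "n_rep": self.n_rep,
            "n_dropped": self.n_dropped,
            "seed": self.seed,
        }


def ce_probabilities(b: AbundanceMatrix) -> np.ndarray:
    """CE cell probabilities p_ij = (r_i/S_cols + c_j/S_rows) / 2.

    r_i is the number of occupied cells in row i, c_j in column j.  The
    analytic identity sum_ij p_ij = L makes the expected fill of the
    ensemble equal the observed fill.
    """
    binc = np.asarray(b.values) > 0
    n_rows, n_cols = binc.shape
    r = binc.sum(axis=1) / n_cols
    c = binc.sum(axis=0) / n_rows
    return 0.5 * (r[:, None] + c[None, :])


def ce_null(b: AbundanceMatrix, n_rep: int, seed: int | None = None) -> np.ndarray:
    """CE replicates as an (n_rep, S_rows, S_cols) 0/1 array.

    Replicates with empty rows or columns are retained, not resampled.
    """
    if n_rep < 1:
        raise ValueError("n_rep must be >= 1")
    p = ce_probabilities(b)
    rng = np.random.default_rng(seed)
    return (rng.random((n_rep, *p.shape)) < p[None, :, :]).astype(np.int8)


def _rc_one(row_tot: np.ndarray, col_tot: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One RC replicate by sequential proportional placement with rejection.

    Draws are made in batches; a batch prefix is valid up to (and
    including) the first draw that saturates some margin, because before
    that point no rejection can occur.  This is exactly the one-at-a-time
    process, vectorised.
    """
    n_rows, n_cols = len(row_tot), len(col_tot)
    out = np.zeros((n_rows, n_cols), dtype=np.int64)
    rem_r = row_tot.astype(np.int64).copy()
    rem_c = col_tot.astype(np.int64).copy()
    w_r = row_tot.astype(float)
    w_c = col_tot.astype(float)
    remaining = int(row_tot.sum())
    while remaining > 0:
        cum_r = np.cumsum(np.where(rem_r > 0, w_r, 0.0))
        cum_c = np.cumsum(np.where(rem_c > 0, w_c, 0.0))
        batch = remaining
        rows = np.searchsorted(cum_r, rng.random(batch) * cum_r[-1], side="right")
        cols = np.searchsorted(cum_c, rng.random(batch) * cum_c[-1], side="right")
        # first position at which some margin reaches zero remaining capacity
        take = batch
        counts_r = np.bincount(rows, minlength=n_rows)
        counts_c = np.bincount(cols, minlength=n_cols)
        for idx_arr, counts, rem in ((rows, counts_r, rem_r), (cols, counts_c, rem_c)):
            sat = np.flatnonzero((counts >= rem) & (rem > 0))
            if len(sat):
                order = np.argsort(idx_arr, kind="stable")
                starts = np.concatenate(([0], np.cumsum(counts)[:-1]))
                pos = order[starts[sat] + rem[sat] - 1]
                take = min(take, int(pos.min()) + 1)
        np.add.at(out, (rows[:take], cols[:take]), 1)
        rem_r -= np.bincount(rows[:take], minlength=n_rows)
        rem_c -= np.bincount(cols[:take], minlength=n_cols)
        remaining -= take
    return out


def rc_null(a: AbundanceMatrix, n_rep: int, seed: int | None = None) -> np.ndarray:
    """RC replicates as an (n_rep, S_rows, S_cols) integer array.

    Each replicate conserves every row total, every column total and the
    grand total exactly (asserted).
    """
    if n_rep < 1:
        raise ValueError("n_rep must be >= 1")
    row_tot = a.row_totals
    col_tot = a.col_totals
    if a.individuals <= 0:
        raise ValueError("RC null requires a positive grand total")
    rng = np.random.default_rng(seed)
    reps = np.empty((n_rep, a.n_rows, a.n_cols), dtype=np.int64)
    for k in range(n_rep):
        rep = _rc_one(row_tot, col_tot, rng)
        assert (rep.sum(axis=1) == row_tot).all() and (rep.sum(axis=0) == col_tot).all()
        reps[k] = rep
    return reps


def _iter_null_matrices(
    a: AbundanceMatrix, null_kind: str, n_rep: int, seed: int | None
) -> Iterator[AbundanceMatrix]:
    kind = null_kind.lower()
    if kind == "ce":
        arrays = ce_null(a.binarize(), n_rep, seed)
        cls: type = IncidenceMatrix
    elif kind == "rc":
        arrays = rc_null(a, n_rep, seed)
        cls = AbundanceMatrix
    else:
        raise ValueError(f"null_kind must be 'ce' or 'rc', got {null_kind!r}")
    for arr in arrays:
        yield cls(arr, a.row_labels, a.col_labels)


def significance(
    statistic: Callable[[AbundanceMatrix], float],
    a: AbundanceMatrix,
    null_kind: str = "ce",
    n_rep: int = 1000,
    seed: int | None = None,
    name: str | None = None,
    null_basis: AbundanceMatrix | None = None,
) -> NullEnsemble:
    """Monte-Carlo significance of ``statistic(a)`` under a CE or RC null.

    By default the null ensemble is parameterised by ``a`` itself (its
    occupancy proportions for CE, its marginal totals for RC).
    ``null_basis`` conditions the ensemble on a different reference matrix
    instead; when ``a`` is itself a draw from that ensemble the p-value is
    exactly uniform by exchangeability, which is how the calibration of
    the test is checked.

    Replicates on which the statistic is undefined (raises a ValueError,
    e.g. a degenerate CE draw) are dropped and counted; a warning is issued
    if more than 1% are dropped.
    """
    observed = float(statistic(a))
    nulls: list[float] = []
    dropped = 0
    for null_matrix in _iter_null_matrices(null_basis or a, null_kind, n_rep, seed):
        try:
            nulls.append(float(statistic(null_matrix)))
        except ValueError:
            dropped += 1
    if dropped > 0.01 * n_rep:
        warnings.warn(
            f"{dropped}/{n_rep} null replicates dropped (statistic undefined)",
            stacklevel=2,
        )
    return NullEnsemble(
        statistic=name or getattr(statistic, "__name__", "statistic"),
        observed=observed,
        null_values=np.asarray(nulls, dtype=float),
        n_rep=n_rep,
        seed=seed,
        n_dropped=dropped,
    )


def nodf_significance(
    a: AbundanceMatrix, n_rep: int = 1000, seed: int | None = None
) -> NullEnsemble:
    """NODF against the CE null (the qualitative test)."""
    from .nestedness import nodf

    return significance(
        lambda mat: nodf(mat).total, a.binarize(), "ce", n_rep, seed, name="NODF"
    )


def wnodf_significance(
    a: AbundanceMatrix, n_rep: int = 1000, seed: int | None = None
) -> NullEnsemble:
    """WNODF against the RC null (the quantitative test)."""
    from .nestedness import wnodf

    return significance(
        lambda mat: wnodf(mat).total, a, "rc", n_rep, seed, name="WNODF"
    )
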