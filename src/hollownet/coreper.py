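"""Categorical core/periphery structure on the bipartite incidence matrix.

The model partitions both row and column nodes into a core and a
periphery.  Fitness of an assignment is the Pearson correlation between
the observed 0/1 cells and the ideal pattern in which every
core-row x core-column cell is 1 and every periphery x periphery cell is
0; the mixed (core x periphery) blocks are excluded from the correlation.
A single fit hill-climbs from a random assignment by steepest-ascent
single-node flips (with a few random restarts per fit, keeping the best
local optimum).

Following the 25-run frequency protocol, an ensemble of independent fits
yields a per-node core frequency, classified into two tiers:
frequency >= 80% -> core_a, 65-79% -> core_b, otherwise periphery.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .matrix import AbundanceMatrix

#: Default tier thresholds (fractions of runs in which a node is core).
CORE_A_MIN = 0.80
CORE_B_MIN = 0.65


class ZeroVarianceError(ValueError):
    """Constant matrix: the core/periphery correlation is undefined."""


@dataclass(frozen=True)
class CoreFit:
    """One local optimum: boolean core masks for both levels and fitness."""

    row_core: np.ndarray
    col_core: np.ndarray
    fitness: float


@dataclass(frozen=True)
class CorePeripheryProfile:
    """Per-node core frequency over an ensemble of fits, with tiers.

    Frequencies are multiples of 1/n_runs; tiers are a pure function of
    the frequency vector and the two thresholds.
    """

    row_labels: tuple[str, ...]
    col_labels: tuple[str, ...]
    row_frequency: np.ndarray
    col_frequency: np.ndarray
    fitnesses: np.ndarray
    n_runs: int
    core_a_min: float = CORE_A_MIN
    core_b_min: float = CORE_B_MIN

    @property
    def row_tiers(self) -> list[str]:
        return [classify_tier(f, self.core_a_min, self.core_b_min) for f in self.row_frequency]

    @property
    def col_tiers(self) -> list[str]:
        return [classify_tier(f, self.core_a_min, self.core_b_min) for f in self.col_frequency]

    def tier_of(self, node: str) -> str:
        if node in self.row_labels:
            return self.row_tiers[self.row_labels.index(node)]
        return self.col_tiers[self.col_labels.index(node)]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"node": lab, "level": "species", "core_frequency": float(f), "tier": t}
            for lab, f, t in zip(self.row_labels, self.row_frequency, self.row_tiers)
        ] + [
            {"node": lab, "level": "hollow", "core_frequency": float(f), "tier": t}
            for lab, f, t in zip(self.col_labels, self.col_frequency, self.col_tiers)
        ]
        return pd.DataFrame(rows)


def classify_tier(
    frequency: float, core_a_min: float = CORE_A_MIN, core_b_min: float = CORE_B_MIN
) -> str:
    """Two-tier classification of a core frequency.

    The boundary value ``frequency == core_a_min`` (80%) is assigned to
    core_a.
    """
    if frequency >= core_a_min:
        return "core_a"
    if frequency >= core_b_min:
        return "core_b"
    return "periphery"


def _fitness_from_counts(n1, n0, s1, s0):
    """Pearson correlation from block counts (vectorised, -inf if undefined).

    n1/n0 = number of core-core / periphery-periphery cells included,
    s1/s0 = number of observed 1s among them.  x (observed) and y (ideal)
    are both binary, so the correlation is a closed form of these counts.
    """
    n1 = np.asarray(n1, dtype=float)
    n0 = np.asarray(n0, dtype=float)
    s1 = np.asarray(s1, dtype=float)
    s0 = np.asarray(s0, dtype=float)
    n = n1 + n0
    s = s1 + s0
    with np.errstate(divide="ignore", invalid="ignore"):
        mx = s / n
        my = n1 / n
        var_x = mx * (1.0 - mx)
        var_y = my * (1.0 - my)
        cov = s1 / n - mx * my
        fit = cov / np.sqrt(var_x * var_y)
    bad = (n <= 0) | (n1 <= 0) | (n0 <= 0) | (var_x <= 0) | (var_y <= 0)
    return np.where(bad, -np.inf, fit)


class _Climber:
    def __init__(self, binc: np.ndarray):
        self.b = binc
        self.n_rows, self.n_cols = binc.shape
        self.row_sum = binc.sum(axis=1)
        self.col_sum = binc.sum(axis=0)

    def start(self, row_core: np.ndarray, col_core: np.ndarray) -> None:
        self.rc = row_core.copy()
        self.cc = col_core.copy()
        self._refresh()

    def _refresh(self) -> None:
        self.d_core = self.b @ self.cc          # per-row links into core columns
        self.e_core = self.rc @ self.b          # per-col links from core rows
        ncr, ncc = int(self.rc.sum()), int(self.cc.sum())
        npr, npc = self.n_rows - ncr, self.n_cols - ncc
        self.n1 = ncr * ncc
        self.n0 = npr * npc
        self.s1 = int(self.d_core @ self.rc)
        self.s0 = int((self.row_sum - self.d_core) @ (1 - self.rc))

    def fitness(self) -> float:
        return float(_fitness_from_counts(self.n1, self.n0, self.s1, self.s0))

    def _candidates(self):
        ncr, ncc = int(self.rc.sum()), int(self.cc.sum())
        npr, npc = self.n_rows - ncr, self.n_cols - ncc
        # rows: flipping row r toggles membership; sign +1 when periphery->core
        sign_r = 1 - 2 * self.rc
        n1_r = self.n1 + sign_r * ncc
        n0_r = self.n0 - sign_r * npc
        s1_r = self.s1 + sign_r * self.d_core
        s0_r = self.s0 - sign_r * (self.row_sum - self.d_core)
        fit_r = _fitness_from_counts(n1_r, n0_r, s1_r, s0_r)
        sign_c = 1 - 2 * self.cc
        n1_c = self.n1 + sign_c * ncr
        n0_c = self.n0 - sign_c * npr
        s1_c = self.s1 + sign_c * self.e_core
        s0_c = self.s0 - sign_c * (self.col_sum - self.e_core)
        fit_c = _fitness_from_counts(n1_c, n0_c, s1_c, s0_c)
        return fit_r, fit_c

    def climb(self, max_steps: int | None = None) -> float:
        max_steps = max_steps or 10 * (self.n_rows + self.n_cols)
        current = self.fitness()
        for _ in range(max_steps):
            fit_r, fit_c = self._candidates()
            br = int(np.argmax(fit_r))
            bc = int(np.argmax(fit_c))
            best_fit, flip_row = (fit_r[br], True) if fit_r[br] >= fit_c[bc] else (fit_c[bc], False)
            if not best_fit > current + 1e-12:
                return current
            if flip_row:
                self.rc[br] ^= 1
            else:
                self.cc[bc] ^= 1
            self._refresh()
            current = best_fit
        return current

    def expand_core(self, current: float) -> float:
        """Grow the core at constant fitness (tie-break toward larger cores).

        The correlation is flat over nested subsets of a perfect core
        (mixed blocks are excluded), so among equally good assignments we
        prefer the one including more core-core cells; this makes planted
        cores recoverable exactly.
        """
        while True:
            fit_r, fit_c = self._candidates()
            grew = False
            for arr, fits, mask in ((self.rc, fit_r, self.rc == 0), (self.cc, fit_c, self.cc == 0)):
                cand = np.where(mask, fits, -np.inf)
                best = int(np.argmax(cand))
                if cand[best] >= current - 1e-12 and np.isfinite(cand[best]):
                    arr[best] = 1
                    self._refresh()
                    current = max(current, float(cand[best]))
                    grew = True
                    break
            if not grew:
                return current


def fit_once(
    b: AbundanceMatrix, seed: int | None = None, n_restarts: int = 5
) -> CoreFit:
    """One core/periphery fit: best of ``n_restarts`` hill-climbs.

    Raises :class:`ZeroVarianceError` on a constant matrix (e.g. all ones),
    where the correlation objective is undefined.
    """
    binc = (np.asarray(b.values) > 0).astype(np.int64)
    if binc.size == 0 or binc.min() == binc.max():
        raise ZeroVarianceError("constant matrix: core/periphery fit undefined")
    rng = np.random.default_rng(seed)
    climber = _Climber(binc)
    best: CoreFit | None = None
    for _ in range(n_restarts):
        climber.start(
            rng.integers(0, 2, size=binc.shape[0]),
            rng.integers(0, 2, size=binc.shape[1]),
        )
        fit = climber.climb()
        fit = climber.expand_core(fit)
        if best is None or fit > best.fitness:
            best = CoreFit(climber.rc.astype(bool), climber.cc.astype(bool), float(fit))
    assert best is not None
    return best


def fit_ensemble(
    b: AbundanceMatrix,
    n_runs: int = 25,
    seed: int | None = None,
    core_a_min: float = CORE_A_MIN,
    core_b_min: float = CORE_B_MIN,
) -> CorePeripheryProfile:
    """``n_runs`` independent fits from random starts -> core frequencies."""
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    rng = np.random.default_rng(seed)
    run_seeds = rng.integers(2**31, size=n_runs)
    row_count = np.zeros(b.n_rows)
    col_count = np.zeros(b.n_cols)
    fits = np.empty(n_runs)
    for k in range(n_runs):
        fit = fit_once(b, seed=int(run_seeds[k]))
        row_count += fit.row_core
        col_count += fit.col_core
        fits[k] = fit.fitness
    return CorePeripheryProfile(
        row_labels=b.row_labels,
        col_labels=b.col_labels,
        row_frequency=row_count / n_runs,
        col_frequency=col_count / n_runs,
        fitnesses=fits,
        n_runs=n_runs,
        core_a_min=core_a_min,
        core_b_min=core_b_min,
    )
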