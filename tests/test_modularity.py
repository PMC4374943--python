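"""Barber modularity: exact evaluation, oracle, SA optimizer, significance."""

import itertools
from fractions import Fraction

import numpy as np
import pytest

from hollownet import (
    ModulePartition,
    SASchedule,
    barber_modularity,
    modularity_significance,
    optimize_sa,
)
from hollownet.synthetic import SynthSpec, generate_modular

from conftest import labeled, random_abundance


def barber_oracle(binc: np.ndarray, row_mod, col_mod) -> Fraction:
    """Independent rational-arithmetic evaluation of bipartite modularity."""
    total = int(binc.sum())
    row_deg = binc.sum(axis=1)
    col_deg = binc.sum(axis=0)
    mods = set(row_mod) | set(col_mod)
    acc = Fraction(0)
    for mod in mods:
        l_m = sum(
            int(binc[i, j])
            for i in range(binc.shape[0])
            for j in range(binc.shape[1])
            if row_mod[i] == mod and col_mod[j] == mod
        )
        k_a = sum(int(row_deg[i]) for i in range(binc.shape[0]) if row_mod[i] == mod)
        k_b = sum(int(col_deg[j]) for j in range(binc.shape[1]) if col_mod[j] == mod)
        acc += Fraction(l_m, total) - Fraction(k_a * k_b, total**2)
    return acc


def set_partitions(items):
    """All partitions of a list (restricted growth strings)."""
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for smaller in set_partitions(rest):
        for k in range(len(smaller)):
            yield smaller[:k] + [[first] + smaller[k]] + smaller[k + 1:]
        yield [[first]] + smaller


class TestEvaluation:
    def test_one_module_is_zero(self, two_blocks):
        part = ModulePartition([0] * 4, [0] * 4)
        assert barber_modularity(two_blocks, part) == pytest.approx(0.0, abs=1e-12)

    def test_planted_two_blocks_is_half(self, two_blocks):
        part = ModulePartition([0, 0, 1, 1], [0, 0, 1, 1])
        assert barber_modularity(two_blocks, part) == pytest.approx(0.5, abs=1e-12)

    def test_complete_bipartite_never_positive(self):
        """Exhaustive: no partition of K_{2,2} has positive modularity."""
        k22 = labeled(np.ones((2, 2), dtype=int))
        nodes = ["r0", "r1", "c0", "c1"]
        best = -np.inf
        for blocks in set_partitions(nodes):
            assignment = {n: k for k, block in enumerate(blocks) for n in block}
            part = ModulePartition(
                [assignment["r0"], assignment["r1"]],
                [assignment["c0"], assignment["c1"]],
            )
            best = max(best, barber_modularity(k22, part))
        assert best <= 1e-12

    def test_matches_rational_oracle_on_random_partitions(self):
        rng = np.random.default_rng(21)
        for _ in range(25):
            m = random_abundance(rng, max_rows=10, max_cols=10)
            binc = (m.values > 0).astype(int)
            if binc.sum() == 0:
                continue
            k = int(rng.integers(1, 5))
            row_mod = rng.integers(0, k, m.n_rows)
            col_mod = rng.integers(0, k, m.n_cols)
            ours = barber_modularity(m, ModulePartition(row_mod, col_mod))
            assert ours == pytest.approx(float(barber_oracle(binc, row_mod, col_mod)), abs=1e-12)

    def test_invariance_under_relabeling_and_permutation(self):
        rng = np.random.default_rng(22)
        m = random_abundance(rng).drop_empty()
        row_mod = rng.integers(0, 3, m.n_rows)
        col_mod = rng.integers(0, 3, m.n_cols)
        base = barber_modularity(m, ModulePartition(row_mod, col_mod))
        relab = barber_modularity(m, ModulePartition(7 - row_mod, 7 - col_mod))
        assert relab == pytest.approx(base, abs=1e-12)
        pr, pc = rng.permutation(m.n_rows), rng.permutation(m.n_cols)
        perm = barber_modularity(m.permuted(pr, pc), ModulePartition(row_mod[pr], col_mod[pc]))
        assert perm == pytest.approx(base, abs=1e-12)


class TestOptimizer:
    def test_two_blocks_recovered(self, two_blocks):
        part = optimize_sa(two_blocks, seed=0)
        assert part.modularity == pytest.approx(0.5, abs=1e-12)
        assert part.n_modules == 2

    def test_complete_bipartite_returns_single_module(self):
        k22 = labeled(np.ones((3, 3), dtype=int))
        part = optimize_sa(k22, seed=1)
        assert part.modularity == pytest.approx(0.0, abs=1e-12)
        assert part.n_modules == 1

    def test_reported_m_consistent_with_direct_evaluation(self):
        rng = np.random.default_rng(23)
        m = random_abundance(rng).drop_empty()
        part = optimize_sa(m.binarize(), seed=2)
        assert part.modularity == pytest.approx(barber_modularity(m, part), abs=1e-10)
        assert part.modularity >= -1e-12  # never below the one-module baseline

    def test_planted_partition_m_matched_at_high_strength(self):
        spec = SynthSpec(
            30, 30, 0.2, structure="modular", structure_strength=0.95, n_modules=3, seed=31
        )
        m, planted = generate_modular(spec)
        planted_m = barber_modularity(m, planted)
        best = optimize_sa(m.binarize(), seed=3).modularity
        assert best >= 0.99 * planted_m

    def test_longer_schedule_not_worse_on_average(self):
        spec = SynthSpec(
            20, 20, 0.2, structure="modular", structure_strength=0.6, n_modules=3, seed=77
        )
        m, _ = generate_modular(spec)
        short = [optimize_sa(m.binarize(), SASchedule.greedy(), seed=s).modularity for s in range(5)]
        full = [optimize_sa(m.binarize(), SASchedule.default(), seed=s).modularity for s in range(5)]
        assert np.mean(full) >= np.mean(short) - 1e-9


class TestSignificance:
    def test_zero_randomizations_rejected(self, two_blocks):
        with pytest.raises(ValueError):
            modularity_significance(two_blocks, n_rand=0, seed=0)

    def test_planted_structure_is_significant(self):
        spec = SynthSpec(
            24, 24, 0.25, structure="modular", structure_strength=1.0, n_modules=4, seed=13
        )
        m, _ = generate_modular(spec)
        n_rand = 100
        ens = modularity_significance(m, n_rand=n_rand, seed=14)
        assert ens.p_value == pytest.approx(1 / (n_rand + 1))

    def test_ce_generated_input_usually_nonsignificant(self):
        """Calibration under the null: CE draws should rarely look modular."""
        from hollownet.matrix import IncidenceMatrix
        from hollownet.nullmodels import ce_null
        from hollownet.synthetic import generate_nested

        ref = generate_nested(SynthSpec(16, 16, 0.3, structure_strength=0.5, seed=7))
        nonsig = 0
        n_trials = 50
        for t in range(n_trials):
            draw = ce_null(ref.binarize(), 1, seed=1000 + t)[0]
            b = IncidenceMatrix(draw, ref.row_labels, ref.col_labels)
            ens = modularity_significance(b, n_rand=60, seed=2000 + t)
            if ens.p_value > 0.05:
                nonsig += 1
        assert nonsig >= 0.9 * n_trials
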