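"""NODF/WNODF: worked examples, brute-force oracle, invariances."""

import itertools
import subprocess
import sys
import textwrap

import numpy as np
import pytest

from hollownet import DegenerateNetworkError, nodf, wnodf, write_matrix

from conftest import labeled, random_abundance


def nodf_bruteforce(binc: np.ndarray) -> float:
    """Independent exhaustive pairwise NODF (plain loops, no vectorization)."""

    def axis_contribs(mat):
        out = []
        for u, v in itertools.combinations(range(mat.shape[0]), 2):
            fu, fv = mat[u].sum(), mat[v].sum()
            if fu > fv and fv > 0:
                out.append(100.0 * np.sum(mat[u] * mat[v]) / fv)
            elif fv > fu and fu > 0:
                out.append(100.0 * np.sum(mat[u] * mat[v]) / fu)
            else:
                out.append(0.0)
        return out

    contribs = axis_contribs(binc) + axis_contribs(binc.T)
    return float(np.mean(contribs))


def wnodf_bruteforce(w: np.ndarray) -> float:
    """Independent exhaustive pairwise WNODF."""

    def pair(heavy, light):
        npos = np.count_nonzero(light)
        if npos == 0:
            return 0.0
        hits = np.sum((light > 0) & (light < heavy))
        return 100.0 * hits / npos

    def axis_contribs(mat):
        out = []
        for u, v in itertools.combinations(range(mat.shape[0]), 2):
            tu, tv = mat[u].sum(), mat[v].sum()
            if tu > tv:
                out.append(pair(mat[u], mat[v]))
            elif tv > tu:
                out.append(pair(mat[v], mat[u]))
            else:
                out.append(0.0)
        return out

    contribs = axis_contribs(w) + axis_contribs(w.T)
    return float(np.mean(contribs))


class TestWorkedExamples:
    def test_packed_triangle_is_100(self, triangle3):
        assert nodf(triangle3).total == 100.0

    def test_equal_fills_give_zero(self, identity3):
        assert nodf(identity3).total == 0.0

    def test_three_by_three_enumeration(self):
        m = labeled([[1, 1, 0], [0, 1, 1], [1, 0, 0]])
        # rows: (0,2)=100, others 0; cols: (1,2)=100, others 0; mean of 6
        assert nodf(m).total == pytest.approx(100 / 3, abs=1e-9)

    def test_wnodf_strict_staircase_is_100(self):
        m = labeled([[3, 2, 1], [2, 1, 0], [1, 0, 0]])
        assert wnodf(m).total == 100.0

    def test_wnodf_equal_totals_zero(self):
        m = labeled([[2, 1], [1, 2]])  # equal row totals and col totals
        assert wnodf(m).total == 0.0

    def test_wnodf_binary_ties_never_count(self):
        # on a 0/1 matrix a positive cell of the lighter row is never
        # strictly smaller than the heavier row's cell, so WNODF is 0
        rng = np.random.default_rng(0)
        for _ in range(30):
            binc = (rng.random((5, 6)) < 0.5).astype(int)
            if binc.sum() == 0:
                continue
            m = labeled(binc)
            assert wnodf(m).total == 0.0
            assert wnodf_bruteforce(binc) == 0.0

    def test_single_cell_matrix_undefined(self):
        with pytest.raises(DegenerateNetworkError):
            nodf(labeled([[1]]))


class TestOracle:
    def test_matches_bruteforce_on_random_matrices(self):
        rng = np.random.default_rng(2024)
        for _ in range(60):
            m = random_abundance(rng)
            binc = (m.values > 0).astype(int)
            assert nodf(m).total == pytest.approx(nodf_bruteforce(binc), abs=1e-10)
            assert wnodf(m).total == pytest.approx(wnodf_bruteforce(m.values), abs=1e-10)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            m = random_abundance(rng)
            perm = m.permuted(rng.permutation(m.n_rows), rng.permutation(m.n_cols))
            assert nodf(perm).total == pytest.approx(nodf(m).total, abs=1e-10)
            assert wnodf(perm).total == pytest.approx(wnodf(m).total, abs=1e-10)

    def test_row_col_components_assemble_total(self):
        rng = np.random.default_rng(6)
        m = random_abundance(rng)
        val = nodf(m)
        n_r = m.n_rows * (m.n_rows - 1) // 2
        n_c = m.n_cols * (m.n_cols - 1) // 2
        assert val.total == pytest.approx(
            (val.row_component * n_r + val.col_component * n_c) / (n_r + n_c)
        )


R_SCRIPT = textwrap.dedent(
    """
    suppressMessages(library(vegan))
    args <- commandArgs(trailingOnly=TRUE)
    m <- as.matrix(read.csv(args[1], row.names=1, check.names=FALSE))
    q <- nestednodf(m, order=TRUE, weighted=FALSE)
    w <- nestednodf(m, order=TRUE, weighted=TRUE)
    cat(sprintf("%.10f %.10f", q$statistic["NODF"], w$statistic["NODF"]))
    """
)


@pytest.mark.parametrize("seed", [11, 23])
def test_independent_reference_implementation_agrees(tmp_path, seed):
    """Cross-check against vegan::nestednodf on matrices where its weighted
    pair condition (binary fill) coincides with ours (marginal totals):
    fills and totals strictly co-decreasing."""
    rng = np.random.default_rng(seed)
    n = 6
    vals = np.zeros((n, n), dtype=int)
    for i in range(n):
        for j in range(n - i):
            # strict staircase; value ramp keeps totals co-monotone with fills
            vals[i, j] = 3 * (n - i) + 3 * (n - j) + int(rng.integers(0, 3))
    m = labeled(vals).drop_empty()
    path = tmp_path / "m.csv"
    write_matrix(m, path)
    script = tmp_path / "check.R"
    script.write_text(R_SCRIPT)
    try:
        proc = subprocess.run(
            ["Rscript", str(script), str(path)],
            capture_output=True, text=True, timeout=120, check=True,
        )
    except (FileNotFoundError, subprocess.CalledProcessError):
        pytest.skip("Rscript/vegan unavailable")
    ref_nodf, ref_wnodf = map(float, proc.stdout.split())
    assert nodf(m).total == pytest.approx(ref_nodf, abs=1e-6)
    assert wnodf(m).total == pytest.approx(ref_wnodf, abs=1e-6)
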